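# Methods

This note documents the statistical procedures `tp53tx` implements, the
synthetic-cohort model used to exercise them, the numerical choices made
where the design was open, and what the package's tests do and do not
establish about real data.

## DNA-level status rules

Copy-number log2 fold-changes are binned as amplification (≥ 0.8), gain
[0.2, 0.8), neutral (−0.2, 0.2), deletion [−2.0, −0.2], deep deletion
(< −2.0). The interval-notation boundaries are assigned so the two strict
or inclusive signs that are unambiguous (≥ 0.8, < −2.0) are respected and
deletion is closed on both ends; the neutral band is open. B-allele
frequencies are folded to [0, 0.5] via min(b, 1−b); LOH is folded BAF
strictly below 0.25. A sample is **biallelic** given deep deletion, or a
mutation (missense/nonsense/frameshift/splice-site, no VAF floor) combined
with deletion, or a mutation combined with LOH — evidence recorded as the
first matching rule in that order. Any single hit (mutation, deletion, or
LOH) is **monoallelic**; LOH alone counts as monoallelic evidence whether
or not it is copy-neutral. Gain/amplification never contributes to loss.
Gene-level CNV from segment files takes the largest-overlap segment,
breaking overlap ties toward the more extreme |log2FC|; no overlap is
neutral (0.0). Coordinates are 1-based inclusive (SEG/MAF convention).

## Differential expression and signature tiers

Testing runs on Log₂(TPM+1). Each gene gets a Welch two-sample *t*-test
(biallelic vs wild-type) with Benjamini–Hochberg FDR across all tested
genes; genes with zero variance in both groups are assigned p = 1 rather
than NaN. A moderated (empirical-Bayes) test would shrink per-gene
variances; at the group sizes involved (tens vs hundreds) the unmoderated
Welch test is adequate and keeps the package self-contained. Fold-change
is computed on the linear scale as (mean TPM₁ + 1)/(mean TPM₀ + 1) — the
same +1 pseudocount as the transform, and reciprocal-symmetric so the
1.4 / 0.71 cutoffs treat up- and down-regulation alike. The expression
floor ("Log₂(TPM+1) > 1 in either group") is interpreted as the *group
mean* of transformed values. Tier sets FC > {1.5, 2, 2.5, 3} (or below the
reciprocal) are nested by construction; the base filter keeps its own
1.4 / 0.71 bounds, which are intentionally looser than the lowest tier.

## Signature model

A *regression* random forest is fit to 0/1 labels; the score is the
ensemble mean and lies in [0, 1]. The hyperparameter grid spans tree
counts over the open integer interval (1, n_genes) and two leaf-fraction
regularizers over (0, 1) in 0.05 steps (19 values each). Two numerical
choices here:

* the "minimum samples per leaf" parameter is treated as a **fraction of
  training samples** (its grid is printed over the unit interval, which
  only makes sense as a fraction);
* the tree builder rejects min_weight_fraction_leaf above 0.5 (such a
  leaf constraint can never admit a split), so values above 0.5 are
  clamped to 0.5 when fitting — they behave identically: every tree
  predicts the training-label mean.

Model selection uses the validation split only: among candidates with
AUROC > 0.8, the highest AUPRC wins; ties break to fewer trees, then a
larger leaf fraction (the stronger regularizer). If nothing clears the
floor the best-AUPRC candidate is returned with a warning flag rather
than an error. AUROC is trapezoidal (identical to the Mann–Whitney
concordance probability); AUPRC is step-integrated precision over recall
— both are oracle-tested against brute-force enumeration. The default
end-to-end search uses the full tree range but a 0.2-step fraction grid
(25 combinations per tree count), a problem size that keeps a full
cohort run in seconds; the full 0.05-step grid remains available through
`hyperparameter_grid`. The reported signature is the set of features with
nonzero impurity importance in the winning forest.

The operating point is the **maximum-sensitivity cutoff**: the minimum
validation score over known biallelic samples, applied inclusively
(score ≥ cutoff ⇒ predicted biallelic). Sensitivity on the deriving set is
therefore exactly 1 — a guarantee, not an empirical result — and the
specificity cost is whatever the score distribution implies.

## Splicing, isoforms, mechanisms

PSI = intron reads / (junction + intron reads), undefined (NaN-flagged)
at zero depth; the junction count is the excising junction for the event,
supplied by the caller. dPSI = mean PSI(normals) − PSI(tumor): splicing
gain in the tumor is *negative*. The isoform imbalance ratio is
(TAp53β + TAp53γ)/TAp53α over transcript classes given by a user-supplied
map (β vs γ is a transcript-annotation distinction, not computable from
counts here, so the map carries it). Mechanism calls accumulate labels:

| label | rule | default |
|---|---|---|
| cryptic_exon_inclusion | dPSI ≤ −dpsi_min | dpsi_min = 0.2 |
| retained_intron | tumor PSI ≥ psi_min and normal mean ≤ normal_psi_max | 0.2 / 0.05 |
| low_total_expression | Log₂(TPM+1) ≤ expr_floor or log2FC vs normals ≤ −0.8 | expr_floor = 1.0 |
| splice_site_mutation_driven | splice-site VAF ≥ vaf_floor and a splicing label co-occurs | vaf_floor = 0.2 |
| unexplained | none of the above | — |

The thresholds bracket the worked values the analysis is built around
(cryptic-exon dPSI of −0.54 and −0.29; a low-expression case at
Log₂(TPM+1) = 1.01 with log2FC −0.89; driver splice-site VAFs 0.26–0.83
against an average of 0.1 for non-drivers) and are all exposed in
`MechanismThresholds`. Missing data layers produce a partial call with the
missing layers listed, not an error. Regulator ranking uses Spearman ρ
with average ranks for ties, sorted by |ρ|.

## Survival statistics

Kaplan–Meier, log-rank, and Mann–Whitney are implemented natively (they
are part of what the package is for) and cross-checked against lifelines
and scipy in the test suite. Conventions: events precede censorings at
tied times; the median is the smallest event time with S(t) ≤ 0.5, with
"not reached" propagated as an explicit token; the log-rank variance is
the standard hypergeometric form with the (n−d)/(n−1) correction; all
tests are two-sided. Mann–Whitney p-values are exact by enumeration of
all label assignments when min(n) ≤ 8 and total n ≤ 16 (two-sidedness via
distance of U from its null mean, which remains valid under ties), and
use the tie-corrected normal approximation without continuity correction
otherwise. Cox regression is deliberately out of scope; the log-rank test
carries all group comparisons. ARS (after-relapse survival) is measured
from the first day the abnormality was detected or predicted to death or
censoring.

The log-rank χ² approximation is asymptotic; in simulation its size is
~5.4% at n = 100 per group but inflates (~7%) at n = 25, so the null
calibration check runs at n = 100 — a property of the statistic, not of
this implementation (lifelines agrees to machine precision).

## Synthetic cohort model

The generator emulates the study inputs with ground truth:

* **Statuses** are drawn i.i.d. per sample at prevalences 3.6% biallelic /
  9.8% monoallelic / 86.5% wild-type; 42% of monoallelic samples are
  flagged cryptic-biallelic and given one planted transcriptomic
  mechanism (cryptic exon + LOH or + deletion, low expression + deletion,
  retained intron, splice-site mutation) alongside exactly one DNA hit,
  so the DNA rules see them as monoallelic.
* **DNA tables** (MAF-style mutations, SEG segments, folded BAF) are
  sampled so the rule-based caller reproduces the DNA-level truth for
  100% of samples (an invariant under test).
* **Expression** is log-normal on the Log₂(TPM+1) scale: per-gene
  baselines U(3, 8), Gaussian noise with sd 0.5 (a realistic bulk
  RNA-seq log-scale dispersion), and a signed signature effect added in
  biallelic *and* cryptic-biallelic samples. Effect magnitudes are drawn
  U(1, 3) log2 units with alternating signs (half up, half down) — a
  stand-in, since no per-gene effect distribution is published beyond the
  fold-change tiers; it is exposed in `CohortConfig`. The pipeline
  consumes TPM, so a count-level negative-binomial model would add
  realism the downstream maths never sees.
* **Splicing counts**: total depth Poisson(200) per event, binomially
  split at the planted PSI — 0.02 baseline (an unexpressed cryptic exon
  in normal cells sits near zero) and 0.6 in mechanism samples, implying
  dPSI ≈ −0.58 in the planted cases. The binomial split makes E[PSI]
  equal the target exactly, giving analytic oracles.
* **Survival**: exponential times with per-group PFS medians
  478 / 623 / 1832 / 1176 days (biallelic / cryptic / monoallelic / WT) —
  the ordering and scale of the clinical separation the classifier is
  meant to recover — with OS medians 2.3× PFS and independent uniform
  censoring on [0, 2 × max median] applied to a 30% random subset. Five
  normal plasma-cell samples accompany every cohort for dPSI and
  expression baselines.

What the generator does **not** model: read-level data, gene–gene
co-regulation and pathway structure, count noise in expression, batch
effects, β-vs-γ sequence differences, and relapse sampling of the same
patients. Passing tests therefore demonstrate that the pipeline's logic
and statistics behave as specified under the planted model — not that the
signature or its operating point transfer to any particular real cohort.

## Problem sizes and determinism

Every stochastic component flows through one seeded
`numpy.random.Generator`; identical config + seed gives byte-identical
bundles and reports. The shipped verification runs use cohorts of
600–1000 samples with 120–500 background genes, 10–20 seed replicates
for recovery rates, 1000 replicates for metric-oracle and null-rate
checks — sizes at which the measured quantities' Monte-Carlo error is
small against the tolerances asserted, while a full suite plus the
acceptance script completes in a few minutes on one CPU.

## Known limitations

* LOH is treated as monoallelic evidence regardless of copy-number
  context; copy-neutral and deletion-associated LOH are not distinguished.
* The Welch/BH DE procedure will be slightly conservative relative to a
  moderated test at very small group sizes.
* The discovery-set prediction inherits the cutoff's asymmetry: 100%
  sensitivity is guaranteed only on the deriving set; discovery recall
  depends on score-distribution transfer.
* Mechanism rules are thresholded heuristics; a sample with several
  planted abnormalities receives all qualifying labels, and "unexplained"
  is an honest residual category, not an error state.
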