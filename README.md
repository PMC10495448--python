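# tp53tx

Detecting **hidden biallelic TP53 inactivation** in multiple myeloma
transcriptomes.

Biallelic loss of *TP53* — both gene copies knocked out — is among the
strongest high-risk markers in multiple myeloma, but DNA evidence alone
(mutation, copy-number loss, loss of heterozygosity) misses cases where the
second hit is *transcriptomic*: cryptic-exon inclusion that switches
transcripts to the high-risk β/γ isoform classes, intron retention,
splice-site mutations, or simply insufficient expression of the remaining
allele. `tp53tx` implements a complete, testable pipeline that

1. **calls DNA-level status** per sample with rule-based logic —
   biallelic ⇔ deep deletion (Log2FC < −2), mutation + deletion
   (−2 ≤ Log2FC ≤ −0.2), or mutation + LOH (folded BAF < 0.25);
   a single hit of any kind ⇔ monoallelic;
2. **derives an expression signature** between known biallelic and
   wild-type samples (Welch *t*-test on Log₂(TPM+1), BH FDR < 0.05,
   FC > 1.4 or < 0.71, mean Log₂(TPM+1) > 1 in a group), tiered into nested
   FC1.5 / FC2 / FC2.5 / FC3 feature sets;
3. **trains a regression random forest** on 0/1 labels over a stratified
   7:3 split, grid-searching trees × leaf fractions, selecting by
   **AUPRC first with an AUROC > 0.8 floor** (AUPRC is the honest metric at
   ~4% prevalence), validating by five-fold CV, and fixing the
   **maximum-sensitivity cutoff** — the lowest validation score among known
   biallelic samples, giving 100% sensitivity on the deriving set by
   construction;
4. **scores the DNA-monoallelic discovery set** to nominate hidden
   ("cryptic") biallelic samples;
5. **assigns each nominee a mechanism** from splicing and isoform data:
   PSI = intron reads / (junction + intron reads),
   dPSI = PSI(normal) − PSI(tumor), the high-risk isoform imbalance
   (TAp53β + TAp53γ)/TAp53α, splice-site-mutation VAF association, and
   candidate-regulator ranking by Spearman ρ;
6. **stratifies survival** (PFS/OS/ARS) with natively implemented
   Kaplan–Meier estimation, log-rank tests, and Mann–Whitney U.

The study's real cohort is controlled-access, so the package ships a
first-class **synthetic cohort generator** that plants all of this
structure — class prevalences (3.6% biallelic / 9.8% monoallelic),
a 16-gene up/down signature, cryptic-biallelic samples (42% of the
monoallelic group) with mechanism-linked splicing counts, and
group-differential survival — with ground truth for every sample.

## Worked example

```bash
tp53tx simulate --n-samples 634 --seed 7 --out cohort/
tp53tx run-all --bundle cohort/ --seed 7 --out run/
```

prints

```
wrote cohort of 634 samples to cohort/
predicted 23 hidden biallelic samples among 56 monoallelic; report in run/
```

and `run/report.json` contains (abridged):

```json
"status_counts": {"biallelic": 23, "monoallelic": 56, "WT": 555},
"model": {"n_trees": 3, "validation_auroc": 1.0, "validation_auprc": 1.0,
          "cutoff": 0.2889, "fold_aurocs": [1.0, 1.0, 1.0, 0.994, 1.0]},
"n_predicted_biallelic": 23,
"survival": {"PFS": {"median_days": {"known_biallelic": 577.1,
              "predicted_biallelic": 481.5, "predicted_monoallelic": 1504.5,
              "WT": 1155.5}}}
```

Reading: the DNA rules found 23 known biallelic samples; the forest scored
the 56 DNA-monoallelic samples and nominated 23 of them (41%) as hidden
biallelic; those nominees' median progression-free survival (481 days) is
as poor as the known biallelic group's (577 days) and far below the
remaining monoallelic (1505 days) and wild-type (1155 days) groups — the
log-rank test between predicted biallelic and predicted monoallelic gives
χ² = 19.5, p ≈ 1 × 10⁻⁵. The `mechanisms.tsv` table explains each nominee
(cryptic-exon dPSI, retained-intron PSI, isoform imbalance, low
expression, splice-site VAF).

Every stage is also available as a library function
(`tp53tx.genomic.classify_tp53_status`, `tp53tx.model.train_signature_model`,
`tp53tx.splicing.assign_mechanism`, `tp53tx.survival.logrank_test`, …) and
as an individual subcommand (`call-status`, `de`, `train`, `predict`,
`splice`, `surv`).

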