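"""Seeded synthetic multiple-myeloma cohorts with planted TP53 biology.

The study data this pipeline targets (bulk RNA-seq plus DNA annotations of
newly diagnosed myeloma) are controlled-access, so every downstream stage is
exercised on generated cohorts carrying the same statistical structure:

* DNA-level TP53 genotypes at realistic prevalences (~3.6% biallelic,
  ~9.8% monoallelic, rest wild-type), written as mutation / segment / BAF
  tables that the rule-based status caller can consume.
* A planted multi-gene expression signature (half up, half down) in
  biallelic samples — and in "cryptic" biallelic samples hiding inside the
  monoallelic group, whose second hit is transcriptomic (cryptic-exon
  inclusion, intron retention, splice-site mutation, or low residual
  expression) rather than genomic.
* Splicing event counts (intron + junction reads) whose expected
  percent-spliced-in matches the planted PSI, transcript-class TPMs with a
  beta/gamma-over-alpha imbalance in cryptic-exon samples, and
  group-differential survival times.

Ground truth (true status + planted mechanism) ships with every bundle.
All randomness flows through one ``numpy.random.Generator`` seeded from the
config, so a fixed config yields byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic import TP53_INTERVAL_HG38

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "CohortConfigError",
    "generate_cohort",
    "simulate_splicing_counts",
    "simulate_survival_times",
    "CRYPTIC_EXON_EVENT",
    "RETAINED_INTRON_EVENT",
]

CRYPTIC_EXON_EVENT = "TP53_cryptic_exon_9_10"
RETAINED_INTRON_EVENT = "TP53_retained_intron_9"

BIALLELIC_MECHANISMS = ("mutation+deletion", "deep_deletion", "mutation+LOH")
CRYPTIC_MECHANISMS = (
    "cryptic_exon+LOH",
    "cryptic_exon+deletion",
    "low_expression+deletion",
    "retained_intron",
    "splice_site_mutation",
)

#: transcript_id -> (length class, C-terminal class) mirroring the p53
#: isoform families: full-length (TA) vs N-terminal truncations, and
#: alpha vs the cryptic-exon-switched beta/gamma C-termini.
DEFAULT_TRANSCRIPT_CLASS_MAP = pd.DataFrame(
    [
        ("TP53_TA_alpha", "TA", "alpha"),
        ("TP53_TA_beta", "TA", "beta"),
        ("TP53_TA_gamma", "TA", "gamma"),
        ("TP53_d133_alpha", "d133", "alpha"),
        ("TP53_d40_alpha", "d40", "alpha"),
    ],
    columns=["transcript_id", "length_class", "cterm_class"],
)


class CohortConfigError(ValueError):
    """Raised for an invalid cohort configuration."""


def _default_medians() -> dict[str, float]:
    # Progression-free survival medians (days) per group; the ordering
    # (biallelic worst, monoallelic/WT similar) mirrors the clinical picture
    # the classifier is meant to stratify.
    return {
        "biallelic": 478.0,
        "cryptic_biallelic": 623.0,
        "monoallelic": 1832.0,
        "WT": 1176.0,
    }


@dataclass
class CohortConfig:
    """Conditions for one synthetic cohort.

    Defaults reproduce the study-scale setting: 634 samples, 3.6%/9.8%
    biallelic/monoallelic prevalence, 42% of monoallelic samples hiding a
    transcriptomic second hit, a 16-gene signature with |log2 effect| in
    [1, 3] on the Log2(TPM+1) scale, and group-differential survival.
    """

    n_samples: int = 634
    prevalence_biallelic: float = 0.036
    prevalence_monoallelic: float = 0.098
    frac_cryptic_biallelic_among_mono: float = 0.42
    n_signature_genes: int = 16
    n_background_genes: int = 500
    #: per-gene signed log2 effects; None -> magnitudes drawn U(1, 3) with
    #: alternating signs (half up, half down) from the seeded generator.
    signature_log2_effect: np.ndarray | None = None
    expression_noise_sd: float = 0.5
    splicing_baseline_psi: float = 0.02
    splicing_planted_psi: float = 0.6
    mean_depth: float = 200.0
    survival_median_days_by_group: Mapping[str, float] = field(
        default_factory=_default_medians
    )
    os_median_multiplier: float = 2.3
    censor_rate: float = 0.3
    n_normals: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 10:
            raise CohortConfigError("n_samples must be >= 10")
        fracs = {
            "prevalence_biallelic": self.prevalence_biallelic,
            "prevalence_monoallelic": self.prevalence_monoallelic,
            "frac_cryptic_biallelic_among_mono": self.frac_cryptic_biallelic_among_mono,
            "censor_rate": self.censor_rate,
            "splicing_baseline_psi": self.splicing_baseline_psi,
            "splicing_planted_psi": self.splicing_planted_psi,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise CohortConfigError(f"{name} must be in [0, 1], got {value}")
        if self.prevalence_biallelic + self.prevalence_monoallelic > 1.0:
            raise CohortConfigError("prevalences sum to more than 1")
        if self.signature_log2_effect is not None:
            eff = np.asarray(self.signature_log2_effect, dtype=float)
            if eff.shape != (self.n_signature_genes,):
                raise CohortConfigError(
                    "signature_log2_effect length must equal n_signature_genes"
                )
        if self.mean_depth <= 0:
            raise CohortConfigError("mean_depth must be positive")
        if self.expression_noise_sd < 0:
            raise CohortConfigError("expression_noise_sd must be >= 0")
        for group, med in self.survival_median_days_by_group.items():
            if med <= 0:
                raise CohortConfigError(f"median for group {group!r} must be > 0")


@dataclass
class CohortBundle:
    """All tables for one cohort, plus ground truth (synthetic only)."""

    mutations: pd.DataFrame       # sample_id, gene, chrom, pos, ref, alt, consequence, vaf
    segments: pd.DataFrame        # sample_id, chrom, start, end, log2fc
    baf: pd.DataFrame             # sample_id, folded_baf
    expression: pd.DataFrame      # genes x tumor samples, TPM
    normal_expression: pd.DataFrame  # genes x normal samples, TPM
    splicing: pd.DataFrame        # sample_id, event_id, event_class, intron_reads, junction_reads
    transcript_tpm: pd.DataFrame  # transcripts x samples, TPM
    transcript_class_map: pd.DataFrame
    clinical: pd.DataFrame        # sample_id, group, progression_day, death_day, followup_day, abnormality_day
    ground_truth: pd.DataFrame    # sample_id, true_status, planted_mechanism
    normal_ids: list[str]
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ground_truth["sample_id"])


def simulate_splicing_counts(
    psi_target: float, mean_depth: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (intron_reads, junction_reads) for one splicing event.

    Total depth is Poisson(mean_depth); the inclusion split is binomial, so
    the expected percent-spliced-in equals ``psi_target`` exactly.
    """
    if not 0.0 <= psi_target <= 1.0:
        raise ValueError(f"psi_target must be in [0, 1], got {psi_target}")
    if mean_depth <= 0:
        raise ValueError(f"mean_depth must be positive, got {mean_depth}")
    total = int(rng.poisson(mean_depth))
    intron = int(rng.binomial(total, psi_target)) if total > 0 else 0
    return intron, total - intron


def simulate_survival_times(
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    size: int = 1,
    median: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time_days, event_flag) for ``size`` subjects of one group.

    Times are exponential with the group's configured median
    (rate = ln 2 / median). With probability ``censor_rate`` a subject gets
    an independent uniform censoring time on [0, 2 x max configured median].
    """
    if median is None:
        if group not in config.survival_median_days_by_group:
            raise ValueError(f"no survival median configured for group {group!r}")
        median = float(config.survival_median_days_by_group[group])
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    rate = np.log(2.0) / median
    times = rng.exponential(1.0 / rate, size=size)
    cmax = 2.0 * max(config.survival_median_days_by_group.values())
    censored = rng.random(size) < config.censor_rate
    ctimes = np.where(censored, rng.uniform(0.0, cmax, size=size), np.inf)
    event = (times <= ctimes).astype(int)
    observed = np.minimum(times, ctimes)
    return observed, event


# --------------------------------------------------------------------------
# cohort generation

def _assign_statuses(config: CohortConfig, rng: np.random.Generator):
    n = config.n_samples
    u = rng.random(n)
    status = np.full(n, "WT", dtype=object)
    status[u < config.prevalence_biallelic] = "biallelic"
    mono = (u >= config.prevalence_biallelic) & (
        u < config.prevalence_biallelic + config.prevalence_monoallelic
    )
    status[mono] = "monoallelic"
    cryptic = mono & (rng.random(n) < config.frac_cryptic_biallelic_among_mono)
    status[cryptic] = "cryptic_biallelic"

    mechanism = np.full(n, "none", dtype=object)
    for i in np.flatnonzero(status == "biallelic"):
        mechanism[i] = rng.choice(BIALLELIC_MECHANISMS, p=[0.5, 0.2, 0.3])
    for i in np.flatnonzero(status == "cryptic_biallelic"):
        mechanism[i] = rng.choice(CRYPTIC_MECHANISMS, p=[0.3, 0.2, 0.2, 0.15, 0.15])
    # plain monoallelic samples still need one DNA hit; store it alongside
    dna_hit = np.full(n, "none", dtype=object)
    for i in np.flatnonzero(status == "monoallelic"):
        dna_hit[i] = rng.choice(["mutation", "deletion", "LOH"], p=[0.5, 0.3, 0.2])
    return status, mechanism, dna_hit


def _dna_tables(sample_ids, status, mechanism, dna_hit, rng):
    chrom, gstart, gend = TP53_INTERVAL_HG38
    bases = np.array(["A", "C", "G", "T"])
    mut_rows, seg_rows, baf_rows = [], [], []

    def add_mutation(sid, consequence, vaf):
        pos = int(rng.integers(gstart, gend + 1))
        ref, alt = rng.choice(bases, size=2, replace=False)
        mut_rows.append(
            dict(sample_id=sid, gene="TP53", chrom=chrom, pos=pos,
                 ref=ref, alt=alt, consequence=consequence,
                 vaf=round(float(vaf), 4))
        )

    for sid, st, mech, hit in zip(sample_ids, status, mechanism, dna_hit):
        log2fc = rng.uniform(-0.1, 0.1)       # neutral default
        folded_baf = rng.uniform(0.35, 0.5)   # balanced default
        if st == "biallelic":
            if mech == "deep_deletion":
                log2fc = rng.uniform(-3.5, -2.1)
                folded_baf = rng.uniform(0.0, 0.1)
            elif mech == "mutation+deletion":
                log2fc = rng.uniform(-1.8, -0.3)
                folded_baf = rng.uniform(0.26, 0.45)
                add_mutation(sid, rng.choice(["missense", "nonsense", "frameshift"]),
                             rng.uniform(0.5, 0.9))
            else:  # mutation+LOH, copy-neutral
                folded_baf = rng.uniform(0.02, 0.2)
                add_mutation(sid, rng.choice(["missense", "nonsense", "frameshift"]),
                             rng.uniform(0.6, 0.9))
        elif st == "cryptic_biallelic":
            if mech == "cryptic_exon+LOH":
                folded_baf = rng.uniform(0.02, 0.2)
            elif mech in ("cryptic_exon+deletion", "low_expression+deletion",
                          "retained_intron"):
                log2fc = rng.uniform(-1.8, -0.3)
                folded_baf = rng.uniform(0.26, 0.45)
            else:  # splice_site_mutation: VAF high enough to drive splicing
                add_mutation(sid, "splice_site", rng.uniform(0.25, 0.85))
        elif st == "monoallelic":
            if hit == "mutation":
                add_mutation(sid, rng.choice(["missense", "nonsense", "frameshift"]),
                             rng.uniform(0.15, 0.45))
            elif hit == "deletion":
                log2fc = rng.uniform(-1.8, -0.3)
                folded_baf = rng.uniform(0.26, 0.45)
            else:
                folded_baf = rng.uniform(0.02, 0.2)
        seg_rows.append(
            dict(sample_id=sid, chrom=chrom,
                 start=gstart - 500_000, end=gend + 500_000,
                 log2fc=round(float(log2fc), 4))
        )
        baf_rows.append(dict(sample_id=sid, folded_baf=round(float(folded_baf), 4)))

    mut_cols = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "consequence", "vaf"]
    mutations = pd.DataFrame(mut_rows, columns=mut_cols)
    return mutations, pd.DataFrame(seg_rows), pd.DataFrame(baf_rows)


def _expression_tables(config, sample_ids, status, mechanism, rng):
    n_sig, n_bg = config.n_signature_genes, config.n_background_genes
    sig_genes = [f"SIG{i + 1:03d}" for i in range(n_sig)]
    bg_genes = [f"BG{i + 1:04d}" for i in range(n_bg)]
    genes = sig_genes + bg_genes + ["TP53"]

    if config.signature_log2_effect is not None:
        effects = np.asarray(config.signature_log2_effect, dtype=float)
    else:
        mags = rng.uniform(1.0, 3.0, size=n_sig)
        signs = np.where(np.arange(n_sig) % 2 == 0, 1.0, -1.0)
        effects = mags * signs

    baseline = rng.uniform(3.0, 8.0, size=len(genes))
    baseline[-1] = 5.0  # TP53 gene-level expression
    affected = np.isin(status, ["biallelic", "cryptic_biallelic"]).astype(float)

    n = len(sample_ids)
    log2m = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(len(genes), n)
    )
    log2m[:n_sig, :] += effects[:, None] * affected[None, :]

    # TP53 itself drops where the planted mechanism removes its output
    tp53_row = len(genes) - 1
    for j, (st, mech) in enumerate(zip(status, mechanism)):
        if mech == "low_expression+deletion":
            log2m[tp53_row, j] = rng.uniform(0.4, 0.9)
        elif mech == "deep_deletion":
            log2m[tp53_row, j] = rng.uniform(0.2, 1.0)

    tpm = np.maximum(np.exp2(log2m) - 1.0, 0.0)
    expression = pd.DataFrame(tpm, index=pd.Index(genes, name="gene"),
                              columns=sample_ids)

    normal_ids = [f"NORMAL_{i + 1}" for i in range(config.n_normals)]
    nlog2 = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, size=(len(genes), config.n_normals)
    )
    normal_expression = pd.DataFrame(
        np.maximum(np.exp2(nlog2) - 1.0, 0.0),
        index=pd.Index(genes, name="gene"), columns=normal_ids,
    )
    return expression, normal_expression, normal_ids, effects


def _splicing_table(config, sample_ids, mechanism, normal_ids, rng):
    rows = []
    events = [
        (CRYPTIC_EXON_EVENT, "cryptic_exon"),
        (RETAINED_INTRON_EVENT, "retained_intron"),
    ]
    base, planted = config.splicing_baseline_psi, config.splicing_planted_psi
    for sid, mech in list(zip(sample_ids, mechanism)) + [
        (nid, "none") for nid in normal_ids
    ]:
        for event_id, event_class in events:
            psi = base
            if event_class == "cryptic_exon" and mech.startswith("cryptic_exon"):
                psi = planted
            if event_class == "retained_intron" and mech in (
                "retained_intron", "splice_site_mutation"
            ):
                psi = planted
            intron, junction = simulate_splicing_counts(psi, config.mean_depth, rng)
            rows.append(
                dict(sample_id=sid, event_id=event_id, event_class=event_class,
                     intron_reads=intron, junction_reads=junction)
            )
    return pd.DataFrame(rows)


def _transcript_table(sample_ids, mechanism, normal_ids, rng):
    tids = list(DEFAULT_TRANSCRIPT_CLASS_MAP["transcript_id"])
    cols = {}
    for sid, mech in list(zip(sample_ids, mechanism)) + [
        (nid, "none") for nid in normal_ids
    ]:
        if mech.startswith("cryptic_exon"):
            # beta/gamma dominate over alpha: the high-risk imbalance
            vals = [rng.uniform(1.0, 3.0), rng.uniform(2.0, 5.0),
                    rng.uniform(1.0, 3.0), rng.uniform(0.2, 1.0),
                    rng.uniform(0.2, 1.0)]
        elif mech == "low_expression+deletion":
            vals = [rng.uniform(0.2, 1.0), rng.uniform(0.0, 0.1),
                    rng.uniform(0.0, 0.1), rng.uniform(0.0, 0.2),
                    rng.uniform(0.0, 0.2)]
        else:
            vals = [rng.uniform(8.0, 15.0), rng.uniform(0.1, 0.8),
                    rng.uniform(0.1, 0.8), rng.uniform(0.5, 2.0),
                    rng.uniform(0.5, 2.0)]
        cols[sid] = np.round(vals, 4)
    return pd.DataFrame(cols, index=pd.Index(tids, name="transcript_id"))


def _clinical_table(config, sample_ids, status, rng):
    rows = []
    medians = config.survival_median_days_by_group
    cmax = 2.0 * config.os_median_multiplier * max(medians.values())
    for sid, st in zip(sample_ids, status):
        med_pfs = float(medians[st])
        med_os = config.os_median_multiplier * med_pfs
        t_prog = rng.exponential(med_pfs / np.log(2.0))
        t_death = t_prog + rng.exponential(
            max(med_os - med_pfs, 0.1 * med_os) / np.log(2.0)
        )
        ctime = (
            rng.uniform(0.0, cmax) if rng.random() < config.censor_rate else np.inf
        )
        followup = min(t_death, ctime)
        death_day = t_death if t_death <= ctime else np.nan
        progression_day = t_prog if t_prog <= followup else np.nan
        if st == "biallelic":
            abnormality_day = 0.0
        elif st == "cryptic_biallelic":
            abnormality_day = min(0.5 * t_prog, followup)
        else:
            abnormality_day = np.nan
        rows.append(
            dict(sample_id=sid, group=st,
                 progression_day=_r(progression_day), death_day=_r(death_day),
                 followup_day=_r(followup), abnormality_day=_r(abnormality_day))
        )
    return pd.DataFrame(rows)


def _r(x: float) -> float:
    return float(np.round(x, 2)) if np.isfinite(x) else np.nan


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate one full synthetic cohort from a validated config.

    Biallelic and cryptic-biallelic samples carry the planted signature
    shift on every signature gene; DNA tables are consistent with the
    ground-truth status (cryptic-biallelic samples carry exactly one
    DNA-level hit, so the rule-based caller sees them as monoallelic).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"SYN_{i + 1:04d}" for i in range(config.n_samples)]
    status, mechanism, dna_hit = _assign_statuses(config, rng)
    mutations, segments, baf = _dna_tables(sample_ids, status, mechanism, dna_hit, rng)
    expression, normal_expression, normal_ids, effects = _expression_tables(
        config, sample_ids, status, mechanism, rng
    )
    splicing = _splicing_table(config, sample_ids, mechanism, normal_ids, rng)
    transcript_tpm = _transcript_table(sample_ids, mechanism, normal_ids, rng)
    clinical = _clinical_table(config, sample_ids, status, rng)

    ground_truth = pd.DataFrame(
        dict(sample_id=sample_ids, true_status=status, planted_mechanism=mechanism)
    )
    resolved = replace(config, signature_log2_effect=effects)
    return CohortBundle(
        mutations=mutations, segments=segments, baf=baf,
        expression=expression, normal_expression=normal_expression,
        splicing=splicing, transcript_tpm=transcript_tpm,
        transcript_class_map=DEFAULT_TRANSCRIPT_CLASS_MAP.copy(),
        clinical=clinical, ground_truth=ground_truth,
        normal_ids=normal_ids, config=resolved,
    )
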