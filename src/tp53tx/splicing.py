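"""Aberrant TP53 splicing, isoform imbalance, and mechanism assignment.

For a predicted-biallelic but DNA-monoallelic sample, the "second hit" must
be transcriptomic. This module quantifies the candidates:

* percent spliced in, PSI = intron reads / (junction reads + intron reads),
  per event per sample, and dPSI = mean PSI(normals) - PSI(tumor), so a
  splicing gain in the tumor gives a negative dPSI;
* transcript-class quantification over {alpha, beta, gamma} C-termini x
  {TA, d40, d133, d160} N-terminal lengths, and the high-risk imbalance
  ratio (TA-beta + TA-gamma) / TA-alpha;
* Spearman association of splice-site-mutation VAF with event PSI, and a
  ranking of candidate splicing regulators by |Spearman rho| between their
  expression and per-sample dPSI;
* a rule-based mechanism call per sample (cryptic-exon inclusion, retained
  intron, low total expression, splice-site-mutation-driven, or
  unexplained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MechanismThresholds",
    "MechanismCall",
    "compute_psi",
    "compute_psi_table",
    "compute_dpsi",
    "classify_transcript",
    "isoform_imbalance_ratio",
    "rank_splicing_regulators",
    "vaf_splicing_association",
    "assign_mechanism",
]


@dataclass(frozen=True)
class MechanismThresholds:
    """Decision thresholds for mechanism assignment.

    Defaults bracket the worked values seen in practice (cryptic-exon
    dPSI of -0.54 and -0.29; a low-expression case at Log2(TPM+1) = 1.01
    with log2FC -0.89 vs normal; driver splice-site VAFs 0.26-0.83 against
    an average 0.1 for non-drivers).
    """

    dpsi_min: float = 0.2          # |dPSI| needed to call cryptic-exon inclusion
    psi_min: float = 0.2           # tumor PSI needed to call a retained intron
    normal_psi_max: float = 0.05   # "normals ~ 0" ceiling for novel events
    expr_floor: float = 1.0        # Log2(TPM+1) at/below which expression is "low"
    log2fc_floor: float = -0.8     # log2FC vs normal mean at/below which it is "low"
    vaf_floor: float = 0.2         # splice-site VAF needed to drive splicing


@dataclass
class MechanismCall:
    """Mechanism labels and supporting values for one sample."""

    sample_id: str
    labels: set[str]
    dpsi_cryptic: float | None = None
    retained_psi: float | None = None
    imbalance_ratio: float | None = None
    tp53_log2: float | None = None
    tp53_log2fc_vs_normal: float | None = None
    splice_site_vaf: float | None = None
    missing_layers: tuple[str, ...] = ()


def compute_psi(intron_reads: int, junction_reads: int) -> float:
    """PSI = intron / (junction + intron); NaN when both counts are zero."""
    if intron_reads < 0 or junction_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = intron_reads + junction_reads
    if total == 0:
        return float("nan")
    return intron_reads / total


def compute_psi_table(splicing: pd.DataFrame) -> pd.DataFrame:
    """Add a ``psi`` column to an event-count table (NaN where depth is 0)."""
    if (splicing[["intron_reads", "junction_reads"]] < 0).any().any():
        raise ValueError("read counts must be non-negative")
    out = splicing.copy()
    total = out["intron_reads"] + out["junction_reads"]
    with np.errstate(invalid="ignore"):
        out["psi"] = np.where(total > 0, out["intron_reads"] / total, np.nan)
    return out


def compute_dpsi(
    psi_normals: Sequence[float], psi_tumor: float | Sequence[float]
) -> float:
    """dPSI = mean PSI over normals minus (mean) tumor PSI.

    More inclusion in the tumor gives a negative dPSI. Undefined (NaN)
    PSIs are dropped; a side with no defined PSI is an error.
    """
    normals = np.asarray(psi_normals, dtype=float)
    normals = normals[~np.isnan(normals)]
    tumor = np.atleast_1d(np.asarray(psi_tumor, dtype=float))
    tumor = tumor[~np.isnan(tumor)]
    if normals.size == 0 or tumor.size == 0:
        raise ValueError("each side needs at least one defined PSI")
    return float(normals.mean() - tumor.mean())


def classify_transcript(
    transcript_id: str,
    class_map: pd.DataFrame | Mapping[str, tuple[str, str]],
) -> tuple[str, str]:
    """Look up a transcript's (length_class, cterm_class).

    The class map mirrors the p53 transcript-variant table: the C-terminal
    type records cryptic-exon status (none -> alpha, cryptic form 1 ->
    beta, form 2 -> gamma) and the length class records the start site
    (TA, d40, d133, d160). Unknown transcripts come back as
    ("unclassified", "unclassified").
    """
    if isinstance(class_map, pd.DataFrame):
        lookup = {
            row.transcript_id: (row.length_class, row.cterm_class)
            for row in class_map.itertuples()
        }
    else:
        lookup = dict(class_map)
    return lookup.get(transcript_id, ("unclassified", "unclassified"))


def isoform_imbalance_ratio(
    class_tpm: Mapping[tuple[str, str], float] | pd.Series,
) -> float:
    """High-risk imbalance: (TA-beta + TA-gamma) / TA-alpha.

    Keys are (length_class, cterm_class). TA-alpha of zero with a positive
    numerator flags infinity; all-zero classes are undefined (NaN).
    """
    get = class_tpm.get if hasattr(class_tpm, "get") else class_tpm.__getitem__
    ta_alpha = float(get(("TA", "alpha"), 0.0))
    ta_beta = float(get(("TA", "beta"), 0.0))
    ta_gamma = float(get(("TA", "gamma"), 0.0))
    if min(ta_alpha, ta_beta, ta_gamma) < 0:
        raise ValueError("class TPMs must be non-negative")
    numerator = ta_beta + ta_gamma
    if ta_alpha == 0.0:
        return float("nan") if numerator == 0.0 else float("inf")
    return numerator / ta_alpha


def class_tpm_per_sample(
    transcript_tpm: pd.DataFrame, class_map: pd.DataFrame
) -> pd.DataFrame:
    """Sum transcript TPM into (length_class, cterm_class) rows per sample."""
    classes = transcript_tpm.index.map(
        lambda t: classify_transcript(t, class_map)
    )
    grouped = transcript_tpm.groupby(
        [pd.Index([c[0] for c in classes]), pd.Index([c[1] for c in classes])]
    ).sum()
    grouped.index.names = ["length_class", "cterm_class"]
    return grouped


def rank_splicing_regulators(
    log_expr: pd.DataFrame, dpsi_by_sample: pd.Series
) -> pd.DataFrame:
    """Spearman rho of each gene's expression against per-sample dPSI.

    ``log_expr`` is genes x samples; samples are aligned on the dPSI index.
    Genes come back sorted by |rho| descending with a 1-based rank column.
    Ties in expression get average ranks (scipy convention).
    """
    dpsi = dpsi_by_sample.dropna()
    if dpsi.size < 5:
        raise ValueError("need at least 5 samples with defined dPSI")
    if dpsi.nunique() == 1:
        raise ValueError("dPSI vector is constant; correlation undefined")
    aligned = log_expr[dpsi.index].to_numpy(dtype=float)
    rho, _ = stats.spearmanr(aligned.T, dpsi.to_numpy())
    # spearmanr on a 2-D input returns the full correlation matrix
    rho = np.atleast_2d(rho)[:-1, -1] if aligned.shape[0] > 1 else np.array(
        [stats.spearmanr(aligned[0], dpsi.to_numpy()).statistic]
    )
    out = pd.DataFrame({"gene": log_expr.index, "rho": rho})
    out = out.sort_values("rho", key=np.abs, ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def vaf_splicing_association(
    vafs: Sequence[float],
    psi_values: Sequence[float],
    vaf_floor: float = 0.2,
    psi_min: float = 0.2,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of splice-site-mutation VAF with event PSI.

    Returns (rho, p, table). The per-sample table flags cases where a low
    VAF plausibly explains the absence of aberrant splicing
    (VAF < vaf_floor and PSI < psi_min). A constant PSI vector yields
    rho = NaN (correlation undefined under total ties).
    """
    v = np.asarray(vafs, dtype=float)
    p = np.asarray(psi_values, dtype=float)
    if v.size != p.size:
        raise ValueError("VAF and PSI vectors must be paired")
    if v.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(p).size == 1 or np.unique(v).size == 1:
        rho, pval = float("nan"), float("nan")
    else:
        res = stats.spearmanr(v, p)
        rho, pval = float(res.statistic), float(res.pvalue)
    table = pd.DataFrame(
        {
            "vaf": v,
            "psi": p,
            "low_vaf_no_splicing": (v < vaf_floor) & (p < psi_min),
        }
    )
    return rho, pval, table


def assign_mechanism(
    sample_id: str,
    *,
    dpsi_cryptic: float | None = None,
    retained_psi: float | None = None,
    retained_psi_normal_mean: float | None = None,
    tp53_log2: float | None = None,
    tp53_log2fc_vs_normal: float | None = None,
    splice_site_vaf: float | None = None,
    imbalance_ratio: float | None = None,
    thresholds: MechanismThresholds = MechanismThresholds(),
) -> MechanismCall:
    """Rule-based transcriptomic second-hit call for one sample.

    Intended for samples the model predicts biallelic despite a
    DNA-monoallelic genotype. Rules (labels accumulate, not exclusive):

    * cryptic_exon_inclusion — cryptic-exon dPSI <= -dpsi_min;
    * retained_intron — a novel retained-intron event with tumor PSI >=
      psi_min while normals sit at or below normal_psi_max;
    * low_total_expression — gene Log2(TPM+1) <= expr_floor, or log2FC vs
      the normal mean <= log2fc_floor;
    * splice_site_mutation_driven — a splice-site mutation with VAF >=
      vaf_floor co-occurring with either splicing label;
    * unexplained — none of the above.

    Layers passed as None are recorded in ``missing_layers`` and their
    rules skipped (a partial call, not an error).
    """
    t = thresholds
    labels: set[str] = set()
    missing = []

    if dpsi_cryptic is None:
        missing.append("cryptic_exon_dpsi")
    elif not math.isnan(dpsi_cryptic) and dpsi_cryptic <= -t.dpsi_min:
        labels.add("cryptic_exon_inclusion")

    if retained_psi is None:
        missing.append("retained_intron_psi")
    else:
        normal_ok = (
            retained_psi_normal_mean is None
            or retained_psi_normal_mean <= t.normal_psi_max
        )
        if not math.isnan(retained_psi) and retained_psi >= t.psi_min and normal_ok:
            labels.add("retained_intron")

    if tp53_log2 is None and tp53_log2fc_vs_normal is None:
        missing.append("gene_expression")
    else:
        low_abs = tp53_log2 is not None and tp53_log2 <= t.expr_floor
        low_rel = (
            tp53_log2fc_vs_normal is not None
            and tp53_log2fc_vs_normal <= t.log2fc_floor
        )
        if low_abs or low_rel:
            labels.add("low_total_expression")

    has_splicing = labels & {"cryptic_exon_inclusion", "retained_intron"}
    if splice_site_vaf is not None and splice_site_vaf >= t.vaf_floor and has_splicing:
        labels.add("splice_site_mutation_driven")

    if not labels:
        labels.add("unexplained")

    return MechanismCall(
        sample_id=sample_id,
        labels=labels,
        dpsi_cryptic=dpsi_cryptic,
        retained_psi=retained_psi,
        imbalance_ratio=imbalance_ratio,
        tp53_log2=tp53_log2,
        tp53_log2fc_vs_normal=tp53_log2fc_vs_normal,
        splice_site_vaf=splice_site_vaf,
        missing_layers=tuple(missing),
    )
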