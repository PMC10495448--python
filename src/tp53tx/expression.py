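"""Expression transform and differential-expression signature derivation.

Expression arrives as TPM; all testing happens on the Log2(TPM+1) scale.
Differential expression between biallelic and wild-type samples uses a
per-gene Welch two-sample t-test with Benjamini-Hochberg FDR control.
Significant genes must clear three filters simultaneously: FDR < 0.05,
linear fold-change > 1.4 or < 0.71, and mean Log2(TPM+1) > 1 in at least
one group. The significant set is then tiered by fold-change (FC1.5 / FC2 /
FC2.5 / FC3) to form nested candidate feature sets for the classifier.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_transform",
    "inverse_log_transform",
    "differential_expression",
    "select_signature_set",
    "FC_TIERS",
    "FDR_CUTOFF",
    "FC_UP_CUTOFF",
    "FC_DOWN_CUTOFF",
    "EXPRESSION_FLOOR",
]

FC_TIERS = (1.5, 2.0, 2.5, 3.0)
FDR_CUTOFF = 0.05
FC_UP_CUTOFF = 1.4
FC_DOWN_CUTOFF = 0.71
EXPRESSION_FLOOR = 1.0  # on the Log2(TPM+1) scale, group mean


def log_transform(tpm: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise Log2(TPM + 1); rejects negative entries."""
    values = np.asarray(tpm, dtype=float)
    if (values < 0).any():
        raise ValueError("TPM matrix contains negative entries")
    out = np.log2(values + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    return out


def inverse_log_transform(transformed):
    """Invert Log2(TPM+1), recovering TPM."""
    values = np.asarray(transformed, dtype=float)
    out = np.exp2(values) - 1.0
    if isinstance(transformed, pd.DataFrame):
        return pd.DataFrame(out, index=transformed.index, columns=transformed.columns)
    return out


def differential_expression(
    tpm: pd.DataFrame,
    group_biallelic: Sequence[str],
    group_wt: Sequence[str],
) -> pd.DataFrame:
    """Per-gene biallelic-vs-WT differential expression.

    Returns one row per gene with columns gene / fold_change / p_value /
    fdr / mean_log2_biallelic / mean_log2_wt / significant. Fold-change is
    computed on the linear scale as (mean TPM_bi + 1) / (mean TPM_wt + 1),
    matching the +1 pseudocount of the transform; the test runs on
    transformed values. Genes with zero variance in both groups get p = 1.
    """
    ga, gb = list(group_biallelic), list(group_wt)
    if set(ga) & set(gb):
        raise ValueError("biallelic and WT groups overlap")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 samples")

    tpm_a = tpm[ga].to_numpy(dtype=float)
    tpm_b = tpm[gb].to_numpy(dtype=float)
    log_a = np.log2(tpm_a + 1.0)
    log_b = np.log2(tpm_b + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    # zero variance in both groups -> undefined Welch statistic -> null
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    fc = (tpm_a.mean(axis=1) + 1.0) / (tpm_b.mean(axis=1) + 1.0)
    mean_a = log_a.mean(axis=1)
    mean_b = log_b.mean(axis=1)

    significant = (
        (fdr < FDR_CUTOFF)
        & ((fc > FC_UP_CUTOFF) | (fc < FC_DOWN_CUTOFF))
        & (np.maximum(mean_a, mean_b) > EXPRESSION_FLOOR)
    )
    return pd.DataFrame(
        {
            "gene": tpm.index,
            "fold_change": fc,
            "p_value": pvals,
            "fdr": fdr,
            "mean_log2_biallelic": mean_a,
            "mean_log2_wt": mean_b,
            "significant": significant,
        }
    ).reset_index(drop=True)


def select_signature_set(degs: pd.DataFrame, tier: float) -> list[str]:
    """Genes from the significant DEG set with FC > tier or FC < 1/tier.

    Tiers are nested: FC3 is a subset of FC2.5 of FC2 of FC1.5.
    """
    if tier not in FC_TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {FC_TIERS}")
    sig = degs[degs["significant"]]
    mask = (sig["fold_change"] > tier) | (sig["fold_change"] < 1.0 / tier)
    return sig.loc[mask, "gene"].tolist()
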