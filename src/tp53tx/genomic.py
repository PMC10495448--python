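"""Rule-based TP53 DNA-level status calling.

Classifies each sample as biallelic / monoallelic / wild-type from three
evidence layers: somatic mutations (with VAF and consequence class),
copy-number segments (log2 fold-change), and folded B-allele frequency.

Biallelic inactivation means both gene copies are lost: a deep deletion, a
mutation combined with a single-copy deletion, or a mutation combined with
loss of heterozygosity (LOH). A single hit of any kind is monoallelic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TP53_INTERVAL_HG38",
    "ELIGIBLE_CONSEQUENCES",
    "TP53StatusCall",
    "fold_baf",
    "call_loh",
    "categorize_cnv",
    "gene_level_cnv",
    "classify_tp53_status",
    "call_cohort_status",
]

#: TP53 locus, hg38, 1-based inclusive (chrom, start, end).
TP53_INTERVAL_HG38 = ("chr17", 7668402, 7687550)

#: Mutation consequence classes that count as a functional hit.
ELIGIBLE_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site"}
)

#: LOH is called when folded BAF falls strictly below this value.
LOH_THRESHOLD = 0.25

CNV_CATEGORIES = ("amplification", "gain", "neutral", "deletion", "deep_deletion")


@dataclass(frozen=True)
class TP53StatusCall:
    """DNA-level TP53 status for one sample and the rule that triggered it."""

    sample_id: str
    status: str  # biallelic | monoallelic | WT
    cnv_category: str
    has_mutation: bool
    has_loh: bool
    evidence_rule: str  # deep_deletion | mutation+deletion | mutation+LOH |
    #                     mono_mutation | mono_deletion | mono_LOH | none


def fold_baf(raw_baf: float) -> float:
    """Fold a raw B-allele frequency in [0, 1] onto the [0, 0.5] scale.

    0.5 corresponds to balanced alleles; 0 to complete loss of
    heterozygosity.
    """
    if not 0.0 <= raw_baf <= 1.0:
        raise ValueError(f"raw BAF must be in [0, 1], got {raw_baf!r}")
    return min(raw_baf, 1.0 - raw_baf)


def call_loh(folded_baf: float) -> bool:
    """True iff folded BAF < 0.25 (strict inequality at the boundary)."""
    if not 0.0 <= folded_baf <= 0.5:
        raise ValueError(f"folded BAF must be in [0, 0.5], got {folded_baf!r}")
    return folded_baf < LOH_THRESHOLD


def categorize_cnv(log2fc: float) -> str:
    """Bin a copy-number log2 fold-change into a CNV category.

    >=0.8 amplification; [0.2, 0.8) gain; (-0.2, 0.2) neutral;
    [-2.0, -0.2] deletion; < -2.0 deep deletion.
    """
    if not np.isfinite(log2fc):
        raise ValueError(f"log2fc must be finite, got {log2fc!r}")
    if log2fc >= 0.8:
        return "amplification"
    if log2fc >= 0.2:
        return "gain"
    if log2fc > -0.2:
        return "neutral"
    if log2fc >= -2.0:
        return "deletion"
    return "deep_deletion"


def gene_level_cnv(
    segments: pd.DataFrame,
    gene_interval: tuple[str, int, int] = TP53_INTERVAL_HG38,
) -> float:
    """Collapse overlapping segments to a single gene-level log2 fold-change.

    ``segments`` needs columns chrom/start/end/log2fc (1-based inclusive,
    SEG convention). The segment with the largest overlap with the gene wins;
    overlap-length ties go to the more extreme \\|log2fc\\|. No overlap -> 0.0.
    """
    chrom, gstart, gend = gene_interval
    if gstart > gend:
        raise ValueError(f"malformed gene interval: start {gstart} > end {gend}")
    if segments.empty:
        return 0.0
    if (segments["start"] > segments["end"]).any():
        bad = segments[segments["start"] > segments["end"]].index[0]
        raise ValueError(f"malformed segment at row {bad}: start > end")
    on_chrom = segments[segments["chrom"] == chrom]
    best_fc = 0.0
    best_key = (0, 0.0)  # (overlap length, |log2fc|)
    for _, seg in on_chrom.iterrows():
        overlap = min(gend, int(seg["end"])) - max(gstart, int(seg["start"])) + 1
        if overlap <= 0:
            continue
        fc = float(seg["log2fc"])
        key = (overlap, abs(fc))
        if key > best_key:
            best_key = key
            best_fc = fc
    return best_fc


def classify_tp53_status(
    mutations: Iterable[str] | Sequence[str],
    cnv_category: str,
    has_loh: bool,
    sample_id: str = "",
) -> TP53StatusCall:
    """Apply the biallelic/monoallelic/WT decision rules for one sample.

    ``mutations`` is the sample's TP53 mutation consequence classes; only
    missense/nonsense/frameshift/splice_site count as hits (no VAF floor).

    Biallelic: deep deletion, or mutation plus deletion, or mutation plus
    LOH (first match wins, in that order). Monoallelic: any single hit —
    a mutation, a deletion/deep deletion, or LOH. Otherwise wild-type.
    Copy-number gain or amplification never contributes to allele loss.
    """
    if cnv_category not in CNV_CATEGORIES:
        raise ValueError(f"unknown CNV category {cnv_category!r}")
    has_mutation = any(c in ELIGIBLE_CONSEQUENCES for c in mutations)

    if cnv_category == "deep_deletion":
        status, rule = "biallelic", "deep_deletion"
    elif has_mutation and cnv_category == "deletion":
        status, rule = "biallelic", "mutation+deletion"
    elif has_mutation and has_loh:
        status, rule = "biallelic", "mutation+LOH"
    elif has_mutation:
        status, rule = "monoallelic", "mono_mutation"
    elif cnv_category == "deletion":
        status, rule = "monoallelic", "mono_deletion"
    elif has_loh:
        status, rule = "monoallelic", "mono_LOH"
    else:
        status, rule = "WT", "none"

    return TP53StatusCall(
        sample_id=sample_id,
        status=status,
        cnv_category=cnv_category,
        has_mutation=has_mutation,
        has_loh=has_loh,
        evidence_rule=rule,
    )


def call_cohort_status(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    baf: pd.DataFrame,
    sample_ids: Sequence[str],
    gene: str = "TP53",
    gene_interval: tuple[str, int, int] = TP53_INTERVAL_HG38,
) -> pd.DataFrame:
    """Run the status rules across a cohort and return one call per sample.

    Samples absent from a table contribute no evidence of that kind
    (neutral CNV, no mutation, balanced BAF).
    """
    mut_by_sample = {
        sid: grp["consequence"].tolist()
        for sid, grp in mutations[mutations["gene"] == gene].groupby("sample_id")
    }
    seg_by_sample = dict(tuple(segments.groupby("sample_id")))
    baf_by_sample = baf.set_index("sample_id")["folded_baf"].to_dict()

    rows = []
    for sid in sample_ids:
        segs = seg_by_sample.get(sid)
        log2fc = gene_level_cnv(segs, gene_interval) if segs is not None else 0.0
        call = classify_tp53_status(
            mut_by_sample.get(sid, []),
            categorize_cnv(log2fc),
            call_loh(baf_by_sample.get(sid, 0.5)),
            sample_id=sid,
        )
        rows.append(
            {
                "sample_id": sid,
                "status": call.status,
                "cnv_category": call.cnv_category,
                "has_mutation": call.has_mutation,
                "has_loh": call.has_loh,
                "evidence_rule": call.evidence_rule,
            }
        )
    return pd.DataFrame(rows)
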