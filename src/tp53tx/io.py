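"""Readers and writers for all pipeline tables (plain TSV + JSON).

Every reader validates schema and value ranges and reports the offending
file, line, and column; writers emit a stable column order so reruns are
byte-identical. A whole cohort round-trips through :func:`write_bundle` /
:func:`read_bundle`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortBundle, CohortConfig

__all__ = [
    "SchemaError",
    "read_mutations",
    "read_segments",
    "read_baf",
    "read_expression",
    "read_splicing",
    "read_clinical",
    "write_bundle",
    "read_bundle",
]

MUTATION_COLUMNS = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "consequence", "vaf"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "log2fc"]
BAF_COLUMNS = ["sample_id", "folded_baf"]
SPLICING_COLUMNS = ["sample_id", "event_id", "event_class", "intron_reads", "junction_reads"]
CLINICAL_COLUMNS = [
    "sample_id", "group", "progression_day", "death_day", "followup_day", "abnormality_day",
]


class SchemaError(ValueError):
    """A table failed validation; message names file, line, and column."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_range(df: pd.DataFrame, column: str, lo: float, hi: float, path) -> None:
    bad = df.index[(df[column] < lo) | (df[column] > hi)]
    if len(bad):
        # +2: one for the header, one for 1-based line numbers
        raise SchemaError(
            f"{path}, line {bad[0] + 2}, column {column!r}: "
            f"value {df.loc[bad[0], column]!r} outside [{lo}, {hi}]"
        )


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, MUTATION_COLUMNS, path)
    _check_range(df, "vaf", 0.0, 1.0, path)
    if (df["pos"] <= 0).any():
        bad = df.index[df["pos"] <= 0][0]
        raise SchemaError(f"{path}, line {bad + 2}, column 'pos': must be positive")
    return df[MUTATION_COLUMNS]


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, SEGMENT_COLUMNS, path)
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise SchemaError(f"{path}, line {bad[0] + 2}: start > end")
    return df[SEGMENT_COLUMNS]


def read_baf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, BAF_COLUMNS, path)
    _check_range(df, "folded_baf", 0.0, 0.5, path)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    return df[BAF_COLUMNS]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise SchemaError(f"{path}: negative TPM values")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene {dup!r}")
    return df


def read_splicing(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, SPLICING_COLUMNS, path)
    for col in ("intron_reads", "junction_reads"):
        if (df[col] < 0).any():
            bad = df.index[df[col] < 0][0]
            raise SchemaError(f"{path}, line {bad + 2}, column {col!r}: negative count")
    return df[SPLICING_COLUMNS]


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["sample_id", "followup_day"], path)
    if (df["followup_day"] < 0).any():
        bad = df.index[df["followup_day"] < 0][0]
        raise SchemaError(f"{path}, line {bad + 2}, column 'followup_day': negative")
    return df


def write_bundle(bundle: CohortBundle, out_dir) -> None:
    """Write a cohort as TSV tables plus a ground-truth/config JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.mutations.to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
    bundle.segments.to_csv(out / "segments.seg.tsv", sep="\t", index=False)
    bundle.baf.to_csv(out / "baf.tsv", sep="\t", index=False)
    bundle.expression.round(4).to_csv(out / "expression.tsv", sep="\t")
    bundle.normal_expression.round(4).to_csv(out / "normal_expression.tsv", sep="\t")
    bundle.splicing.to_csv(out / "splicing.tsv", sep="\t", index=False)
    bundle.transcript_tpm.to_csv(out / "transcript_tpm.tsv", sep="\t")
    bundle.transcript_class_map.to_csv(out / "transcript_class_map.tsv", sep="\t", index=False)
    bundle.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    gt = {
        "normal_ids": bundle.normal_ids,
        "samples": bundle.ground_truth.to_dict(orient="records"),
        "config": _config_to_dict(bundle.config),
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2) + "\n")


def read_bundle(in_dir) -> CohortBundle:
    """Read a cohort written by :func:`write_bundle`."""
    d = Path(in_dir)
    gt = json.loads((d / "ground_truth.json").read_text())
    cfg_dict = gt["config"]
    effect = cfg_dict.pop("signature_log2_effect", None)
    config = CohortConfig(**cfg_dict)
    if effect is not None:
        config.signature_log2_effect = np.asarray(effect, dtype=float)
    return CohortBundle(
        mutations=read_mutations(d / "mutations.maf.tsv"),
        segments=read_segments(d / "segments.seg.tsv"),
        baf=read_baf(d / "baf.tsv"),
        expression=read_expression(d / "expression.tsv"),
        normal_expression=read_expression(d / "normal_expression.tsv"),
        splicing=read_splicing(d / "splicing.tsv"),
        transcript_tpm=pd.read_csv(d / "transcript_tpm.tsv", sep="\t", index_col=0),
        transcript_class_map=pd.read_csv(d / "transcript_class_map.tsv", sep="\t"),
        clinical=read_clinical(d / "clinical.tsv"),
        ground_truth=pd.DataFrame(gt["samples"]),
        normal_ids=list(gt["normal_ids"]),
        config=config,
    )


def _config_to_dict(config: CohortConfig) -> dict:
    out = {}
    for key, value in vars(config).items():
        if isinstance(value, np.ndarray):
            value = [float(v) for v in value]
        elif isinstance(value, dict):
            value = {k: float(v) for k, v in value.items()}
        out[key] = value
    return out
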