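"""Readers/writers for the flat-file dialects the pipeline consumes and emits.

All tables are UTF-8, tab-delimited, with a required header row. Lines
starting with ``#`` are comments (the synthetic generators record their seed
and parameters there) and are ignored on read.

Dialects
--------
probe table      promoter_id, gene, probe_index, chrom, start, end, strand, methylation
promoter table   promoter_id, gene, chrom, start, end, tss, strand
BED6 sites       chrom, start, end, name (protein label), score (read support), strand
CLIP reads       mapped_sequences: read_id, sequence, copies
                 genome_mappings: read_id, chrom, start, end, strand,
                                  mismatches, insertions, deletions
gel lanes        replicate_id, assay, band_size, intensity  (+ optional group)
CT table         sample_id, ct_target_case, ct_reference_case,
                 ct_target_control, ct_reference_control
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PROBE_COLUMNS = [
    "promoter_id", "gene", "probe_index", "chrom", "start", "end", "strand",
    "methylation",
]
PROMOTER_COLUMNS = ["promoter_id", "gene", "chrom", "start", "end", "tss", "strand"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
MAPPED_COLUMNS = ["read_id", "sequence", "copies"]
MAPPINGS_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand", "mismatches", "insertions",
    "deletions",
]
LANE_COLUMNS = ["replicate_id", "assay", "band_size", "intensity"]
CT_COLUMNS = [
    "sample_id", "ct_target_case", "ct_reference_case", "ct_target_control",
    "ct_reference_control",
]


def write_tsv(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    """Write a TSV with optional leading '#' comment lines (provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_probe_table(path) -> pd.DataFrame:
    """Read and structurally validate a probe-methylation table."""
    df = _read_tsv(path, PROBE_COLUMNS)
    return validate_probe_table(df)


def validate_probe_table(df: pd.DataFrame) -> pd.DataFrame:
    if ((df["end"] - df["start"]) != 50).any():
        bad = df[(df["end"] - df["start"]) != 50]
        raise ValueError(f"{len(bad)} probes are not 50 bp long")
    if (~df["probe_index"].between(1, 15)).any():
        raise ValueError("probe_index outside 1..15")
    vals = df["methylation"].to_numpy(float)
    if not np.all(np.isfinite(vals)) or (vals < 0).any():
        raise ValueError("methylation values must be finite and >= 0")
    counts = df.groupby("promoter_id")["probe_index"].nunique()
    bad = counts[counts != 15]
    if len(bad):
        raise ValueError(
            f"{len(bad)} promoters do not have exactly 15 distinct probes "
            f"(e.g. {bad.index[0]!r})"
        )
    return df


def read_promoter_table(path) -> pd.DataFrame:
    return _read_tsv(path, PROMOTER_COLUMNS)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into a sites DataFrame (headerless, per BED)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED requires at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    """Write sites as BED6: name = protein label, score = read support."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df.get("name", df.get("ago", ".")),
            "score": df.get("score", df.get("support", 0)),
            "strand": df.get("strand", "."),
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, header=False, lineterminator="\n")


def read_clipz_mapped(path) -> pd.DataFrame:
    df = _read_tsv(path, MAPPED_COLUMNS)
    if (df["copies"] < 1).any():
        raise ValueError("copies must be >= 1")
    return df


def read_clipz_mappings(path) -> pd.DataFrame:
    df = _read_tsv(path, MAPPINGS_COLUMNS)
    for col in ("mismatches", "insertions", "deletions"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} must be >= 0")
    return df


def read_lane_table(path) -> pd.DataFrame:
    return _read_tsv(path, LANE_COLUMNS)


def read_ct_table(path) -> pd.DataFrame:
    return _read_tsv(path, CT_COLUMNS)
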