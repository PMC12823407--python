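"""Readers and writers for summary-statistic TSVs and BED intervals.

Conventions: tab-separated tables with a header row; P values stored as
log10 (a ``p`` column is accepted and converted with a logged notice);
genomic coordinates 0-based, half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("specdrift")

__all__ = ["read_summary_tsv", "write_summary_tsv", "write_bed", "read_bed"]

SCHEMAS = {
    "gwas": ["chrom", "pos", "beta", "se", "maf"],
    "burden": ["gene_id", "beta", "se", "p_lof"],
}


class SchemaError(ValueError):
    """A summary table violated its schema."""


def _check_numeric(df: pd.DataFrame, col: str, path: str) -> None:
    bad = df[col].isna() | ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
    if bad.any():
        row = int(np.where(bad)[0][0])
        raise SchemaError(f"{path}: non-numeric value in column {col!r} at data row {row}")


def read_summary_tsv(path: str | Path, kind: str = "gwas") -> pd.DataFrame:
    """Read and validate a GWAS or burden summary table.

    Either a ``log10p`` or a linear ``p`` column must be present; linear P
    values are validated to (0, 1] and converted to log10.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown summary kind {kind!r}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "log10p" not in df.columns:
        if "p" not in df.columns:
            raise SchemaError(f"{path}: need a 'log10p' or 'p' column")
        _check_numeric(df, "p", str(path))
        bad = (df["p"] <= 0) | (df["p"] > 1)
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise SchemaError(
                f"{path}: P value out of (0, 1] in column 'p' at data row {row}"
            )
        logger.info("converting linear 'p' column of %s to log10p", path)
        df["log10p"] = np.log10(df["p"])
        df = df.drop(columns=["p"])
    for col in SCHEMAS[kind] + ["log10p"]:
        if df[col].dtype == object and col not in ("gene_id", "chrom"):
            _check_numeric(df, col, str(path))
    if (df["log10p"] > 0).any():
        row = int(np.where(df["log10p"] > 0)[0][0])
        raise SchemaError(f"{path}: log10p must be <= 0 (data row {row})")
    if kind == "gwas" and ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        row = int(np.where((df["maf"] < 0) | (df["maf"] > 0.5))[0][0])
        raise SchemaError(f"{path}: MAF out of [0, 0.5] at data row {row}")
    logger.info("read %d rows from %s (%s schema)", len(df), path, kind)
    return df


def write_summary_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, start, end[, name, score]) intervals as sorted BED."""
    for c in ("chrom", "start", "end"):
        if c not in intervals.columns:
            raise ValueError(f"interval table missing column {c!r}")
    if (intervals["start"] >= intervals["end"]).any():
        raise ValueError("BED intervals must have start < end")
    out = intervals.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        if out.empty:
            fh.write("# empty interval set\n")
            return
        cols = ["chrom", "start", "end"] + [
            c for c in ("name", "score") if c in out.columns
        ]
        out[cols].to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED file (comment lines ignored)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rec = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if len(parts) > 3:
                rec["name"] = parts[3]
            rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"][: 4 if rows and "name" in rows[0] else 3])
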