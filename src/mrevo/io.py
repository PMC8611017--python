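"""Readers and writers for the pipeline's tabular formats.

Coordinate conventions: positions and SEG intervals are 1-based (intervals
inclusive of both ends) on disk, following the SEG/TSV habit of copy-number
callers; everything in memory is 0-based half-open.  The converters in this
module are the only place the conversion happens.

Validation errors carry 1-based file line numbers (header = line 1) so a
malformed row can be found with a pager.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

_VARIANT_COLS = ["patient", "sample", "chrom", "pos", "ref", "alt",
                 "alt_count", "depth"]
_SEG_COLS = ["sample", "chrom", "start", "end", "cn_major", "cn_minor",
             "purity", "ploidy"]
_SNP_COLS = ["chrom", "pos", "sample", "b_count", "depth"]


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _offending(mask: pd.Series) -> str:
    """Format 1-based line numbers of bad rows (data starts at line 2)."""
    lines = (np.flatnonzero(mask.to_numpy()) + 2).tolist()
    return ", ".join(map(str, lines[:20])) + ("..." if len(lines) > 20 else "")


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path) -> pd.DataFrame:
    """Read a variant TSV; positions converted to 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, _VARIANT_COLS, path)
    bad = (df["alt_count"] > df["depth"]) | (df["alt_count"] < 0)
    if bad.any():
        raise ValidationError(
            f"{path}: alt_count exceeds depth (or negative) on lines "
            f"{_offending(bad)}")
    bad = df["pos"] < 1
    if bad.any():
        raise ValidationError(f"{path}: non-positive positions on lines "
                              f"{_offending(bad)}")
    df = df.copy()
    df["pos"] = df["pos"] - 1
    for col in ("gene", "pathway"):     # optional annotation columns
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_variant_table(df: pd.DataFrame, path) -> Path:
    """Write a variant TSV; internal 0-based positions become 1-based."""
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


def write_vcf(df: pd.DataFrame, path, sample_order=None) -> Path:
    """Minimal VCF export of a variant table (AD and DP in FORMAT).

    One VCF sample column per biopsy; sites are the distinct (chrom, pos,
    ref, alt) tuples.  Positions are written 1-based per the VCF spec.
    """
    samples = sample_order or sorted(df["sample"].unique())
    keyed = df.set_index(["chrom", "pos", "ref", "alt", "sample"])
    sites = sorted(set(zip(df["chrom"], df["pos"], df["ref"], df["alt"])),
                   key=lambda t: (str(t[0]), t[1]))
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Read depth per allele">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for chrom, pos, ref, alt in sites:
        cells = []
        for s in samples:
            try:
                r = keyed.loc[(chrom, pos, ref, alt, s)]
                ad = f"{int(r['depth']) - int(r['alt_count'])},{int(r['alt_count'])}"
                cells.append(f"{ad}:{int(r['depth'])}")
            except KeyError:
                cells.append(".:.")
        lines.append(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tAD:DP\t"
                     + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


# ---------------------------------------------------------------------------
# segment tables (SEG-like)
# ---------------------------------------------------------------------------

def read_seg(path) -> pd.DataFrame:
    """Read a SEG-like TSV; 1-based inclusive intervals become half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, _SEG_COLS, path)
    bad = df["end"] < df["start"]
    if bad.any():
        raise ValidationError(f"{path}: end < start on lines {_offending(bad)}")
    bad = (df["cn_minor"] > df["cn_major"]) | (df["cn_minor"] < 0)
    if bad.any():
        raise ValidationError(
            f"{path}: cn_minor invalid (negative or > cn_major) on lines "
            f"{_offending(bad)}")
    bad = ~df["purity"].between(0, 1) | (df["purity"] <= 0)
    if bad.any():
        raise ValidationError(f"{path}: purity outside (0, 1] on lines "
                              f"{_offending(bad)}")
    df = df.copy()
    df["start"] = df["start"] - 1     # half-open: end stays put
    return df


def write_seg(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# SNP BAF tables
# ---------------------------------------------------------------------------

def read_snp_baf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, _SNP_COLS, path)
    bad = (df["b_count"] > df["depth"]) | (df["b_count"] < 0)
    if bad.any():
        raise ValidationError(
            f"{path}: b_count exceeds depth (or negative) on lines "
            f"{_offending(bad)}")
    df = df.copy()
    df["pos"] = df["pos"] - 1
    return df


def write_snp_baf(df: pd.DataFrame, path) -> Path:
    out = df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# cytobands (BED-like: already 0-based half-open on disk)
# ---------------------------------------------------------------------------

def read_cytobands(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "band"],
                     dtype={"chrom": str})
    bad = df["end"] <= df["start"]
    if bad.any():
        raise ValidationError(f"{path}: empty bands on lines {_offending(bad)}")
    return df


def write_cytobands(df: pd.DataFrame, path) -> Path:
    df[["chrom", "start", "end", "band"]].to_csv(
        path, sep="\t", index=False, header=False)
    return Path(path)
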