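"""Reading and writing the formats the pipeline touches.

CTSS tables use the CAGEr-style 4-column dialect (chrom, 1-based position,
strand, raw tag count), optionally extended with a 5th tags-per-million
column.  Genomic windows around a TSS use the no-zero relative-coordinate
convention: the TSS itself is +1, the first upstream base is -1, and a
window written -U/+D contains exactly U + D bases.  BED output is 0-based
half-open, as standard.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtssDataset",
    "read_ctss",
    "write_ctss",
    "read_fasta",
    "write_fasta",
    "fetch_window",
    "clusters_to_bed",
    "read_bed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


class CtssParseError(ValueError):
    """Malformed CTSS input; carries the 1-based line number."""


@dataclass
class CtssDataset:
    """Per-sample CTSS table sorted by (chrom, strand, pos).

    ``df`` holds columns chrom, pos, strand, count and, after
    normalization, tpm.  (chrom, pos, strand) is unique.
    """

    df: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.df = _canonicalize(self.df)

    @property
    def total_raw(self) -> int:
        return int(self.df["count"].sum())

    @property
    def has_tpm(self) -> bool:
        return "tpm" in self.df.columns

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CtssDataset):
            return NotImplemented
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if set(a.columns) != set(b.columns):
            return False
        return a[sorted(a.columns)].equals(b[sorted(b.columns)])


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Sum duplicate positions and sort by (chrom, strand, pos)."""
    if len(df) == 0:
        cols = list(df.columns) if len(df.columns) else CTSS_COLUMNS
        return pd.DataFrame({c: pd.Series(dtype="int64" if c in ("pos", "count") else object) for c in cols})
    agg = {"count": "sum"}
    if "tpm" in df.columns:
        agg["tpm"] = "sum"
    out = (
        df.groupby(["chrom", "strand", "pos"], as_index=False, sort=False)
        .agg(agg)
        .sort_values(["chrom", "strand", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    cols = ["chrom", "pos", "strand", "count"] + (["tpm"] if "tpm" in out.columns else [])
    return out[cols]


def read_ctss(path: str | os.PathLike, sample_id: str | None = None) -> CtssDataset:
    """Read a 4/5-column CTSS TSV; duplicate positions are summed.

    Raises :class:`CtssParseError` naming the first offending line on a
    malformed strand or non-integer count.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise CtssParseError(f"line {lineno}: expected 4 or 5 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, count_s = parts[:4]
            if strand not in ("+", "-"):
                raise CtssParseError(f"line {lineno}: invalid strand {strand!r}")
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError:
                raise CtssParseError(f"line {lineno}: non-integer position or count") from None
            if count < 1:
                raise CtssParseError(f"line {lineno}: raw count must be >= 1")
            row = {"chrom": chrom, "pos": pos, "strand": strand, "count": count}
            if len(parts) == 5:
                row["tpm"] = float(parts[4])
            rows.append(row)
    if not rows:
        df = pd.DataFrame(columns=CTSS_COLUMNS)
    else:
        df = pd.DataFrame(rows)
    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(str(path)))[0]
    return CtssDataset(df, sample_id=sid)


def write_ctss(dataset: CtssDataset, path: str | os.PathLike, include_tpm: bool = False) -> None:
    """Write the 4-column CTSS TSV (5 columns when ``include_tpm``)."""
    cols = CTSS_COLUMNS + (["tpm"] if include_tpm and dataset.has_tpm else [])
    dataset.df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a (small) FASTA into an in-memory dict of upper-case sequences."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA content before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _chrom_seq(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice padded with N beyond the contig."""
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        rec = genome[chrom]
    else:  # pyfaidx.Fasta or similar indexed access
        try:
            rec = genome[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None
    length = len(rec)
    lo, hi = max(start, 1), min(end, length)
    if hi >= lo:
        core = rec[lo - 1 : hi]
        core = (core if isinstance(core, str) else str(core)).upper()
    else:
        core = ""
    left = max(0, min(end + 1, 1) - start)
    right = max(0, end - max(start - 1, length))
    return "N" * left + core + "N" * right


def fetch_window(
    genome,
    chrom: str,
    center_pos: int,
    strand: str,
    upstream: int,
    downstream: int,
) -> str:
    """Oriented sequence of a -upstream/+downstream window around a TSS.

    No-zero convention: the base at ``center_pos`` is +1; -1 is the first
    upstream base.  The returned string has length upstream + downstream,
    reads 5'->3' on the given strand, and is padded with N where the window
    leaves the contig.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "+":
        start = center_pos - upstream
        end = center_pos + downstream - 1
        return _chrom_seq(genome, chrom, start, end)
    start = center_pos - downstream + 1
    end = center_pos + upstream
    return reverse_complement(_chrom_seq(genome, chrom, start, end))


# ---------------------------------------------------------------------------
# BED

def clusters_to_bed(clusters: pd.DataFrame, path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Convert a tag/consensus cluster table to BED6+ (0-based half-open).

    Score is the rounded total TPM; thickStart/thickEnd mark the dominant
    TSS when the table carries one.
    """
    bed = pd.DataFrame(
        {
            "chrom": clusters["chrom"],
            "chromStart": clusters["start"].astype(int) - 1,
            "chromEnd": clusters["end"].astype(int),
            "name": clusters["id"].astype(str) if "id" in clusters else np.arange(len(clusters)).astype(str),
            "score": clusters["total_tpm"].astype(float).round().astype(int) if "total_tpm" in clusters else 0,
            "strand": clusters["strand"],
        }
    )
    if "dominant_pos" in clusters:
        bed["thickStart"] = clusters["dominant_pos"].astype(int) - 1
        bed["thickEnd"] = clusters["dominant_pos"].astype(int)
    if path is not None:
        bed.to_csv(path, sep="\t", header=False, index=False)
    return bed


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open) into a DataFrame."""
    names = ["chrom", "chromStart", "chromEnd", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [f"extra{i}" for i in range(max(0, df.shape[1] - 6))]
    return df
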