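"""Condition subtraction and distance-based TSS clustering.

Subtraction isolates the condition-specific signal: every WT position that
carries any tags in the mutant is removed outright (counts are never
partially subtracted), leaving the set of TSSs whose activity depends on
the factor knocked out in the mutant.

Clustering follows distclu semantics: CTSSs passing a TPM threshold are
joined single-linkage along each (chrom, strand) whenever consecutive
passing positions are at most ``max_dist`` apart; singleton clusters are
dropped unless their signal exceeds a rescue threshold.  Promoter sharpness
is the interquantile width: the span between the positions where cumulative
cluster signal first reaches the 0.1 and 0.9 fractions of the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtssDataset

__all__ = ["subtract_ctss", "cluster_ctss", "interquantile_bounds", "TAG_CLUSTER_COLUMNS"]

TAG_CLUSTER_COLUMNS = [
    "id", "chrom", "strand", "start", "end", "n_ctss", "total_tpm",
    "dominant_pos", "dominant_tpm", "q_low_pos", "q_up_pos", "iq_width",
]


def subtract_ctss(wt: CtssDataset, mutant: CtssDataset, min_mutant_count: int = 1) -> CtssDataset:
    """WT records whose (chrom, pos, strand) is absent from the mutant.

    Counts are untouched; a position is "present in mutant" when its raw
    count is >= ``min_mutant_count``.
    """
    if len(mutant) == 0 or len(wt) == 0:
        return CtssDataset(wt.df.copy(), sample_id=wt.sample_id)
    mut = mutant.df[mutant.df["count"] >= min_mutant_count]
    key_cols = ["chrom", "pos", "strand"]
    merged = wt.df.merge(mut[key_cols].drop_duplicates(), on=key_cols, how="left", indicator=True)
    out = merged[merged["_merge"] == "left_only"].drop(columns="_merge")
    return CtssDataset(out.reset_index(drop=True), sample_id=wt.sample_id)


def interquantile_bounds(positions, tpm, q_low: float = 0.1, q_up: float = 0.9) -> tuple[int, int, int]:
    """Quantile positions of a per-position signal in genomic order.

    Scanning 5'->3' in genomic coordinates, the lower bound is the first
    position where cumulative signal reaches ``q_low`` of the total and the
    upper bound the first where it reaches ``q_up``; width is their
    difference plus one (widths are strand-symmetric).
    """
    positions = np.asarray(positions)
    tpm = np.asarray(tpm, dtype=float)
    if positions.size == 0 or tpm.sum() <= 0:
        raise ValueError("empty or zero signal: interquantile bounds undefined")
    order = np.argsort(positions, kind="mergesort")
    positions, tpm = positions[order], tpm[order]
    cum = np.cumsum(tpm)
    total = cum[-1]
    eps = 1e-9 * total
    i_low = int(np.searchsorted(cum, q_low * total - eps))
    i_up = int(np.searchsorted(cum, q_up * total - eps))
    q_low_pos, q_up_pos = int(positions[i_low]), int(positions[i_up])
    return q_low_pos, q_up_pos, q_up_pos - q_low_pos + 1


def _dominant(positions: np.ndarray, tpm: np.ndarray, strand: str) -> tuple[int, float]:
    """Argmax TPM; ties broken toward the most 5' position on the strand."""
    best = tpm.max()
    at_best = positions[tpm >= best]
    pos = at_best.min() if strand == "+" else at_best.max()
    return int(pos), float(best)


def cluster_ctss(
    dataset: CtssDataset,
    threshold: float = 1.0,
    max_dist: int = 20,
    keep_singletons_above: float = 5.0,
    q_low: float = 0.1,
    q_up: float = 0.9,
) -> pd.DataFrame:
    """Distance clustering of normalized CTSSs into tag clusters.

    Returns a DataFrame with TAG_CLUSTER_COLUMNS.  Requires ``tpm`` (raises
    on raw-only data).  CTSSs below ``threshold`` TPM are discarded before
    clustering; single-CTSS clusters are kept only above
    ``keep_singletons_above`` TPM.
    """
    if not dataset.has_tpm:
        raise ValueError("dataset is not normalized: run normalize_power_law first")
    df = dataset.df[dataset.df["tpm"] >= threshold]
    rows = []
    cid = 0
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        tpm = grp["tpm"].to_numpy(dtype=float)
        if pos.size == 0:
            continue
        # positions are sorted within (chrom, strand) by dataset invariant
        breaks = np.flatnonzero(np.diff(pos) > max_dist) + 1
        for seg_pos, seg_tpm in zip(np.split(pos, breaks), np.split(tpm, breaks)):
            total = float(seg_tpm.sum())
            if seg_pos.size == 1 and total < keep_singletons_above:
                continue
            dom_pos, dom_tpm = _dominant(seg_pos, seg_tpm, strand)
            ql, qu, width = interquantile_bounds(seg_pos, seg_tpm, q_low, q_up)
            rows.append(
                (f"TC{cid}", chrom, strand, int(seg_pos[0]), int(seg_pos[-1]),
                 int(seg_pos.size), total, dom_pos, dom_tpm, ql, qu, width)
            )
            cid += 1
    return pd.DataFrame(rows, columns=TAG_CLUSTER_COLUMNS)
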