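"""Shifting-promoter detection between two conditions.

A promoter "shifts" when the within-region distribution of TSS usage
differs between conditions.  For each consensus cluster with enough signal
in both samples, per-position cumulative TSS distributions are compared
with a two-sample Kolmogorov-Smirnov test whose effective sample sizes come
from the raw tag totals; promoters are selected by Benjamini-Hochberg FDR
(0.01 by default) with no shift-score cutoff.

The KS p-value is the asymptotic Kolmogorov tail with the Stephens
small-sample factor: p = Q(lambda), lambda = (sqrt(ne) + 0.12 +
0.11/sqrt(ne)) * D, ne = n1*n2/(n1+n2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests

from .io import CtssDataset

__all__ = [
    "cumulative_distribution",
    "score_shift",
    "score_all_shifts",
    "bh_fdr",
    "get_shifting_promoters",
    "SHIFT_COLUMNS",
]

SHIFT_COLUMNS = [
    "consensus_id", "ks_D", "p_value", "fdr", "shift_score",
    "dominant_offset", "direction", "n_dep", "n_indep",
]


class InsufficientSignalError(ValueError):
    """No usable signal for a cumulative distribution."""


def _region_signal(ds: CtssDataset, chrom: str, strand: str, start: int, end: int):
    sub = ds.df[(ds.df["chrom"] == chrom) & (ds.df["strand"] == strand)
                & (ds.df["pos"] >= start) & (ds.df["pos"] <= end)]
    return sub["pos"].to_numpy(), sub


def cumulative_distribution(positions, weights, start: int, end: int, strand: str = "+"):
    """Cumulative TSS-usage fraction over a region, 5'->3' on the strand.

    Returns (grid_positions, F): genomic positions start..end in strand
    orientation and the non-decreasing cumulative fraction reaching 1 at
    the 3' end.
    """
    positions = np.asarray(positions)
    weights = np.asarray(weights, dtype=float)
    if positions.size == 0 or weights.sum() <= 0:
        raise InsufficientSignalError("zero signal in region")
    grid = np.arange(start, end + 1)
    per_pos = np.zeros(grid.size)
    np.add.at(per_pos, positions - start, weights)
    if strand == "-":
        grid = grid[::-1]
        per_pos = per_pos[::-1]
    f = np.cumsum(per_pos) / per_pos.sum()
    return grid, f


def ks_two_sample(f1: np.ndarray, f2: np.ndarray, n1: float, n2: float) -> tuple[float, float]:
    """KS statistic and asymptotic p for two cumulative curves on one grid."""
    d = float(np.max(np.abs(f1 - f2)))
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * d
    p = float(min(1.0, max(0.0, kolmogorov(lam))))
    return d, p


def score_shift(
    consensus_row,
    dep: CtssDataset,
    indep: CtssDataset,
    min_tpm: float = 3.0,
    use_raw_counts: bool = True,
) -> dict | None:
    """KS shift scoring of one consensus cluster between two samples.

    Returns a dict of SHIFT_COLUMNS (without fdr) or None when either
    sample lacks ``min_tpm`` TPM inside the region (skipped cluster).
    ``shift_score`` is the signed cumulative difference (independent minus
    dependent) at the position of maximal absolute difference: positive
    means the dependent sample's TSS usage sits 3' of the independent one.
    """
    chrom, strand = consensus_row["chrom"], consensus_row["strand"]
    start, end = int(consensus_row["start"]), int(consensus_row["end"])
    pos_d, sub_d = _region_signal(dep, chrom, strand, start, end)
    pos_i, sub_i = _region_signal(indep, chrom, strand, start, end)
    if len(sub_d) == 0 or len(sub_i) == 0:
        return None
    tpm_d = sub_d["tpm"].to_numpy(dtype=float) if "tpm" in sub_d else sub_d["count"].to_numpy(dtype=float)
    tpm_i = sub_i["tpm"].to_numpy(dtype=float) if "tpm" in sub_i else sub_i["count"].to_numpy(dtype=float)
    if tpm_d.sum() < min_tpm or tpm_i.sum() < min_tpm:
        return None
    _, f_d = cumulative_distribution(pos_d, tpm_d, start, end, strand)
    _, f_i = cumulative_distribution(pos_i, tpm_i, start, end, strand)
    n_d = float(sub_d["count"].sum()) if use_raw_counts else float(tpm_d.sum())
    n_i = float(sub_i["count"].sum()) if use_raw_counts else float(tpm_i.sum())
    d, p = ks_two_sample(f_d, f_i, n_d, n_i)
    k = int(np.argmax(np.abs(f_d - f_i)))
    shift_score = float(f_i[k] - f_d[k])
    # strand-oriented dominant offset, dependent relative to independent
    dom_d = _dominant_pos(pos_d, tpm_d, strand)
    dom_i = _dominant_pos(pos_i, tpm_i, strand)
    offset = (dom_d - dom_i) if strand == "+" else (dom_i - dom_d)
    direction = "none" if offset == 0 else ("5'" if offset < 0 else "3'")
    return {
        "consensus_id": consensus_row["id"],
        "ks_D": d,
        "p_value": p,
        "shift_score": shift_score,
        "dominant_offset": int(offset),
        "direction": direction,
        "n_dep": n_d,
        "n_indep": n_i,
    }


def _dominant_pos(positions: np.ndarray, tpm: np.ndarray, strand: str) -> int:
    best = tpm.max()
    at_best = positions[tpm >= best]
    return int(at_best.min() if strand == "+" else at_best.max())


def score_all_shifts(
    consensus: pd.DataFrame,
    dep: CtssDataset,
    indep: CtssDataset,
    min_tpm: float = 3.0,
    use_raw_counts: bool = True,
) -> pd.DataFrame:
    """Score every consensus cluster; skipped clusters are omitted.

    Adds the BH-adjusted ``fdr`` column over the scored clusters.
    """
    rows = []
    for _, row in consensus.iterrows():
        res = score_shift(row, dep, indep, min_tpm=min_tpm, use_raw_counts=use_raw_counts)
        if res is not None:
            rows.append(res)
    if not rows:
        return pd.DataFrame(columns=SHIFT_COLUMNS)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out[SHIFT_COLUMNS]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def get_shifting_promoters(
    results: pd.DataFrame,
    fdr_threshold: float = 0.01,
    score_threshold: float = float("-inf"),
) -> pd.DataFrame:
    """Select shifting promoters by FDR (and optionally shift score)."""
    if len(results) == 0:
        return results
    keep = results["fdr"] <= fdr_threshold
    if score_threshold != float("-inf"):
        keep &= results["shift_score"] > score_threshold
    return results[keep]
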