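"""Consensus promoter regions and per-sample expression.

Per-sample tag clusters above a TPM threshold are trimmed to their
interquantile span and pooled across samples; trimmed intervals on the same
(chrom, strand) merge whenever the gap between them is at most ``max_dist``
(100 bp by default).  Each merged region is a consensus cluster — one
promoter tracked across conditions.  Expression of a consensus cluster in a
sample is the sum of ALL of that sample's normalized CTSS signal inside the
region (robust to per-sample cluster fragmentation), and the per-sample
dominant TSS is the argmax position within the region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CtssDataset

__all__ = ["aggregate_clusters", "expression_matrix", "subset_by_regions"]


def _merge_intervals(iv: np.ndarray, max_dist: int) -> list[tuple[int, int]]:
    """Merge sorted [start, end] (1-based inclusive) intervals with gap <= max_dist."""
    merged: list[list[int]] = []
    for s, e in iv:
        if merged and s - merged[-1][1] <= max_dist:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def aggregate_clusters(
    cluster_tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
    tpm_threshold: float = 3.0,
    max_dist: int = 100,
) -> pd.DataFrame:
    """Pool per-sample tag clusters into consensus promoter regions.

    Clusters under ``tpm_threshold`` total TPM are discarded; survivors are
    trimmed to [q_low_pos, q_up_pos] and merged across samples.  Returns a
    DataFrame with columns id, chrom, strand, start, end.
    """
    tables = list(cluster_tables.values()) if isinstance(cluster_tables, dict) else list(cluster_tables)
    tables = [t for t in tables if len(t)]
    if not tables:
        return pd.DataFrame(columns=["id", "chrom", "strand", "start", "end"])
    pooled = pd.concat(tables, ignore_index=True)
    pooled = pooled[pooled["total_tpm"] >= tpm_threshold]
    rows = []
    cid = 0
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        iv = grp[["q_low_pos", "q_up_pos"]].to_numpy(dtype=int)
        iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
        for s, e in _merge_intervals(iv, max_dist):
            rows.append((f"CC{cid}", chrom, strand, int(s), int(e)))
            cid += 1
    return pd.DataFrame(rows, columns=["id", "chrom", "strand", "start", "end"])


def expression_matrix(
    consensus: pd.DataFrame,
    datasets: dict[str, CtssDataset],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-consensus-cluster TPM and dominant TSS for each sample.

    Returns ``(expr, dominants)``: expr is clusters x samples of summed TPM
    inside each region (strand-matched); dominants holds the per-sample
    argmax position (NaN where the sample has no signal in the region).
    """
    expr = pd.DataFrame(0.0, index=consensus["id"], columns=list(datasets))
    dom = pd.DataFrame(np.nan, index=consensus["id"], columns=list(datasets))
    for sample, ds in datasets.items():
        if not ds.has_tpm:
            raise ValueError(f"dataset {sample!r} is not normalized")
        for (chrom, strand), cons_grp in consensus.groupby(["chrom", "strand"], sort=False):
            sub = ds.df[(ds.df["chrom"] == chrom) & (ds.df["strand"] == strand)]
            if len(sub) == 0:
                continue
            pos = sub["pos"].to_numpy()
            tpm = sub["tpm"].to_numpy(dtype=float)
            cum = np.concatenate([[0.0], np.cumsum(tpm)])
            starts = cons_grp["start"].to_numpy()
            ends = cons_grp["end"].to_numpy()
            lo = np.searchsorted(pos, starts, side="left")
            hi = np.searchsorted(pos, ends, side="right")
            expr.loc[cons_grp["id"], sample] = cum[hi] - cum[lo]
            for cid, l, h, strand_ in zip(cons_grp["id"], lo, hi, cons_grp["strand"]):
                if h > l:
                    seg_tpm = tpm[l:h]
                    best = seg_tpm.max()
                    at_best = pos[l:h][seg_tpm >= best]
                    dom.loc[cid, sample] = at_best.min() if strand_ == "+" else at_best.max()
    return expr, dom


def subset_by_regions(clusters: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Clusters whose dominant TSS falls inside any BED region.

    ``regions`` uses BED half-open 0-based coordinates (columns chrom,
    chromStart, chromEnd); matching is strand-agnostic.
    """
    if len(regions) == 0 or len(clusters) == 0:
        return clusters.iloc[0:0]
    keep = np.zeros(len(clusters), dtype=bool)
    for chrom, grp in regions.groupby("chrom"):
        mask = clusters["chrom"] == chrom
        if not mask.any():
            continue
        pos0 = clusters.loc[mask, "dominant_pos"].to_numpy() - 1  # to 0-based
        starts = grp["chromStart"].to_numpy()
        ends = grp["chromEnd"].to_numpy()
        inside = ((pos0[:, None] >= starts[None, :]) & (pos0[:, None] < ends[None, :])).any(axis=1)
        keep[np.flatnonzero(mask.to_numpy())] = inside
    return clusters[keep]
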