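"""Ground-truth linkage for synthetic-study evaluation.

Connects clusters called by the pipeline back to the planted promoters so
recovery tests can ask class-resolved questions (are clusters at true
sharp promoters narrower than at true broad ones? do planted shifts get
detected?).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_clusters_to_truth"]


def match_clusters_to_truth(
    clusters: pd.DataFrame,
    truth: pd.DataFrame,
    condition: str = "wt",
    slack: int = 0,
) -> pd.DataFrame:
    """Attach the planted promoter (if any) to each cluster.

    A cluster matches a promoter when the promoter's dominant TSS for
    ``condition`` lies within the cluster span (+- ``slack``) on the same
    chrom and strand.  Returns ``clusters`` with promoter_id and
    promoter_class columns (NaN where unmatched); at most one promoter per
    cluster (promoters are planted far apart).
    """
    dom_col = f"dominant_tss_{condition}"
    out = clusters.copy()
    out["promoter_id"] = pd.NA
    out["promoter_class"] = pd.NA
    for (chrom, strand), tgrp in truth.groupby(["chrom", "strand"]):
        mask = (clusters["chrom"] == chrom) & (clusters["strand"] == strand)
        if not mask.any():
            continue
        sub = clusters[mask]
        dom = tgrp[dom_col].to_numpy()
        order = np.argsort(dom)
        dom_sorted = dom[order]
        ids = tgrp["promoter_id"].to_numpy()[order]
        classes = tgrp["promoter_class"].to_numpy()[order]
        starts = sub["start"].to_numpy() - slack
        ends = sub["end"].to_numpy() + slack
        # first planted dominant TSS at or after each cluster start
        j = np.searchsorted(dom_sorted, starts, side="left")
        hit = (j < dom_sorted.size) & (np.where(j < dom_sorted.size, dom_sorted[np.minimum(j, dom_sorted.size - 1)], np.inf) <= ends)
        idx = np.flatnonzero(mask.to_numpy())
        out.iloc[idx[hit], out.columns.get_loc("promoter_id")] = ids[j[hit]]
        out.iloc[idx[hit], out.columns.get_loc("promoter_class")] = classes[j[hit]]
    return out
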