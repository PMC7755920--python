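"""Self-organising-map classification of promoter expression profiles.

Consensus clusters expressed above a TPM threshold in at least one sample
are scaled to unit sum across samples and mapped onto a small rectangular
SOM (3x2 by default), giving a handful of promoter activity classes
(e.g. WT-specific, mutant-specific, constitutive).  The SOM is a standard
online Kohonen map: Gaussian neighborhood on the grid, learning rate and
radius decaying linearly over 100 iterations per profile, prototypes
initialised from randomly drawn profiles.  Training is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SelfOrganisingMap", "SomResult", "som_profiles", "label_condition_nodes"]


@dataclass
class SomResult:
    xdim: int
    ydim: int
    assignments: pd.Series          # cluster id -> flat node index
    prototypes: np.ndarray          # (xdim*ydim, n_samples)
    profiles: pd.DataFrame          # the scaled profiles that were mapped
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.xdim * self.ydim

    def node_grid(self, node: int) -> tuple[int, int]:
        return node % self.xdim, node // self.xdim


class SelfOrganisingMap:
    """Minimal seeded rectangular SOM (online training)."""

    def __init__(self, xdim: int, ydim: int, seed: int = 0,
                 lr0: float = 0.5, lr1: float = 0.02, sigma1: float = 0.3):
        self.xdim, self.ydim = int(xdim), int(ydim)
        self.seed = int(seed)
        self.lr0, self.lr1 = lr0, lr1
        self.sigma0 = max(xdim, ydim) / 2.0
        self.sigma1 = sigma1
        gx, gy = np.meshgrid(np.arange(self.xdim), np.arange(self.ydim), indexing="xy")
        self._grid = np.column_stack([gx.ravel(), gy.ravel()])  # flat index = x + y*xdim
        self.weights: np.ndarray | None = None

    def fit(self, X: np.ndarray, n_iter: int | None = None) -> "SelfOrganisingMap":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if n < 2:
            raise ValueError("need at least 2 profiles to train a SOM")
        rng = np.random.default_rng(self.seed)
        k = self.xdim * self.ydim
        init_idx = rng.choice(n, size=k, replace=n < k)
        w = X[init_idx] + rng.normal(0.0, 1e-4, size=(k, d))
        if n_iter is None:
            n_iter = 100 * n
        order = rng.integers(0, n, size=n_iter)
        grid2 = ((self._grid[:, None, :] - self._grid[None, :, :]) ** 2).sum(-1)  # squared grid distances
        for t, i in enumerate(order):
            frac = t / max(n_iter - 1, 1)
            lr = self.lr0 + (self.lr1 - self.lr0) * frac
            sigma = self.sigma0 + (self.sigma1 - self.sigma0) * frac
            x = X[i]
            bmu = int(np.argmin(((w - x) ** 2).sum(1)))
            h = np.exp(-grid2[bmu] / (2.0 * sigma * sigma))
            w += lr * h[:, None] * (x - w)
        self.weights = w
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("SOM not trained")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)


def som_profiles(expr: pd.DataFrame, tpm_threshold: float = 3.0,
                 xdim: int = 3, ydim: int = 2, seed: int = 0) -> SomResult:
    """Map consensus expression profiles onto a small SOM.

    Clusters whose maximum expression across samples is below
    ``tpm_threshold`` are excluded; retained profiles are scaled to sum 1
    across samples before training.
    """
    kept = expr[expr.max(axis=1) >= tpm_threshold]
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} profiles pass the {tpm_threshold} TPM threshold; need >= 2")
    profiles = kept.div(kept.sum(axis=1), axis=0)
    som = SelfOrganisingMap(xdim, ydim, seed=seed).fit(profiles.to_numpy())
    nodes = som.predict(profiles.to_numpy())
    return SomResult(
        xdim=xdim, ydim=ydim,
        assignments=pd.Series(nodes, index=profiles.index, name="som_node"),
        prototypes=som.weights.copy(),
        profiles=profiles,
        seed=seed,
    )


def label_condition_nodes(result: SomResult, sample_a: str, sample_b: str) -> dict[str, int]:
    """Post-hoc labelling of the two most condition-specific nodes.

    Returns the node whose prototype puts maximal weight on ``sample_a``
    (e.g. the WT-specific / "downregulated in mutant" class) and likewise
    for ``sample_b``.
    """
    cols = list(result.profiles.columns)
    ia, ib = cols.index(sample_a), cols.index(sample_b)
    return {
        sample_a: int(np.argmax(result.prototypes[:, ia])),
        sample_b: int(np.argmax(result.prototypes[:, ib])),
    }
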