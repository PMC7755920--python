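"""Core-promoter sequence analysis.

Sharp maternal-type promoters carry a TATA-like A/T-rich element (W-box)
around -30; broad promoters are TATA-less.  This module quantifies that
code: WW-dinucleotide occurrence maps over -250/+250 promoter windows
(rows ordered by promoter sharpness), best TATA-PWM relative match inside
the -35/-20 window of each dominant TSS, Wilcoxon rank-sum comparison of
match distributions between promoter sets, and information-content matrices
for sequence logos.

PWM scoring is log-odds with pseudocount-regularised frequencies against a
(uniform by default) background, reported as a relative score
100 * (S - S_min) / (S_max - S_min) so 100% is the consensus and 0% the
anti-consensus; N bases contribute their background-expected score.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import mannwhitneyu

from .io import fetch_window

__all__ = [
    "Pwm",
    "load_tbp_pwm",
    "MotifProfile",
    "ww_density",
    "pwm_relative_scores",
    "best_tata_match",
    "wilcoxon_rank_sum",
    "information_content_logo",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_WW = {"AA", "AT", "TA", "TT"}


@dataclass
class Pwm:
    """Position weight matrix with log-odds scoring.

    ``counts`` is 4 x L (rows A, C, G, T).  Frequencies get ``pseudocount``
    added per cell before normalisation; ``background`` defaults to uniform.
    """

    counts: np.ndarray
    source: str = "custom"
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("PWM counts must be a 4 x L matrix (rows A, C, G, T)")
        freq = self.counts + self.pseudocount
        self.freq = freq / freq.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background, dtype=float)
        self.log_odds = np.log2(self.freq / bg[:, None])
        # expected per-column score under background: what an N contributes
        self._n_score = (bg[:, None] * self.log_odds).sum(axis=0)
        self._col_min = self.log_odds.min(axis=0)
        self._col_max = self.log_odds.max(axis=0)

    def __len__(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmax(axis=0))

    @property
    def anti_consensus(self) -> str:
        return "".join(_BASES[i] for i in self.log_odds.argmin(axis=0))

    @classmethod
    def from_jaspar(cls, handle_or_path, **kwargs) -> "Pwm":
        if hasattr(handle_or_path, "read"):
            motif = bio_motifs.read(handle_or_path, "jaspar")
        else:
            with open(handle_or_path) as fh:
                motif = bio_motifs.read(fh, "jaspar")
        counts = np.array([list(motif.counts[b]) for b in _BASES], dtype=float)
        return cls(counts, source=motif.name or "jaspar", **kwargs)


def load_tbp_pwm(pseudocount: float = 0.01, background=None) -> Pwm:
    """The packaged JASPAR-derived TBP (TATA-box) matrix."""
    kwargs = {"pseudocount": pseudocount}
    if background is not None:
        kwargs["background"] = np.asarray(background, dtype=float)
    ref = resources.files("promarch.data").joinpath("tbp_pwm.jaspar")
    with ref.open() as fh:
        pwm = Pwm.from_jaspar(fh, **kwargs)
    pwm.source = "TBP (JASPAR MA0108.2)"
    return pwm


def pwm_relative_scores(sequence: str, pwm: Pwm) -> np.ndarray:
    """Relative PWM match (%) at every valid start of the sequence.

    One score per start (len(sequence) - L + 1), each in [0, 100].
    N bases are scored as background (their expected log-odds).
    """
    seq = sequence.upper()
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} shorter than motif length {L}")
    idx = np.array([_BASE_INDEX.get(c, -1) for c in seq])
    n_starts = len(seq) - L + 1
    scores = np.empty(n_starts)
    lo = pwm.log_odds
    for s in range(n_starts):
        cols = idx[s : s + L]
        known = cols >= 0
        val = lo[cols[known], np.flatnonzero(known)].sum() + pwm._n_score[~known].sum()
        scores[s] = val
    s_min, s_max = pwm._col_min.sum(), pwm._col_max.sum()
    return 100.0 * (scores - s_min) / (s_max - s_min)


@dataclass
class MotifProfile:
    """Binary WW-occurrence matrix with rows ordered by promoter sharpness."""

    occurrence: np.ndarray          # (n_sequences, window_length - 1), 0/1
    widths: np.ndarray              # sorted ascending, parallel to rows
    order: np.ndarray               # original indices in row order

    @property
    def positional_mean(self) -> np.ndarray:
        return self.occurrence.mean(axis=0)

    def smoothed(self, bandwidth: tuple[float, float] = (5.0, 3.0)) -> np.ndarray:
        """2D-Gaussian-smoothed density for rendering; analysis stays unsmoothed."""
        from scipy.ndimage import gaussian_filter

        return gaussian_filter(self.occurrence.astype(float), sigma=bandwidth)


def ww_density(sequences, widths) -> MotifProfile:
    """WW (AA/AT/TA/TT) dinucleotide occurrence per position per sequence.

    Sequences must be equal-length and strand-oriented; position i is
    marked when s[i:i+2] is WW (the final base has no score).  Rows are
    sorted by ascending interquantile width.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be equal length")
    widths = np.asarray(widths)
    if widths.size != len(seqs):
        raise ValueError("one width per sequence required")
    occ = np.zeros((len(seqs), L - 1), dtype=np.int8)
    for r, s in enumerate(seqs):
        occ[r] = [1 if s[i : i + 2] in _WW else 0 for i in range(L - 1)]
    order = np.argsort(widths, kind="mergesort")
    return MotifProfile(occurrence=occ[order], widths=widths[order], order=order)


def best_tata_match(
    clusters: pd.DataFrame,
    genome,
    pwm: Pwm | None = None,
    window: tuple[int, int] = (-35, -20),
) -> pd.Series:
    """Best relative PWM match inside a fixed upstream window per cluster.

    The window is given in no-zero relative coordinates around the dominant
    TSS (default -35..-20, 16 bases); the motif may start anywhere it fits
    fully inside.  Off-contig windows are N-padded (N scores as
    background).  Returns a Series of best scores indexed by cluster id.
    """
    if pwm is None:
        pwm = load_tbp_pwm()
    up_from, up_to = window
    if not (up_from < up_to < 0):
        raise ValueError("window must be strictly upstream, e.g. (-35, -20)")
    win_len = up_to - up_from + 1
    if win_len < len(pwm):
        raise ValueError("window shorter than the motif")
    best = np.empty(len(clusters))
    for i, (_, row) in enumerate(clusters.iterrows()):
        seq = fetch_window(genome, row["chrom"], int(row["dominant_pos"]), row["strand"],
                           upstream=-up_from, downstream=0)
        best[i] = pwm_relative_scores(seq[:win_len], pwm).max()
    index = clusters["id"] if "id" in clusters else clusters.index
    return pd.Series(best, index=index, name="best_tata_match")


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (midranks for ties).

    Exact enumeration for n1 + n2 <= 12; otherwise the tie-corrected
    normal approximation with continuity correction.  Returns the rank sum
    of ``a`` and the two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    w_obs = ranks[: a.size].sum()
    if a.size + b.size <= 12:
        n = pooled.size
        e_w = a.size * (n + 1) / 2.0
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), a.size):
            total += 1
            if abs(ranks[list(comb)].sum() - e_w) >= abs(w_obs - e_w) - 1e-12:
                count += 1
        return float(w_obs), count / total
    _, p = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(w_obs), float(p)


def information_content_logo(sequences, alphabet: str = _BASES) -> pd.DataFrame:
    """Per-position base frequencies and information content (bits).

    IC(pos) = 2 - H(pos) with H the Shannon entropy of the base frequencies
    at that position (no small-sample correction); N/other characters are
    ignored in the frequency estimate.  A position with only N gets IC 0
    and the ``all_n`` flag.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be equal length")
    rows = []
    for i in range(L):
        counts = np.zeros(4)
        for s in seqs:
            j = _BASE_INDEX.get(s[i], -1)
            if j >= 0:
                counts[j] += 1
        total = counts.sum()
        if total == 0:
            rows.append({"position": i, "A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0,
                         "ic": 0.0, "all_n": True})
            continue
        freq = counts / total
        nz = freq[freq > 0]
        h = float(-(nz * np.log2(nz)).sum())
        rows.append({"position": i, **{b: float(freq[k]) for k, b in enumerate(_BASES)},
                     "ic": 2.0 - h, "all_n": False})
    return pd.DataFrame(rows)
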