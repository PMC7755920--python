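"""Synthetic CAGE data with the statistical structure the analysis assumes.

Real two-condition CAGE of growing oocytes contrasts a WT sample, where the
oocyte-specific machinery drives sharp, W-box-directed initiation, with a
knockout where only broad, TATA-less initiation remains.  The generator
reproduces exactly the features the pipeline exploits, with ground truth
for recovery tests:

* per-position tag counts whose reverse-cumulative distribution is a power
  law (Zipf) with configurable exponent;
* sharp promoters (small Gaussian TSS spread) carrying a planted W-box
  (8-mer over {A, T}) in the -31..-24 window of the WT dominant TSS,
  expressed in the WT condition only;
* broad TATA-less promoters (large spread) dominated by the mutant
  condition, with a fraction of WT signal at the same positions so that
  position-level subtraction has work to do;
* dual-code shifting promoters: two TSS components a fixed offset apart,
  used with opposite mixture weights in the two conditions.

Conditions are named "wt" and "mutant"; tag totals are conserved exactly
and every sampling step is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CtssDataset

__all__ = [
    "PromoterSpec",
    "default_specs",
    "generate_genome",
    "plant_promoters",
    "simulate_ctss",
    "simulate_study",
    "sample_power_law_counts",
    "dataset_from_counts",
    "CONDITIONS",
]

CONDITIONS = ("wt", "mutant")

TRUTH_COLUMNS = [
    "promoter_id", "chrom", "strand", "promoter_class",
    "dominant_tss_wt", "dominant_tss_mutant",
    "tss_spread_sd", "wbox_start", "wbox_end",
    "true_shift_offset", "expected_expression_rank", "zipf_weight",
    "expr_weight_wt", "expr_weight_mutant", "mix_wt", "mix_mutant",
]

_CLASS_DEFAULTS = {
    # (tss_spread_sd, condition_weights, shift_offset, mixture)
    "sharp_wbox": (1.0, (1.0, 0.0), 0),
    "sharp_nomotif": (1.0, (1.0, 0.0), 0),
    "broad": (25.0, (0.2, 1.0), 0),
    "shifting": (2.0, (0.9, 0.1), 50),
}


@dataclass
class PromoterSpec:
    """One homogeneous batch of synthetic promoters.

    ``condition_weights`` are per-condition expression weights for the
    sharp/broad classes; for the shifting class they are the per-condition
    mixture weights P(5' component) and expression is equal in both
    conditions.
    """

    promoter_class: str
    n: int
    tss_spread_sd: float | None = None
    wbox_offset_range: tuple[int, int] = (-31, -24)
    shift_offset: int | None = None
    condition_weights: tuple[float, float] | None = None
    expression_zipf_alpha: float = 1.9

    def __post_init__(self) -> None:
        if self.promoter_class not in _CLASS_DEFAULTS:
            raise ValueError(f"unknown promoter class {self.promoter_class!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        sd, cw, shift = _CLASS_DEFAULTS[self.promoter_class]
        if self.tss_spread_sd is None:
            self.tss_spread_sd = sd
        if self.condition_weights is None:
            self.condition_weights = cw
        if self.shift_offset is None:
            self.shift_offset = shift if self.promoter_class == "shifting" else 0
        if self.promoter_class != "shifting":
            self.shift_offset = 0
        if self.tss_spread_sd < 0:
            raise ValueError("tss_spread_sd must be >= 0")
        if not all(0.0 <= w <= 1.0 for w in self.condition_weights):
            raise ValueError("condition weights must lie in [0, 1]")
        if self.expression_zipf_alpha <= 1.0:
            raise ValueError("expression_zipf_alpha must be > 1")


def default_specs(n_sharp: int = 500, n_broad: int = 500, n_shifting: int = 100) -> list[PromoterSpec]:
    """The standard two-condition study composition."""
    return [
        PromoterSpec("sharp_wbox", n_sharp),
        PromoterSpec("broad", n_broad),
        PromoterSpec("shifting", n_shifting),
    ]


def generate_genome(n_chroms: int, chrom_length: int, gc_content: float, seed: int) -> dict[str, str]:
    """Random genome with the requested GC content, one dict entry per chrom."""
    if chrom_length < 1000:
        raise ValueError("chrom_length must be >= 1000")
    if not (0.0 < gc_content < 1.0):
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(rng.choice(bases, size=chrom_length, p=[at, gc, gc, at]))
        for i in range(n_chroms)
    }


def _zipf_weights(n: int, alpha: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-CDF Pareto weights at rank quantiles, shuffled over promoters.

    Rank r gets weight ((r - 0.5)/n)^(-1/alpha), so the weight CCDF is
    proportional to w^-alpha over the truncated support ranks 1..n.
    """
    ranks = rng.permutation(n) + 1
    weights = ((ranks - 0.5) / n) ** (-1.0 / alpha)
    return weights, ranks


def plant_promoters(
    genome: dict[str, str],
    specs: Sequence[PromoterSpec],
    min_spacing: int = 1000,
    seed: int = 0,
    wbox_pwm=None,
) -> pd.DataFrame:
    """Place promoters on the genome and write W-boxes into sharp ones.

    Mutates ``genome`` in place only inside planted motif intervals.
    Returns the ground-truth table (TRUTH_COLUMNS).  Raises when the
    genome cannot hold all promoters at ``min_spacing``.
    """
    rng = np.random.default_rng(seed)
    margin = 400
    slots = []
    for chrom, seq in genome.items():
        usable = len(seq) - 2 * margin
        k = usable // min_spacing + 1 if usable >= 0 else 0
        for i in range(k):
            slots.append((chrom, margin + i * min_spacing))
    n_total = sum(s.n for s in specs)
    if n_total > len(slots):
        raise ValueError(
            f"insufficient genome space: {n_total} promoters need {n_total} slots, "
            f"only {len(slots)} available at spacing {min_spacing}"
        )
    slot_idx = rng.permutation(len(slots))[:n_total]
    jitter = rng.integers(0, max(min_spacing // 5, 1), size=n_total)
    strands = rng.choice(["+", "-"], size=n_total)

    mutable = {c: list(s) for c, s in genome.items()}
    rows = []
    pid = 0
    cursor = 0
    for spec in specs:
        if spec.n == 0:
            continue
        weights, ranks = _zipf_weights(spec.n, spec.expression_zipf_alpha, rng)
        for j in range(spec.n):
            chrom, base = slots[slot_idx[cursor]]
            strand = strands[cursor]
            tss = int(base + jitter[cursor])
            cursor += 1
            sign = 1 if strand == "+" else -1
            shift = int(spec.shift_offset)
            tss_b = tss + sign * shift
            wbox_start = wbox_end = np.nan
            if spec.promoter_class == "sharp_wbox":
                lo_rel, hi_rel = spec.wbox_offset_range
                motif_len = hi_rel - lo_rel + 1
                if wbox_pwm is not None:
                    probs = wbox_pwm.freq
                    motif = "".join(
                        "ACGT"[rng.choice(4, p=probs[:, k] / probs[:, k].sum())]
                        for k in range(motif_len)
                    )
                else:
                    motif = "".join(rng.choice(["A", "T"], size=motif_len))
                if strand == "+":
                    g_start, g_end = tss + lo_rel, tss + hi_rel
                    written = motif
                else:
                    g_start, g_end = tss - hi_rel, tss - lo_rel
                    written = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                if g_start < 1 or g_end > len(genome[chrom]):
                    raise ValueError("motif interval leaves the chromosome; increase margins")
                mutable[chrom][g_start - 1 : g_end] = list(written)
                wbox_start, wbox_end = g_start, g_end
            if spec.promoter_class == "shifting":
                mix_wt, mix_mut = spec.condition_weights
                ew_wt = ew_mut = 1.0
            else:
                mix_wt = mix_mut = 1.0
                ew_wt, ew_mut = spec.condition_weights
            dom_wt = tss if mix_wt >= 0.5 else tss_b
            dom_mut = tss if mix_mut >= 0.5 else tss_b
            rows.append(
                (f"P{pid}", chrom, strand, spec.promoter_class, dom_wt, dom_mut,
                 spec.tss_spread_sd, wbox_start, wbox_end,
                 shift, int(ranks[j]), float(weights[j]),
                 ew_wt, ew_mut, mix_wt, mix_mut)
            )
            pid += 1
    for chrom in genome:
        genome[chrom] = "".join(mutable[chrom])
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def simulate_ctss(
    truth: pd.DataFrame,
    condition: str,
    total_tags: int,
    seed: int,
    chrom_sizes: dict[str, int] | None = None,
) -> CtssDataset:
    """Draw a CTSS dataset for one condition; counts sum to ``total_tags``.

    Per-promoter totals are multinomial with Zipf-law expression weights
    scaled by the condition's expression weight; tag positions are the
    promoter's component TSS (mixture-weighted for shifting promoters) plus
    rounded Gaussian spread.
    """
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    w = truth["zipf_weight"].to_numpy() * truth[f"expr_weight_{condition}"].to_numpy()
    if w.sum() <= 0:
        raise ValueError(f"no promoter is expressed in condition {condition!r}")
    alloc = rng.multinomial(total_tags, w / w.sum())
    mix = truth[f"mix_{condition}"].to_numpy()
    sign = np.where(truth["strand"].to_numpy() == "+", 1, -1)
    tss_a = np.where(mix >= 0.5,
                     truth[f"dominant_tss_{condition}"].to_numpy(),
                     truth[f"dominant_tss_{condition}"].to_numpy() - sign * truth["true_shift_offset"].to_numpy())
    # tss_a is always the 5' component; the 3' component sits shift further along
    tss_b = tss_a + sign * truth["true_shift_offset"].to_numpy()
    sds = truth["tss_spread_sd"].to_numpy(dtype=float)
    chroms = truth["chrom"].to_numpy()
    strands = truth["strand"].to_numpy()

    parts = []
    for i in np.flatnonzero(alloc):
        k = int(alloc[i])
        use_a = rng.random(k) < mix[i]
        centers = np.where(use_a, tss_a[i], tss_b[i])
        pos = centers + np.rint(rng.normal(0.0, sds[i], size=k)).astype(np.int64)
        hi = chrom_sizes.get(chroms[i]) if chrom_sizes else None
        pos = np.clip(pos, 1, hi)
        upos, ucnt = np.unique(pos, return_counts=True)
        parts.append(pd.DataFrame({"chrom": chroms[i], "pos": upos, "strand": strands[i], "count": ucnt}))
    if not parts:
        df = pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
    else:
        df = pd.concat(parts, ignore_index=True)
    return CtssDataset(df, sample_id=condition)


def simulate_study(
    seed: int = 0,
    specs: Sequence[PromoterSpec] | None = None,
    n_chroms: int = 2,
    chrom_length: int = 700_000,
    gc_content: float = 0.42,
    total_tags: int = 1_000_000,
    min_spacing: int = 1000,
):
    """Full two-condition synthetic study.

    Returns ``(genome, truth, datasets)`` with datasets keyed by condition.
    Seeds for the genome, planting and each condition are derived from
    ``seed`` so the whole study is reproducible from one integer.
    """
    if specs is None:
        specs = default_specs()
    ss = np.random.SeedSequence(seed)
    s_gen, s_plant, s_wt, s_mut = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    genome = generate_genome(n_chroms, chrom_length, gc_content, s_gen)
    truth = plant_promoters(genome, specs, min_spacing=min_spacing, seed=s_plant)
    sizes = {c: len(s) for c, s in genome.items()}
    datasets = {
        "wt": simulate_ctss(truth, "wt", total_tags, s_wt, chrom_sizes=sizes),
        "mutant": simulate_ctss(truth, "mutant", total_tags, s_mut, chrom_sizes=sizes),
    }
    return genome, truth, datasets


def sample_power_law_counts(
    n_positions: int,
    alpha: float = 1.9,
    seed: int = 0,
    count_cap: int = 150,
) -> np.ndarray:
    """I.i.d. per-position tag counts with reverse-cumulative slope alpha.

    Counts are floor(U^(-1/alpha)) so that P(count >= x) = x^-alpha
    exactly, truncated at ``count_cap`` (finite library depth keeps the
    empirical log-log law linear over its populated range).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    x = np.floor(rng.random(n_positions) ** (-1.0 / alpha)).astype(np.int64)
    return np.clip(x, 1, count_cap)


def dataset_from_counts(counts, chrom: str = "chrS", strand: str = "+",
                        start: int = 1, spacing: int = 2, sample_id: str = "synthetic") -> CtssDataset:
    """Lay counts out at evenly spaced positions on one strand."""
    counts = np.asarray(counts, dtype=np.int64)
    pos = start + spacing * np.arange(counts.size)
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand, "count": counts})
    return CtssDataset(df, sample_id=sample_id)
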