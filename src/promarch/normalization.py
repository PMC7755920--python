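"""Power-law normalization of CAGE tag counts.

CAGE per-position tag counts follow an approximate power law: the reverse
cumulative N(x) (number of positions with count >= x) is close to linear in
log-log space.  Samples of different depth are made comparable by fitting
each sample's law on a fixed count range and mapping every raw count onto a
common referent law with slope ``alpha`` (default 1.53) and total signal
``T`` (default 10^6 tags), yielding tags-per-million-like values.

The map is the unique monotone transform equating the two reverse-cumulative
laws: with the fitted sample law N_s(x) = B_s x^(-alpha_s) and the referent
N_r(y) = B_r y^(-alpha_r), B_r = T / zeta(alpha_r) (so that the referent's
total tag count sum_{x>=1} N_r(x) equals T), a raw count x maps to

    y = (B_s x^(-alpha_s) / B_r)^(-1/alpha_r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import zeta

from .io import CtssDataset

__all__ = [
    "PowerLawFit",
    "reverse_cumulative",
    "fit_power_law",
    "normalize_power_law",
    "DegenerateFitError",
]


class DegenerateFitError(ValueError):
    """Too few usable points in the fit range to fit a power law."""


@dataclass(frozen=True)
class PowerLawFit:
    alpha_sample: float
    intercept_sample: float          # log10 B_s
    fit_range: tuple[int, int]
    n_points_fit: int
    alpha_ref: float = 1.53
    total_ref: float = 1e6

    @property
    def b_sample(self) -> float:
        return 10.0 ** self.intercept_sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "alpha_sample": self.alpha_sample,
                    "intercept_log10": self.intercept_sample,
                    "n_points_fit": self.n_points_fit,
                    "fit_lo": self.fit_range[0],
                    "fit_hi": self.fit_range[1],
                    "alpha_ref": self.alpha_ref,
                    "total_ref": self.total_ref,
                }
            ]
        )


@lru_cache(maxsize=None)
def _zeta(alpha: float) -> float:
    return float(zeta(alpha, 1))


def reverse_cumulative(values) -> pd.DataFrame:
    """Tabulate N(x) = number of entries >= x at every distinct value.

    Accepts a CtssDataset (raw counts), a DataFrame with a count/tpm
    column, or a plain array of values.  N is non-increasing and
    N(min value) equals the number of positions.
    """
    arr = _as_values(values)
    if arr.size == 0:
        raise ValueError("empty dataset: reverse cumulative undefined")
    vals, cnts = np.unique(arr, return_counts=True)
    n_ge = cnts[::-1].cumsum()[::-1]
    return pd.DataFrame({"x": vals, "n_ge": n_ge})


def _as_values(values) -> np.ndarray:
    if isinstance(values, CtssDataset):
        return values.df["count"].to_numpy()
    if isinstance(values, pd.DataFrame):
        col = "count" if "count" in values.columns else "tpm"
        return values[col].to_numpy()
    return np.asarray(values)


def fit_power_law(values, fit_range: tuple[int, int] = (5, 1000), alpha_ref: float = 1.53,
                  total_ref: float = 1e6) -> PowerLawFit:
    """Least-squares line through (log10 x, log10 N(x)) inside the fit range.

    ``alpha_sample`` is minus the slope.  Raises DegenerateFitError with
    fewer than two usable points.
    """
    lo, hi = fit_range
    if not (1 <= lo < hi):
        raise ValueError("fit range lower bound must be >= 1 and < upper")
    rc = reverse_cumulative(values)
    m = (rc["x"] >= lo) & (rc["x"] <= hi) & (rc["n_ge"] > 0)
    if int(m.sum()) < 2:
        raise DegenerateFitError(
            f"only {int(m.sum())} distinct count values in [{lo}, {hi}]; cannot fit"
        )
    lx = np.log10(rc.loc[m, "x"].to_numpy(dtype=float))
    ln = np.log10(rc.loc[m, "n_ge"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(lx, ln, 1)
    return PowerLawFit(
        alpha_sample=float(-slope),
        intercept_sample=float(intercept),
        fit_range=(lo, hi),
        n_points_fit=int(m.sum()),
        alpha_ref=alpha_ref,
        total_ref=total_ref,
    )


def _power_law_map(x: np.ndarray, fit: PowerLawFit) -> np.ndarray:
    b_r = fit.total_ref / _zeta(fit.alpha_ref)
    x = np.asarray(x, dtype=float)
    return (fit.b_sample * x ** (-fit.alpha_sample) / b_r) ** (-1.0 / fit.alpha_ref)


def normalize_power_law(dataset: CtssDataset, fit: PowerLawFit | None = None,
                        fit_range: tuple[int, int] = (5, 1000), alpha: float = 1.53,
                        total: float = 1e6) -> tuple[CtssDataset, PowerLawFit | None]:
    """Fill ``tpm`` by quantile-matching raw counts onto the referent law.

    The map is strictly increasing, so equal raw counts get equal tpm and
    count order is preserved.  When the sample has too few distinct counts
    to fit (degenerate fit), falls back to simple tags-per-million
    (count * 10^6 / total_raw) with a warning, returning fit None.
    """
    df = dataset.df.copy()
    if len(df) == 0:
        raise ValueError("empty dataset: nothing to normalize")
    if fit is None:
        try:
            fit = fit_power_law(dataset, fit_range=fit_range, alpha_ref=alpha, total_ref=total)
        except DegenerateFitError as exc:
            warnings.warn(
                f"power-law fit degenerate ({exc}); falling back to simple tags per million",
                RuntimeWarning,
                stacklevel=2,
            )
            df["tpm"] = df["count"].to_numpy(dtype=float) * 1e6 / dataset.total_raw
            return CtssDataset(df, sample_id=dataset.sample_id), None
    df["tpm"] = _power_law_map(df["count"].to_numpy(), fit)
    return CtssDataset(df, sample_id=dataset.sample_id), fit
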