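"""Growth-rate estimation from cell-count time series.

Specific growth rates are the slope of the ordinary least squares
regression of ln(cell concentration) on experimental day over the
exponential phase; the exponential window can be detected automatically or
supplied explicitly.  Rates are in day^-1, times in days, ln is natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthSeries",
    "GrowthRateEstimate",
    "LagResult",
    "UnbalancedDesignError",
    "detect_exponential_phase",
    "growth_rate",
    "stationary_max",
    "lag_time",
    "generations",
    "two_way_anova",
]


class UnbalancedDesignError(ValueError):
    """Two-way ANOVA supports balanced designs with replication only."""


@dataclass(frozen=True)
class GrowthSeries:
    """One replicate's cell-count trajectory at one assay temperature.

    ``observations`` is an ordered sequence of (day, cells_per_ml) pairs
    with strictly increasing days and strictly positive counts.
    """

    sample_id: str
    replicate: int
    temperature_c: float
    observations: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        obs = tuple((float(d), float(c)) for d, c in self.observations)
        object.__setattr__(self, "observations", obs)
        if len(obs) < 2:
            raise ValueError("a growth series needs >= 2 observations")
        days = [d for d, _ in obs]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(c <= 0 for _, c in obs):
            raise ValueError("cell counts must be > 0")

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations])

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for d, c in self.observations])


@dataclass(frozen=True)
class GrowthRateEstimate:
    """OLS growth-rate estimate over one window of a series."""

    mu: float
    window: tuple[float, float]
    r_squared: float
    stderr: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("estimate needs >= 3 points")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of range: {self.r_squared}")


@dataclass(frozen=True)
class LagResult:
    """Lag duration; ``reached`` is False when the threshold was never hit."""

    days: float
    reached: bool


def _ols_loglinear(days: np.ndarray, counts: np.ndarray):
    """Slope, R^2 and slope stderr of ln(counts) on days.

    R^2 is defined as 1 - SSR/SST with the convention R^2 = 1 when the
    response is constant and perfectly fit (SST = SSR = 0).
    """
    y = np.log(counts)
    x = days
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    if sst == 0.0:
        r2 = 1.0 if ssr <= 1e-24 else 0.0
    else:
        r2 = max(0.0, 1.0 - ssr / sst)
    stderr = math.sqrt(ssr / (n - 2) / sxx) if n > 2 else float("nan")
    return slope, r2, stderr


def detect_exponential_phase(
    series: GrowthSeries,
    min_points: int = 3,
    r2_threshold: float = 0.95,
) -> tuple[float, float]:
    """Select the exponential-phase window of a series.

    Enumerates every contiguous window of at least ``min_points``
    observations and returns the one with the steepest log-linear slope
    among windows whose R^2 meets ``r2_threshold``; if no window qualifies,
    the window with the highest R^2 is returned.  Ties are broken by the
    longer window, then the earlier start.

    Returns
    -------
    (first_day, last_day) of the selected window.
    """
    days, counts = series.days, series.counts
    n = days.size
    if n < min_points:
        raise ValueError(
            f"series has {n} observations, need >= {min_points}"
        )

    best_q = None  # (slope, length, -start_day, window)
    best_any = None  # (r2, length, -start_day, window)
    for i in range(n - min_points + 1):
        for j in range(i + min_points, n + 1):
            slope, r2, _ = _ols_loglinear(days[i:j], counts[i:j])
            length = j - i
            window = (float(days[i]), float(days[j - 1]))
            key_any = (r2, length, -days[i], window)
            if best_any is None or key_any[:3] > best_any[:3]:
                best_any = key_any
            if r2 >= r2_threshold:
                key_q = (slope, length, -days[i], window)
                if best_q is None or key_q[:3] > best_q[:3]:
                    best_q = key_q
    chosen = best_q if best_q is not None else best_any
    return chosen[3]


def growth_rate(
    series: GrowthSeries, window: tuple[float, float] | None = None
) -> GrowthRateEstimate:
    """Estimate the specific growth rate over a window of a series.

    The rate is the OLS slope of ln(count) on day; ``r_squared`` and the
    slope standard error come from the same regression.  When ``window`` is
    None the exponential phase is detected automatically.
    """
    if window is None:
        window = detect_exponential_phase(series)
    lo, hi = window
    days, counts = series.days, series.counts
    mask = (days >= lo) & (days <= hi)
    if int(mask.sum()) < 3:
        raise ValueError("window must contain >= 3 points")
    slope, r2, stderr = _ols_loglinear(days[mask], counts[mask])
    return GrowthRateEstimate(
        mu=slope,
        window=(float(lo), float(hi)),
        r_squared=min(r2, 1.0),
        stderr=stderr,
        n_points=int(mask.sum()),
    )


def stationary_max(series: GrowthSeries) -> float:
    """Maximum observed cell count of a series (cells per ml)."""
    return float(series.counts.max())


def lag_time(series: GrowthSeries, fold_threshold: float = 2.0) -> LagResult:
    """First day the count reaches ``fold_threshold`` times the initial count.

    If the threshold is never reached the last observed day is returned
    with ``reached=False``.
    """
    days, counts = series.days, series.counts
    n0 = counts[0]
    hit = np.nonzero(counts >= fold_threshold * n0)[0]
    if hit.size == 0:
        return LagResult(days=float(days[-1]), reached=False)
    return LagResult(days=float(days[hit[0]]), reached=True)


def generations(mu: float, duration: float) -> float:
    """Number of generations: mu * duration / ln 2."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    return mu * duration / math.log(2.0)


def two_way_anova(
    response: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction for balanced designs.

    Sums of squares follow the standard balanced-design decomposition
    (equivalent to type I/II/III under balance).  Requires every factor
    combination to appear with the same number of replicates (>= 2).

    Returns
    -------
    DataFrame indexed by ``factor_a``, ``factor_b``, ``interaction``,
    ``residual`` with columns ``sum_sq, df, F, p`` (F and p are NaN for the
    residual row).
    """
    y = np.asarray(response, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("response and factors must have equal length")

    a_levels = sorted(set(fa.tolist()))
    b_levels = sorted(set(fb.tolist()))
    na, nb = len(a_levels), len(b_levels)
    cell_sizes = {
        (la, lb): int(np.sum((fa == la) & (fb == lb)))
        for la in a_levels
        for lb in b_levels
    }
    sizes = set(cell_sizes.values())
    if 0 in sizes or len(sizes) != 1:
        raise UnbalancedDesignError(
            "two_way_anova requires a balanced design (equal, nonzero cell sizes)"
        )
    n_rep = sizes.pop()
    if n_rep < 2:
        raise UnbalancedDesignError("interaction requires >= 2 replicates per cell")

    grand = y.mean()
    mean_a = {la: y[fa == la].mean() for la in a_levels}
    mean_b = {lb: y[fb == lb].mean() for lb in b_levels}
    mean_ab = {
        (la, lb): y[(fa == la) & (fb == lb)].mean()
        for la in a_levels
        for lb in b_levels
    }

    ss_a = nb * n_rep * sum((mean_a[la] - grand) ** 2 for la in a_levels)
    ss_b = na * n_rep * sum((mean_b[lb] - grand) ** 2 for lb in b_levels)
    ss_ab = n_rep * sum(
        (mean_ab[(la, lb)] - mean_a[la] - mean_b[lb] + grand) ** 2
        for la in a_levels
        for lb in b_levels
    )
    ss_e = float(
        sum(
            np.sum((y[(fa == la) & (fb == lb)] - mean_ab[(la, lb)]) ** 2)
            for la in a_levels
            for lb in b_levels
        )
    )

    df_a = na - 1
    df_b = nb - 1
    df_ab = df_a * df_b
    df_e = na * nb * (n_rep - 1)

    def f_and_p(ss: float, df: int) -> tuple[float, float]:
        ms_e = ss_e / df_e
        if ms_e == 0.0:
            if ss <= 1e-24:
                return 0.0, 1.0
            return float("inf"), 0.0
        f_val = (ss / df) / ms_e
        return f_val, float(stats.f.sf(f_val, df, df_e))

    fa_f, fa_p = f_and_p(ss_a, df_a)
    fb_f, fb_p = f_and_p(ss_b, df_b)
    fab_f, fab_p = f_and_p(ss_ab, df_ab)

    return pd.DataFrame(
        {
            "sum_sq": [ss_a, ss_b, ss_ab, ss_e],
            "df": [df_a, df_b, df_ab, df_e],
            "F": [fa_f, fb_f, fab_f, np.nan],
            "p": [fa_p, fb_p, fab_p, np.nan],
        },
        index=["factor_a", "factor_b", "interaction", "residual"],
    )
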