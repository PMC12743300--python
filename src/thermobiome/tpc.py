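"""Thermal performance curves: Norberg model evaluation, fitting and traits.

The model is the Eppley-envelope-times-quadratic curve

    f(T) = a * exp(b*T) * [1 - ((T - z) / (w/2))**2]

with ``a > 0`` (scale, day^-1), ``b`` (exponential rise, degC^-1), ``z``
(centre of the quadratic term, degC) and ``w`` (niche width, degC).  The
curve is positive exactly on the open interval ``(z - w/2, z + w/2)`` and
unimodal there, so the critical thermal limits are the bracket roots and the
optimum has a closed form used as an oracle for the numerical maximiser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NorbergParams",
    "ThermalTraits",
    "FitResult",
    "MultiStartConfig",
    "InsufficientDataError",
    "DegenerateDataError",
    "norberg_growth",
    "t_opt_closed_form",
    "fit_norberg",
    "derive_traits",
    "compare_traits",
    "thermal_reaction_norm",
]


class InsufficientDataError(ValueError):
    """Too few observations or distinct temperatures to fit the curve."""


class DegenerateDataError(ValueError):
    """Observations carry no positive growth signal."""


@dataclass(frozen=True)
class NorbergParams:
    """Parameters of the thermal performance curve.

    Attributes
    ----------
    a : float
        Eppley curve coefficient (day^-1); must be positive.
    b : float
        Eppley curve exponent (degC^-1); may be negative or zero.
    z : float
        Location of the maximum of the quadratic term (degC).
    w : float
        Temperature niche width (degC); must be positive.
    """

    a: float
    b: float
    z: float
    w: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be > 0, got {self.a}")
        if not (self.w > 0):
            raise ValueError(f"w must be > 0, got {self.w}")

    @property
    def ct_min(self) -> float:
        """Lower root of the curve, z - w/2."""
        return self.z - self.w / 2.0

    @property
    def ct_max(self) -> float:
        """Upper root of the curve, z + w/2."""
        return self.z + self.w / 2.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.z, self.w], dtype=float)


@dataclass(frozen=True)
class ThermalTraits:
    """Derived thermal traits of a performance curve.

    mu_max (day^-1) is the rate at the optimum t_opt (degC); ct_min/ct_max
    (degC) are the temperatures of zero growth; b80 (degC) is the width of
    the interval where performance is at least 80% of mu_max.
    """

    mu_max: float
    t_opt: float
    ct_min: float
    ct_max: float
    b80: float

    def __post_init__(self) -> None:
        if not (self.ct_min < self.t_opt < self.ct_max):
            raise ValueError(
                f"require ct_min < t_opt < ct_max, got "
                f"({self.ct_min}, {self.t_opt}, {self.ct_max})"
            )
        if not (self.mu_max > 0):
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not (0.0 <= self.b80 < self.ct_max - self.ct_min):
            raise ValueError("b80 must lie in [0, ct_max - ct_min)")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start least-squares fit."""

    params: NorbergParams
    ssr: float
    n_obs: int
    converged: bool
    n_starts_tried: int


@dataclass(frozen=True)
class MultiStartConfig:
    """Initialization grid for :func:`fit_norberg`.

    ``z`` starts at quantiles of the observed temperatures, ``w`` at
    multiples of the observed temperature span, ``b`` at zero and the
    canonical Eppley exponent 0.063 degC^-1; ``a`` is rescaled so each start
    curve peaks near the largest observed rate.
    """

    z_quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    w_factors: tuple[float, ...] = (0.8, 1.2, 1.6)
    b_values: tuple[float, ...] = (0.0, 0.063)


def norberg_growth(temperature, params: NorbergParams):
    """Evaluate the thermal performance curve.

    Parameters
    ----------
    temperature : float or array-like
        Assay temperature(s) in degC.
    params : NorbergParams

    Returns
    -------
    float or ndarray
        Growth rate(s) in day^-1; negative outside (z - w/2, z + w/2).
    """
    t = np.asarray(temperature, dtype=float)
    half = params.w / 2.0
    u = (t - params.z) / half
    out = params.a * np.exp(params.b * t) * (1.0 - u * u)
    return float(out) if np.isscalar(temperature) or out.ndim == 0 else out


def t_opt_closed_form(params: NorbergParams) -> float:
    """Closed-form optimum temperature.

    Setting df/dT = 0 gives t_opt = z + (sqrt(1 + (b*w/2)^2) - 1)/b, written
    here in the algebraically equivalent form b*(w/2)^2 / (sqrt(...) + 1)
    which is finite and exact in the symmetric limit b -> 0.
    """
    half = params.w / 2.0
    bh = params.b * half
    return params.z + params.b * half * half / (math.sqrt(1.0 + bh * bh) + 1.0)


def _coerce_observations(observations) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(observations, pd.DataFrame):
        cols = list(observations.columns)
        tcol = "temperature_c" if "temperature_c" in cols else cols[0]
        rcol = (
            "growth_rate_per_day" if "growth_rate_per_day" in cols else cols[-1]
        )
        temps = observations[tcol].to_numpy(dtype=float)
        rates = observations[rcol].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(observations), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("observations must be (temperature, rate) pairs")
        temps, rates = arr[:, 0], arr[:, 1]
    return temps, rates


def fit_norberg(
    observations,
    starts: MultiStartConfig | None = None,
    tol: float = 1e-12,
) -> FitResult:
    """Fit the Norberg curve to (temperature, growth rate) observations.

    Multi-start nonlinear least squares: every combination of the start grid
    in `starts` is refined with a trust-region-reflective solver under the
    bounds a > 0, w > 0 (b and z unconstrained); the solution with the
    lowest sum of squared residuals wins, ties broken by the smallest
    parameter-vector norm.  Negative observed rates are retained — they
    constrain the critical thermal limits.

    Parameters
    ----------
    observations : DataFrame or iterable of (temperature, rate) pairs
        DataFrames use columns ``temperature_c``/``growth_rate_per_day``
        when present, otherwise first/last columns.
    starts : MultiStartConfig, optional
    tol : float
        ftol/xtol/gtol passed to the solver.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 observations or fewer than 3 distinct temperatures.
    DegenerateDataError
        No observation with a positive growth rate.
    """
    temps, rates = _coerce_observations(observations)
    n = temps.size
    if n < 4 or np.unique(temps).size < 3:
        raise InsufficientDataError(
            f"need >= 4 observations over >= 3 distinct temperatures, "
            f"got {n} observations over {np.unique(temps).size}"
        )
    if not np.any(rates > 0):
        raise DegenerateDataError("all growth rates are <= 0")

    cfg = starts or MultiStartConfig()
    tmin, tmax = float(temps.min()), float(temps.max())
    span = max(tmax - tmin, 1.0)
    rate_peak = float(rates.max())

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, z, w = theta
        u = (temps - z) / (w / 2.0)
        return a * np.exp(b * temps) * (1.0 - u * u) - rates

    lower = np.array([1e-9, -np.inf, -np.inf, 1e-9])
    upper = np.full(4, np.inf)

    candidates: list[tuple[float, float, np.ndarray, bool]] = []
    n_tried = 0
    for zq in cfg.z_quantiles:
        z0 = float(np.quantile(temps, zq))
        for wf in cfg.w_factors:
            w0 = wf * span
            for b0 in cfg.b_values:
                # scale a so the start curve's envelope matches the data peak
                a0 = max(rate_peak, 1e-3) / math.exp(b0 * z0)
                x0 = np.array([max(a0, 1e-6), b0, z0, max(w0, 1e-3)])
                n_tried += 1
                try:
                    sol = optimize.least_squares(
                        residuals,
                        x0,
                        bounds=(lower, upper),
                        method="trf",
                        ftol=tol,
                        xtol=tol,
                        gtol=tol,
                        max_nfev=2000,
                    )
                except Exception:  # pragma: no cover - solver pathologies
                    continue
                ssr = float(np.sum(sol.fun**2))
                norm = float(np.linalg.norm(sol.x))
                candidates.append((ssr, norm, sol.x, bool(sol.success)))

    if not candidates:  # pragma: no cover
        raise RuntimeError("all optimizer starts failed")

    ssr, _, theta, success = min(candidates, key=lambda c: (c[0], c[1]))
    params = NorbergParams(a=theta[0], b=theta[1], z=theta[2], w=theta[3])
    return FitResult(
        params=params,
        ssr=ssr,
        n_obs=n,
        converged=success,
        n_starts_tried=n_tried,
    )


def derive_traits(params: NorbergParams, fraction: float = 0.8) -> ThermalTraits:
    """Derive thermal traits from curve parameters.

    t_opt comes from bounded numerical maximization of the curve and is
    cross-checked against the closed form (agreement < 1e-6 degC enforced);
    mu_max = f(t_opt); the critical limits are the exact bracket roots
    z -/+ w/2; the performance breadth is the width of the contiguous
    interval where f >= fraction * mu_max, endpoints located by bisection.

    Parameters
    ----------
    params : NorbergParams
    fraction : float
        Performance fraction defining the breadth; 0 < fraction <= 1.
        The default 0.8 yields the 80% breadth.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")

    ct_min = params.ct_min
    ct_max = params.ct_max

    res = optimize.minimize_scalar(
        lambda t: -norberg_growth(t, params),
        bounds=(ct_min, ct_max),
        method="bounded",
        options={"xatol": 1e-10},
    )
    t_opt = float(res.x)
    t_cf = t_opt_closed_form(params)
    if abs(t_opt - t_cf) > 1e-6:  # pragma: no cover - guards optimizer regressions
        raise ArithmeticError(
            f"numerical t_opt {t_opt} disagrees with closed form {t_cf}"
        )
    mu_max = float(norberg_growth(t_opt, params))

    if fraction == 1.0:
        b80 = 0.0
    else:
        target = fraction * mu_max

        def g(t: float) -> float:
            return norberg_growth(t, params) - target

        lo = optimize.bisect(g, ct_min, t_opt, xtol=1e-9)
        hi = optimize.bisect(g, t_opt, ct_max, xtol=1e-9)
        b80 = float(hi - lo)

    return ThermalTraits(
        mu_max=mu_max, t_opt=t_opt, ct_min=ct_min, ct_max=ct_max, b80=b80
    )


_TRAIT_NAMES = ("mu_max", "t_opt", "ct_min", "ct_max", "b80")


def _pooled_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student's t with a zero-variance guard."""
    nx, ny = x.size, y.size
    df = nx + ny - 2
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    diff = float(np.mean(x) - np.mean(y))
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def compare_traits(
    group_a: Sequence[ThermalTraits], group_b: Sequence[ThermalTraits]
) -> pd.DataFrame:
    """Per-trait group comparison by pooled-variance Student's t-test.

    Parameters
    ----------
    group_a, group_b : sequences of ThermalTraits
        Per-replicate trait estimates, at least 2 per group.

    Returns
    -------
    DataFrame indexed by trait name with columns
    ``mean_a, se_a, mean_b, se_b, t, df, p``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    rows = {}
    for name in _TRAIT_NAMES:
        x = np.array([getattr(tr, name) for tr in group_a], dtype=float)
        y = np.array([getattr(tr, name) for tr in group_b], dtype=float)
        t, df, p = _pooled_ttest(x, y)
        rows[name] = {
            "mean_a": x.mean(),
            "se_a": x.std(ddof=1) / math.sqrt(x.size),
            "mean_b": y.mean(),
            "se_b": y.std(ddof=1) / math.sqrt(y.size),
            "t": t,
            "df": df,
            "p": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def thermal_reaction_norm(
    params: NorbergParams, grid: Iterable[float]
) -> pd.DataFrame:
    """Tabulate the curve over a temperature grid for reporting/plotting."""
    temps = np.asarray(list(grid), dtype=float)
    if temps.size == 0:
        raise ValueError("temperature grid must be non-empty")
    return pd.DataFrame(
        {
            "temperature_c": temps,
            "growth_rate_per_day": norberg_growth(temps, params),
        }
    )
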