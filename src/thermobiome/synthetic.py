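"""Seeded synthetic data generators for the analysis pipeline.

Every generator is a pure function of its parameters and an integer seed:
identical inputs give identical outputs.  One global seed can be fanned out
into independent substreams with :func:`spawn_seeds`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import AsvTable
from .growth import GrowthSeries
from .metabolites import MetaboliteTable
from .tpc import NorbergParams, ThermalTraits, derive_traits, norberg_growth

__all__ = [
    "TrajectoryModel",
    "CommunityProfile",
    "MetaboliteEffectSpec",
    "UnsupportedSkewError",
    "spawn_seeds",
    "simulate_growth_series",
    "simulate_thermal_observations",
    "params_from_traits",
    "simulate_asv_table",
    "simulate_metabolite_table",
]

_RANKS = ("genus", "family", "order", "phylum")


class UnsupportedSkewError(ValueError):
    """Trait inversion only supports warm-skewed (b >= 0) curves."""


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent substream seeds from one global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


@dataclass(frozen=True)
class TrajectoryModel:
    """Logistic-with-lag cell-count trajectory model.

    Flat at ``n0`` until ``lag_days``, then logistic growth at rate ``mu``
    towards ``carrying_capacity``; measurement noise is multiplicative
    lognormal with log-sd ``noise_sigma``.
    """

    n0: float
    mu: float
    carrying_capacity: float
    lag_days: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.n0 > 0):
            raise ValueError(f"n0 must be > 0, got {self.n0}")
        if not (self.carrying_capacity >= self.n0):
            raise ValueError("carrying_capacity must be >= n0")
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def expectation(self, t) -> np.ndarray:
        """Noise-free trajectory: n0 before the lag, logistic afterwards."""
        t = np.asarray(t, dtype=float)
        te = np.maximum(t - self.lag_days, 0.0)
        k, n0 = self.carrying_capacity, self.n0
        e = np.exp(self.mu * te)
        return k * n0 * e / (k + n0 * (e - 1.0))


@dataclass(frozen=True)
class CommunityProfile:
    """Expected structure of one group's synthetic ASV community.

    Rank-1 expected relative abundance is ``dominant_fraction``; the
    remaining mass ``1 - dominant_fraction`` is spread over the other
    ``n_asvs - 1`` ranks as a renormalized geometric tail with ratio
    ``tail_decay``.
    """

    n_asvs: int
    dominant_fraction: float
    tail_decay: float
    depth: int
    n_replicates: int = 3
    taxonomy_depth: int = 4

    def __post_init__(self) -> None:
        if self.n_asvs < 1:
            raise ValueError("n_asvs must be >= 1")
        if not (0.0 < self.dominant_fraction < 1.0):
            raise ValueError("dominant_fraction must be in (0, 1)")
        if not (0.0 < self.tail_decay <= 1.0):
            raise ValueError("tail_decay must be in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_asvs < 2:
            raise ValueError(
                "need >= 2 ASVs to place the dominant taxon plus a tail"
            )

    def expected_abundances(self) -> np.ndarray:
        """Expected relative abundances by rank; sums to 1."""
        n_tail = self.n_asvs - 1
        tail = self.tail_decay ** np.arange(n_tail, dtype=float)
        tail *= (1.0 - self.dominant_fraction) / tail.sum()
        return np.concatenate(([self.dominant_fraction], tail))


@dataclass(frozen=True)
class MetaboliteEffectSpec:
    """Class-level lognormal effect model for synthetic metabolite tables."""

    class_map: Mapping[str, str]
    baseline_mean: Mapping[str, float]
    group_fold: Mapping[str, float]
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for fold in self.group_fold.values():
            if not (fold > 0):
                raise ValueError("group_fold values must be > 0")
        unknown = set(self.class_map.values()) - set(self.group_fold)
        if unknown:
            raise ValueError(
                f"classes without a group_fold entry: {sorted(unknown)}"
            )
        missing = set(self.class_map) - set(self.baseline_mean)
        if missing:
            raise ValueError(
                f"metabolites without a baseline_mean: {sorted(missing)}"
            )


def simulate_growth_series(
    model: TrajectoryModel,
    days: Sequence[float],
    seed: int,
    sample_id: str = "S1",
    replicate: int = 1,
    temperature_c: float = 26.0,
) -> GrowthSeries:
    """Simulate one cell-count trajectory at the given sampling days."""
    days_arr = np.asarray(list(days), dtype=float)
    if days_arr.size == 0:
        raise ValueError("days must be non-empty")
    if np.any(np.diff(days_arr) < 0) or np.any(days_arr < 0):
        raise ValueError("days must be non-decreasing and >= 0")
    expect = model.expectation(days_arr)
    rng = np.random.default_rng(seed)
    if model.noise_sigma > 0:
        counts = expect * np.exp(
            rng.normal(0.0, model.noise_sigma, size=days_arr.size)
        )
    else:
        counts = expect
    return GrowthSeries(
        sample_id=sample_id,
        replicate=replicate,
        temperature_c=temperature_c,
        observations=tuple(zip(days_arr.tolist(), counts.tolist())),
    )


def simulate_thermal_observations(
    params: NorbergParams,
    temps: Sequence[float],
    n_reps: int,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Noisy growth-rate observations from a Norberg curve.

    Each observation is the model curve at the assay temperature plus
    Gaussian noise with sd ``noise_sd`` day^-1.

    Returns
    -------
    DataFrame with columns ``temperature_c, replicate, growth_rate_per_day``.
    """
    temps_arr = np.asarray(list(temps), dtype=float)
    if temps_arr.size == 0:
        raise ValueError("temperature list must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        truth = norberg_growth(temps_arr, params)
        obs = truth + (
            rng.normal(0.0, noise_sd, size=temps_arr.size)
            if noise_sd > 0
            else 0.0
        )
        for t, r in zip(temps_arr, np.atleast_1d(obs)):
            rows.append(
                {"temperature_c": t, "replicate": rep, "growth_rate_per_day": r}
            )
    return pd.DataFrame(rows)


def params_from_traits(
    traits: ThermalTraits | Mapping[str, float], verify: bool = True
) -> NorbergParams:
    """Invert thermal traits (mu_max, t_opt, ct_min, ct_max) to curve params.

    The bracket roots fix z = (ct_min + ct_max)/2 and w = ct_max - ct_min;
    with h = w/2 and u* = (t_opt - z)/h the optimum condition gives
    b = 2 u* / (h (1 - u*^2)) and the peak height fixes
    a = mu_max / (exp(b t_opt) (1 - u*^2)).  Only warm-skewed curves
    (t_opt at or above the bracket midpoint, i.e. b >= 0) are supported.

    With ``verify=True`` the forward trait derivation is run on the result
    and must reproduce the inputs within 1e-6.
    """
    if isinstance(traits, Mapping):
        mu_max = float(traits["mu_max"])
        t_opt = float(traits["t_opt"])
        ct_min = float(traits["ct_min"])
        ct_max = float(traits["ct_max"])
    else:
        mu_max, t_opt = traits.mu_max, traits.t_opt
        ct_min, ct_max = traits.ct_min, traits.ct_max

    if not (ct_min < t_opt < ct_max):
        raise ValueError("t_opt must lie strictly inside (ct_min, ct_max)")
    if not (mu_max > 0):
        raise ValueError("mu_max must be > 0")
    z = (ct_min + ct_max) / 2.0
    w = ct_max - ct_min
    if t_opt < z:
        raise UnsupportedSkewError(
            "t_opt below the bracket midpoint implies b < 0 (cold skew), "
            "which this inversion does not support"
        )
    h = w / 2.0
    u = (t_opt - z) / h
    b = 2.0 * u / (h * (1.0 - u * u))
    a = mu_max / (math.exp(b * t_opt) * (1.0 - u * u))
    params = NorbergParams(a=a, b=b, z=z, w=w)

    if verify:
        back = derive_traits(params)
        for name, want in (
            ("mu_max", mu_max),
            ("t_opt", t_opt),
            ("ct_min", ct_min),
            ("ct_max", ct_max),
        ):
            got = getattr(back, name)
            if abs(got - want) > 1e-6 * max(1.0, abs(want)):
                raise ArithmeticError(
                    f"round-trip check failed for {name}: {got} vs {want}"
                )
    return params


def _synth_taxonomy(
    asv_ids: Sequence[str], taxonomy_depth: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Nested synthetic taxonomy: pairs of genera share a family, etc."""
    rows = {}
    for i, asv in enumerate(asv_ids):
        labels = {}
        for depth, rank in enumerate(_RANKS):
            if depth < taxonomy_depth:
                labels[rank] = f"{rank.capitalize()}_{i // (2 ** depth) + 1:02d}"
            else:
                labels[rank] = "unclassified"
        rows[asv] = labels
    return pd.DataFrame.from_dict(rows, orient="index")[list(_RANKS)]


def simulate_asv_table(
    profiles: Mapping[str, CommunityProfile], seed: int
) -> AsvTable:
    """Simulate a multi-group ASV count table.

    Each group's samples are independent multinomial draws at the profile's
    depth from its expected rank-abundance vector.  Groups draw their ASV
    identities from a shared pool so that presence overlaps between groups,
    enabling shared-ASV and extinction accounting downstream.
    """
    if not profiles:
        raise ValueError("need at least one group profile")
    n_groups = len(profiles)
    max_asvs = max(p.n_asvs for p in profiles.values())
    pool_size = max_asvs + max(2, max_asvs // 3)
    pool = [f"ASV{idx + 1:04d}" for idx in range(pool_size)]

    seeds = spawn_seeds(seed, n_groups)
    counts_rows = {}
    sample_rows = {}
    for (group, profile), gseed in zip(sorted(profiles.items()), seeds):
        rng = np.random.default_rng(gseed)
        member_idx = np.sort(
            rng.choice(pool_size, size=profile.n_asvs, replace=False)
        )
        probs = profile.expected_abundances()
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("expected abundances are infeasible")
        for rep in range(1, profile.n_replicates + 1):
            sample = f"{group}_r{rep}"
            draw = rng.multinomial(profile.depth, probs)
            row = dict.fromkeys(pool, 0)
            for idx, c in zip(member_idx, draw):
                row[pool[idx]] = int(c)
            counts_rows[sample] = row
            sample_rows[sample] = {"group": group, "replicate": rep}

    counts = pd.DataFrame.from_dict(counts_rows, orient="index")[pool]
    # drop pool ASVs never observed in any sample
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    max_depth = max(p.taxonomy_depth for p in profiles.values())
    taxonomy = _synth_taxonomy(
        list(counts.columns), max_depth, np.random.default_rng(seed)
    )
    sample_map = pd.DataFrame.from_dict(sample_rows, orient="index")
    return AsvTable(counts=counts, taxonomy=taxonomy, sample_map=sample_map)


def simulate_metabolite_table(
    spec: MetaboliteEffectSpec,
    n_per_group: int,
    seed: int,
    groups: tuple[str, str] = ("A", "B"),
) -> MetaboliteTable:
    """Simulate lognormal metabolite concentrations for two groups.

    Group ``groups[1]`` concentrations are multiplied by the class's
    ``group_fold``.  Replicate noise is lognormal with coefficient of
    variation ``cv`` (cv = 0 gives exact class-fold ratios by construction).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    metabolites = sorted(spec.class_map)
    sigma = math.sqrt(math.log1p(spec.cv**2)) if spec.cv > 0 else 0.0
    rng = np.random.default_rng(seed)

    conc_rows = {}
    sample_rows = {}
    for gi, group in enumerate(groups):
        for rep in range(1, n_per_group + 1):
            sample = f"{group}_r{rep}"
            row = {}
            for met in metabolites:
                base = spec.baseline_mean[met]
                fold = spec.group_fold[spec.class_map[met]] if gi == 1 else 1.0
                noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                row[met] = base * fold * noise
            conc_rows[sample] = row
            sample_rows[sample] = {"group": group, "replicate": rep}

    concentrations = pd.DataFrame.from_dict(conc_rows, orient="index")[
        metabolites
    ]
    sample_map = pd.DataFrame.from_dict(sample_rows, orient="index")
    return MetaboliteTable(
        concentrations=concentrations,
        class_map=dict(spec.class_map),
        sample_map=sample_map,
    )
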