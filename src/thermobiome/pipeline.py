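"""End-to-end pipeline orchestration from a declarative YAML config.

Stages run in dependency order (simulate -> growth/tpc/diversity/
metabolites -> report); every stage writes TSV outputs plus a JSON manifest
recording inputs, parameters, seed and timings.  Re-running with the same
config and seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .diversity import (
    alpha_diversity,
    bray_curtis,
    extinctions,
    filter_table,
    permanova,
    relative_abundance,
    taxon_group_test,
)
from .growth import detect_exponential_phase, growth_rate, lag_time, stationary_max
from .metabolites import class_fractions, class_group_test, fold_change
from .synthetic import (
    CommunityProfile,
    MetaboliteEffectSpec,
    TrajectoryModel,
    params_from_traits,
    simulate_asv_table,
    simulate_growth_series,
    simulate_metabolite_table,
    simulate_thermal_observations,
    spawn_seeds,
)
from .tpc import compare_traits, derive_traits, fit_norberg

logger = logging.getLogger("thermobiome")

STAGES = ("simulate", "growth", "tpc", "diversity", "metabolites")

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "make_report", "default_config"]


class ConfigError(ValueError):
    """Invalid run configuration; message lists every failure found."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    outdir: Path
    stages: tuple[str, ...]
    options: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        errors: list[str] = []
        stages = raw.get("stages", list(STAGES))
        if isinstance(stages, str):
            stages = [stages]
        if "all" in stages:
            stages = list(STAGES)
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            errors.append(f"unknown stage name(s): {unknown}")
        seed = raw.get("seed")
        if seed is None:
            errors.append("seed is required when any stochastic stage is enabled")
        elif not isinstance(seed, int):
            errors.append(f"seed must be an integer, got {seed!r}")
        outdir = raw.get("outdir")
        if not outdir:
            errors.append("outdir is required")
        if "simulate" not in stages:
            opts = {k: v for k, v in raw.items() if k in STAGES}
            for stage, block in opts.items():
                for key, val in (block or {}).items():
                    if key.endswith(("_path", "input")) and val:
                        if not Path(val).exists():
                            errors.append(
                                f"{stage}.{key}: path does not exist: {val}"
                            )
        if errors:
            raise ConfigError("; ".join(errors))
        options = {k: v for k, v in raw.items() if k not in ("seed", "outdir", "stages")}
        return cls(
            seed=int(seed),
            outdir=Path(outdir),
            stages=tuple(s for s in STAGES if s in stages),
            options=options,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ConfigError("config file must contain a mapping")
        return cls.from_mapping(raw)


def default_config(outdir, seed: int = 42) -> RunConfig:
    """A self-contained demo configuration exercising every stage."""
    raw: dict[str, Any] = {
        "seed": seed,
        "outdir": str(outdir),
        "stages": list(STAGES),
        "simulate": {
            "growth": {
                "groups": {
                    "LA": {
                        "n0": 3e5,
                        "mu": 1.2,
                        "carrying_capacity": 5e8,
                        "lag_days": 3,
                        "noise_sigma": 0.03,
                    },
                    "LW": {
                        "n0": 3e5,
                        "mu": 1.4,
                        "carrying_capacity": 2e8,
                        "lag_days": 4,
                        "noise_sigma": 0.03,
                    },
                },
                "days": list(range(0, 11)),
                "n_replicates": 3,
                "temperature_c": 26.0,
            },
            "thermal": {
                "groups": {
                    "LA": {
                        "mu_max": 2.09,
                        "t_opt": 28.74,
                        "ct_min": 14.2,
                        "ct_max": 38.19,
                    },
                    "LW": {
                        "mu_max": 2.41,
                        "t_opt": 28.95,
                        "ct_min": 14.2,
                        "ct_max": 38.39,
                    },
                },
                "temperatures": [16, 18, 22, 24, 26, 30, 34, 36, 38],
                "n_replicates": 3,
                "noise_sd": 0.1,
            },
            "asv": {
                "groups": {
                    "LA": {
                        "n_asvs": 14,
                        "dominant_fraction": 0.5,
                        "tail_decay": 0.7,
                        "depth": 20000,
                        "n_replicates": 3,
                    },
                    "LW": {
                        "n_asvs": 18,
                        "dominant_fraction": 0.43,
                        "tail_decay": 0.75,
                        "depth": 20000,
                        "n_replicates": 3,
                    },
                }
            },
            "metabolites": {
                "n_per_group": 3,
                "groups": ["LA", "LW"],
                "cv": 0.1,
                "classes": {
                    "amino_acid": {"n": 8, "baseline": 4.0, "fold": 1.6},
                    "carbohydrate": {"n": 4, "baseline": 3.0, "fold": 0.35},
                    "other": {"n": 10, "baseline": 5.0, "fold": 1.0},
                },
            },
        },
        "growth": {"r2_threshold": 0.95, "min_points": 3, "fold_threshold": 2.0},
        "tpc": {"fraction": 0.8},
        "diversity": {
            "n_permutations": 999,
            "drop_singletons": True,
            "drop_taxa": [],
            "rank": "genus",
            "reference_group": "LA",
        },
        "metabolites": {"groups": ["LA", "LW"], "pseudocount": 0.0},
    }
    return RunConfig.from_mapping(raw)


def _stage_simulate(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    opts = cfg.options.get("simulate", {})
    seeds = spawn_seeds(cfg.seed, 4)
    outputs = []

    gopts = opts.get("growth")
    if gopts:
        series = []
        sub_seeds = spawn_seeds(seeds[0], len(gopts["groups"]) * gopts["n_replicates"])
        i = 0
        for group, params in sorted(gopts["groups"].items()):
            model = TrajectoryModel(**params)
            for rep in range(1, gopts["n_replicates"] + 1):
                series.append(
                    simulate_growth_series(
                        model,
                        gopts["days"],
                        seed=sub_seeds[i],
                        sample_id=group,
                        replicate=rep,
                        temperature_c=gopts.get("temperature_c", 26.0),
                    )
                )
                i += 1
        path = tio.write_growth_series(series, outdir / "growth_series.tsv")
        outputs.append(str(path))

    topts = opts.get("thermal")
    if topts:
        frames = []
        for group, traits in sorted(topts["groups"].items()):
            params = params_from_traits(traits)
            df = simulate_thermal_observations(
                params,
                topts["temperatures"],
                n_reps=topts["n_replicates"],
                noise_sd=topts["noise_sd"],
                seed=seeds[1],
            )
            df.insert(0, "group", group)
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        path = tio.write_tsv(df, outdir / "thermal_observations.tsv")
        outputs.append(str(path))

    aopts = opts.get("asv")
    if aopts:
        profiles = {
            g: CommunityProfile(**p) for g, p in aopts["groups"].items()
        }
        table = simulate_asv_table(profiles, seed=seeds[2])
        paths = tio.write_asv_table(
            table,
            outdir / "asv_counts.tsv",
            outdir / "asv_taxonomy.tsv",
            outdir / "asv_samples.tsv",
        )
        outputs.extend(str(p) for p in paths)

    mopts = opts.get("metabolites")
    if mopts:
        class_map, baseline, fold = {}, {}, {}
        for cls, block in mopts["classes"].items():
            fold[cls] = block["fold"]
            for k in range(block["n"]):
                met = f"{cls}_{k + 1:02d}"
                class_map[met] = cls
                baseline[met] = block["baseline"] * (1.0 + 0.1 * k)
        spec = MetaboliteEffectSpec(
            class_map=class_map,
            baseline_mean=baseline,
            group_fold=fold,
            cv=mopts.get("cv", 0.0),
        )
        table = simulate_metabolite_table(
            spec,
            n_per_group=mopts["n_per_group"],
            seed=seeds[3],
            groups=tuple(mopts.get("groups", ("A", "B"))),
        )
        paths = tio.write_metabolite_table(
            table,
            outdir / "metabolite_concentrations.tsv",
            outdir / "metabolite_classes.tsv",
            outdir / "metabolite_samples.tsv",
        )
        outputs.extend(str(p) for p in paths)

    manifest["stages"]["simulate"] = {"outputs": outputs, "params": opts}


def _stage_growth(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    opts = cfg.options.get("growth", {})
    input_path = opts.get("input", outdir / "growth_series.tsv")
    series = tio.read_growth_series(input_path)
    rows = []
    for s in series:
        window = detect_exponential_phase(
            s,
            min_points=int(opts.get("min_points", 3)),
            r2_threshold=float(opts.get("r2_threshold", 0.95)),
        )
        est = growth_rate(s, window)
        lag = lag_time(s, fold_threshold=float(opts.get("fold_threshold", 2.0)))
        if not lag.reached:
            logger.warning(
                "lag threshold never reached for %s rep %s", s.sample_id, s.replicate
            )
        rows.append(
            {
                "sample_id": s.sample_id,
                "temperature_c": s.temperature_c,
                "replicate": s.replicate,
                "mu": est.mu,
                "stderr": est.stderr,
                "r2": est.r_squared,
                "window_start": est.window[0],
                "window_end": est.window[1],
                "lag_days": lag.days,
                "lag_reached": lag.reached,
                "stationary_max": stationary_max(s),
            }
        )
    path = tio.write_tsv(pd.DataFrame(rows), outdir / "growth_estimates.tsv")
    manifest["stages"]["growth"] = {
        "inputs": [str(input_path)],
        "outputs": [str(path)],
        "params": {k: v for k, v in opts.items() if k != "input"},
    }


def _stage_tpc(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    opts = cfg.options.get("tpc", {})
    input_path = opts.get("input", outdir / "thermal_observations.tsv")
    df = pd.read_csv(input_path, sep="\t")
    fraction = float(opts.get("fraction", 0.8))
    if "group" not in df.columns:
        df["group"] = "all"
    rows = []
    traits_by_group: dict[str, list] = {}
    for (group, rep), sub in df.groupby(["group", "replicate"]):
        fit = fit_norberg(sub[["temperature_c", "growth_rate_per_day"]])
        traits = derive_traits(fit.params, fraction=fraction)
        traits_by_group.setdefault(group, []).append(traits)
        rows.append(
            {
                "group": group,
                "replicate": rep,
                "a": fit.params.a,
                "b": fit.params.b,
                "z": fit.params.z,
                "w": fit.params.w,
                "ssr": fit.ssr,
                "converged": fit.converged,
                "mu_max": traits.mu_max,
                "t_opt": traits.t_opt,
                "ct_min": traits.ct_min,
                "ct_max": traits.ct_max,
                "b80": traits.b80,
            }
        )
    path = tio.write_tsv(pd.DataFrame(rows), outdir / "tpc_fits.tsv")
    outputs = [str(path)]
    groups = sorted(traits_by_group)
    if len(groups) == 2 and all(len(traits_by_group[g]) >= 2 for g in groups):
        comp = compare_traits(traits_by_group[groups[0]], traits_by_group[groups[1]])
        comp.insert(0, "group_a", groups[0])
        comp.insert(1, "group_b", groups[1])
        cpath = tio.write_tsv(
            comp.rename_axis("trait").reset_index(), outdir / "tpc_comparison.tsv"
        )
        outputs.append(str(cpath))
    manifest["stages"]["tpc"] = {
        "inputs": [str(input_path)],
        "outputs": outputs,
        "params": {"fraction": fraction},
    }


def _stage_diversity(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    opts = cfg.options.get("diversity", {})
    counts = opts.get("counts_path", outdir / "asv_counts.tsv")
    tax = opts.get("taxonomy_path", outdir / "asv_taxonomy.tsv")
    smap = opts.get("sample_map_path", outdir / "asv_samples.tsv")
    table = tio.read_asv_table(counts, tax, smap)
    table = filter_table(
        table,
        drop_singletons=bool(opts.get("drop_singletons", True)),
        drop_taxa=opts.get("drop_taxa", ()) or (),
    )

    div = alpha_diversity(table)
    p1 = tio.write_tsv(
        div.per_sample.rename_axis("sample_id").reset_index(),
        outdir / "alpha_diversity.tsv",
    )
    flat = div.per_group.copy()
    flat.columns = [f"{m}_{s}" for m, s in flat.columns]
    p2 = tio.write_tsv(
        flat.rename_axis("group").reset_index(), outdir / "alpha_diversity_groups.tsv"
    )

    rank = opts.get("rank", "genus")
    per_sample_ra, _ = relative_abundance(table, rank=rank)
    p3 = tio.write_tsv(
        per_sample_ra.rename_axis("sample_id").reset_index(),
        outdir / f"relative_abundance_{rank}.tsv",
    )

    dist = bray_curtis(table)
    p4 = tio.write_tsv(dist.rename_axis("sample_id").reset_index(), outdir / "bray_curtis.tsv")

    groups = table.sample_map.loc[dist.index, "group"]
    res = permanova(
        dist,
        groups.to_numpy(),
        n_permutations=int(opts.get("n_permutations", 999)),
        seed=cfg.seed,
    )
    perm_df = pd.DataFrame(
        [
            {
                "pseudo_f": res.pseudo_f,
                "df_among": res.df_among,
                "df_within": res.df_within,
                "p": res.p,
                "n_permutations": res.n_permutations,
            }
        ]
    )
    p5 = tio.write_tsv(perm_df, outdir / "permanova.tsv")

    outputs = [str(p) for p in (p1, p2, p3, p4, p5)]
    ref = opts.get("reference_group")
    if ref and ref in table.groups:
        ext_rows = []
        for other in table.groups:
            if other == ref:
                continue
            n_lost, lost = extinctions(table, ref, other)
            ext_rows.append(
                {
                    "reference_group": ref,
                    "target_group": other,
                    "extinctions": n_lost,
                    "asvs": ",".join(lost),
                }
            )
        p6 = tio.write_tsv(pd.DataFrame(ext_rows), outdir / "extinctions.tsv")
        outputs.append(str(p6))

    group_list = table.groups
    if len(group_list) == 2:
        tests = taxon_group_test(
            per_sample_ra, table.sample_map["group"], (group_list[0], group_list[1])
        )
        p7 = tio.write_tsv(
            tests.rename_axis("taxon").reset_index(), outdir / "taxon_tests.tsv"
        )
        outputs.append(str(p7))

    manifest["stages"]["diversity"] = {
        "inputs": [str(counts), str(tax), str(smap)],
        "outputs": outputs,
        "params": {
            "rank": rank,
            "n_permutations": int(opts.get("n_permutations", 999)),
            "drop_singletons": bool(opts.get("drop_singletons", True)),
            "drop_taxa": list(opts.get("drop_taxa", ()) or ()),
        },
    }


def _stage_metabolites(cfg: RunConfig, outdir: Path, manifest: dict) -> None:
    opts = cfg.options.get("metabolites", {})
    conc = opts.get("conc_path", outdir / "metabolite_concentrations.tsv")
    cmap = opts.get("class_map_path", outdir / "metabolite_classes.tsv")
    smap = opts.get("sample_map_path", outdir / "metabolite_samples.tsv")
    table = tio.read_metabolite_table(conc, cmap, smap)

    per_sample, per_group = class_fractions(table)
    p1 = tio.write_tsv(
        per_sample.rename_axis("sample_id").reset_index(),
        outdir / "class_fractions.tsv",
    )
    flat = per_group.copy()
    flat.columns = [f"{c}_{s}" for c, s in flat.columns]
    p2 = tio.write_tsv(
        flat.rename_axis("group").reset_index(), outdir / "class_fractions_groups.tsv"
    )

    groups = opts.get("groups") or sorted(table.sample_map["group"].unique())
    fc = fold_change(
        table, groups[1], groups[0], pseudocount=float(opts.get("pseudocount", 0.0))
    )
    n_err = int((fc["error"] != "").sum())
    if n_err:
        logger.warning("%d metabolites had zero-denominator fold changes", n_err)
    p3 = tio.write_tsv(
        fc.rename_axis("metabolite").reset_index(), outdir / "fold_changes.tsv"
    )

    test_rows = []
    for cls in sorted(set(table.class_map.values())):
        f_val, (dfb, dfw), p = class_group_test(table, cls, (groups[0], groups[1]))
        test_rows.append(
            {"class": cls, "F": f_val, "df_between": dfb, "df_within": dfw, "p": p}
        )
    p4 = tio.write_tsv(pd.DataFrame(test_rows), outdir / "class_tests.tsv")

    manifest["stages"]["metabolites"] = {
        "inputs": [str(conc), str(cmap), str(smap)],
        "outputs": [str(p) for p in (p1, p2, p3, p4)],
        "params": {"groups": list(groups), "pseudocount": float(opts.get("pseudocount", 0.0))},
    }


_RUNNERS = {
    "simulate": _stage_simulate,
    "growth": _stage_growth,
    "tpc": _stage_tpc,
    "diversity": _stage_diversity,
    "metabolites": _stage_metabolites,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    from . import __version__

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "timings_s": {},
    }
    for stage in config.stages:
        logger.info("running stage %s (seed=%d)", stage, config.seed)
        t0 = time.perf_counter()
        try:
            _RUNNERS[stage](config, outdir, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 4)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def assign_letters(
    means: Mapping[str, float], pvalues: Mapping[tuple[str, str], float], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from pairwise p-values.

    Groups share a letter exactly when they belong to a common maximal
    clique of the "not significantly different" graph; cliques are lettered
    in descending order of their best group mean.
    """
    import networkx as nx

    names = sorted(means, key=lambda g: -means[g])
    g = nx.Graph()
    g.add_nodes_from(names)
    for (a, b), p in pvalues.items():
        if p >= alpha:
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    letters = {name: "" for name in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for member in clique:
            letters[member] += letter
    return {name: "".join(sorted(letters[name])) for name in names}


def make_report(outdir, alpha: float = 0.05) -> dict[str, Path]:
    """Summary tables: per-group traits with significance letters and
    per-group alpha diversity with extinction counts.

    Requires the ``tpc`` and/or ``diversity`` stage outputs in ``outdir``.
    """
    outdir = Path(outdir)
    written: dict[str, Path] = {}

    fits_path = outdir / "tpc_fits.tsv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path, sep="\t")
        trait_cols = ["mu_max", "t_opt", "ct_min", "ct_max", "b80"]
        rows = []
        groups = sorted(fits["group"].unique())
        for trait in trait_cols:
            means = {
                g: float(fits.loc[fits["group"] == g, trait].mean()) for g in groups
            }
            ses = {
                g: float(fits.loc[fits["group"] == g, trait].sem(ddof=1))
                for g in groups
            }
            pvals = {}
            for i, ga in enumerate(groups):
                for gb in groups[i + 1 :]:
                    x = fits.loc[fits["group"] == ga, trait].to_numpy()
                    y = fits.loc[fits["group"] == gb, trait].to_numpy()
                    from .tpc import _pooled_ttest

                    _, _, p = _pooled_ttest(x, y)
                    pvals[(ga, gb)] = p
            letters = assign_letters(means, pvals, alpha=alpha)
            for g in groups:
                rows.append(
                    {
                        "trait": trait,
                        "group": g,
                        "mean": means[g],
                        "se": ses[g],
                        "letter": letters[g],
                    }
                )
        path = tio.write_tsv(pd.DataFrame(rows), outdir / "report_traits.tsv")
        written["traits"] = path
    elif not (outdir / "alpha_diversity_groups.tsv").exists():
        raise FileNotFoundError(
            "no stage outputs found in outdir; run the 'tpc' and/or "
            "'diversity' stages first"
        )

    div_path = outdir / "alpha_diversity_groups.tsv"
    if div_path.exists():
        div = pd.read_csv(div_path, sep="\t")
        ext_path = outdir / "extinctions.tsv"
        if ext_path.exists():
            ext = pd.read_csv(ext_path, sep="\t")[
                ["target_group", "extinctions"]
            ].rename(columns={"target_group": "group"})
            div = div.merge(ext, on="group", how="left")
        path = tio.write_tsv(div, outdir / "report_diversity.tsv")
        written["diversity"] = path

    return written
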