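# thermobiome

Analysis toolkit for long-term warming-adaptation experiments on
phototroph–microbiome systems: growth-rate estimation from cell-count time
series, Norberg-type thermal-performance-curve fitting with numerical trait
derivation, ASV-table diversity and extinction accounting, metabolite
class-fraction and fold-change analysis, and seeded synthetic-data
generators so the whole chain is testable without raw instrument data.

## Modules

| module | what it does |
| --- | --- |
| `thermobiome.synthetic` | seeded simulators: logistic-with-lag cell trajectories, Norberg-curve growth-rate observations, multinomial ASV tables with a dominant taxon + geometric tail, lognormal metabolite tables; trait→parameter inversion (`params_from_traits`) |
| `thermobiome.growth` | exponential-window detection, log-linear growth-rate regression, lag time, stationary maximum, generation counts, balanced two-way ANOVA |
| `thermobiome.tpc` | `f(T) = a·e^{bT}·[1 − ((T−z)/(w/2))²]` evaluation, multi-start least-squares fitting, numerical trait derivation (μ_max, T_opt, CT_min, CT_max, B_80) with closed-form cross-checks, pooled-t trait comparison |
| `thermobiome.diversity` | singleton/taxon filtering, relative abundance at any rank, richness / Shannon / Smith–Wilson Evar, extinction and shared-ASV set algebra, Bray–Curtis distances, permutation PERMANOVA, per-taxon group tests |
| `thermobiome.metabolites` | class fractions (percent of total concentration), per-metabolite fold changes, one-way ANOVA on class totals |
| `thermobiome.pipeline` / `thermobiome.cli` | YAML-configured, seeded, manifest-writing orchestration of all stages |

All I/O is plain TSV with one-line headers (see `thermobiome.io`).

## CLI

```bash
# run every stage on built-in demo settings
thermobiome all --outdir out --seed 42

# or stage by stage, optionally from a YAML config
thermobiome simulate --config run.yaml
thermobiome tpc --config run.yaml
thermobiome report --outdir out
```

A config file mirrors the structure produced by
`thermobiome.pipeline.default_config` (stage blocks `simulate`, `growth`,
`tpc`, `diversity`, `metabolites` plus top-level `seed`, `outdir`,
`stages`). Every stage writes its outputs and a `manifest.json` recording
inputs, parameters, seed and timings; identical config + seed reproduce
byte-identical numeric outputs.

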