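"""Community diversity analyses on ASV count tables.

Covers table filtering, relative-abundance aggregation, alpha diversity
(richness, Shannon entropy in nats, Smith-Wilson Evar evenness), extinction
and shared-ASV accounting, Bray-Curtis distances and a permutation
PERMANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AsvTable",
    "DiversitySummary",
    "PermanovaResult",
    "SharedAsvSummary",
    "filter_table",
    "relative_abundance",
    "alpha_diversity",
    "shannon",
    "evar",
    "extinctions",
    "shared_asvs",
    "bray_curtis",
    "permanova",
    "taxon_group_test",
]

RANKS = ("genus", "family", "order", "phylum")


@dataclass(frozen=True)
class AsvTable:
    """Samples x ASVs count table with taxonomy and sample metadata.

    Attributes
    ----------
    counts : DataFrame
        Rows = sample ids, columns = ASV ids, non-negative integer reads.
    taxonomy : DataFrame
        Rows = ASV ids, columns ``genus, family, order, phylum``
        (``"unclassified"`` where unknown).
    sample_map : DataFrame
        Rows = sample ids, columns ``group`` and ``replicate``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sample_map: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        vals = counts.to_numpy()
        if vals.size and (
            np.any(vals < 0) or not np.allclose(vals, np.round(vals))
        ):
            raise ValueError("counts must be non-negative integers")
        missing_samples = set(counts.index) - set(self.sample_map.index)
        if missing_samples:
            raise ValueError(f"samples without a group: {sorted(missing_samples)}")
        if "group" not in self.sample_map.columns:
            raise ValueError("sample_map must have a 'group' column")
        missing_tax = set(counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ValueError(f"ASVs without taxonomy: {sorted(missing_tax)}")
        for rank in RANKS:
            if rank not in self.taxonomy.columns:
                raise ValueError(f"taxonomy missing rank column '{rank}'")

    @property
    def groups(self) -> list[str]:
        return sorted(self.sample_map["group"].unique().tolist())

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.sample_map["group"]):
            raise KeyError(f"unknown group: {group!r}")
        sel = self.sample_map.index[self.sample_map["group"] == group]
        return [s for s in sel if s in self.counts.index]

    def group_presence(self, group: str) -> frozenset[str]:
        """ASVs with >= 1 read in >= 1 replicate of ``group``."""
        sub = self.counts.loc[self.samples_in(group)]
        return frozenset(sub.columns[(sub > 0).any(axis=0)])


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample alpha diversity plus per-group mean +/- SE."""

    per_sample: pd.DataFrame
    per_group: pd.DataFrame


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    df_among: int
    df_within: int
    p: float
    n_permutations: int


@dataclass(frozen=True)
class SharedAsvSummary:
    """Set-algebra summary of per-group ASV presence.

    ``region_counts`` maps each non-empty group subset (sorted tuple) to the
    number of ASVs present in exactly those groups; ``pairwise_shared``
    counts pooled-presence intersections per group pair and
    ``pairwise_replicate_mean`` averages per-replicate-pair intersections.
    """

    presence: dict[str, frozenset[str]]
    region_counts: dict[tuple[str, ...], int]
    intersection_all: int
    pairwise_shared: dict[tuple[str, str], int]
    pairwise_replicate_mean: dict[tuple[str, str], float]


def filter_table(
    table: AsvTable,
    drop_singletons: bool = True,
    drop_taxa: Iterable[str] = (),
) -> AsvTable:
    """Remove singleton ASVs and ASVs matching excluded taxonomy labels.

    Singletons are ASVs whose dataset-wide total count is <= 1.
    ``drop_taxa`` labels are matched against every taxonomy rank (e.g.
    ``{"Mitochondria", "Chloroplast", "Eukaryota"}``).
    """
    keep = pd.Series(True, index=table.counts.columns)
    if drop_singletons:
        keep &= table.counts.sum(axis=0) > 1
    drop = set(drop_taxa)
    if drop:
        tax = table.taxonomy.loc[table.counts.columns, list(RANKS)]
        keep &= ~tax.isin(drop).any(axis=1)
    kept = table.counts.columns[keep]
    return AsvTable(
        counts=table.counts[kept],
        taxonomy=table.taxonomy.loc[kept],
        sample_map=table.sample_map,
    )


def relative_abundance(
    table: AsvTable, rank: str = "asv"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample percent relative abundance aggregated at a taxonomy rank.

    Parameters
    ----------
    table : AsvTable
    rank : str
        One of ``asv, genus, family, order, phylum``.

    Returns
    -------
    (per_sample, per_group)
        ``per_sample``: samples x taxa percentages, each row summing to 100.
        ``per_group``: MultiIndex columns (taxon, {mean, se}) per group.
    """
    if rank not in ("asv",) + RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    if rank == "asv":
        agg = table.counts
    else:
        labels = table.taxonomy.loc[table.counts.columns, rank]
        agg = table.counts.T.groupby(labels).sum().T
    per_sample = agg.div(totals, axis=0) * 100.0

    groups = table.sample_map.loc[per_sample.index, "group"]
    grouped = per_sample.groupby(groups)
    mean = grouped.mean()
    se = grouped.sem(ddof=1)
    per_group = pd.concat({"mean": mean, "se": se}, axis=1).swaplevel(
        axis=1
    ).sort_index(axis=1)
    return per_sample, per_group


def shannon(proportions) -> float:
    """Shannon entropy (nats) of an abundance/proportion vector."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    p = p / p.sum()
    return float(-np.sum(p * np.log(p)))


def evar(abundances) -> float:
    """Smith-Wilson Evar: 1 - (2/pi) arctan(population variance of ln x)."""
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    logs = np.log(x)
    v = float(np.mean((logs - logs.mean()) ** 2))
    return 1.0 - (2.0 / math.pi) * math.atan(v)


def alpha_diversity(table: AsvTable) -> DiversitySummary:
    """Richness, Shannon index (nats) and Evar evenness per sample and group.

    Richness counts ASVs with nonzero reads; Shannon uses read proportions;
    Evar uses the variance of log abundances over the nonzero ASVs (scale
    invariant, so counts and proportions give the same value).
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"empty samples: {bad}")
    rows = {}
    for sample in table.counts.index:
        x = table.counts.loc[sample].to_numpy(dtype=float)
        p = x / x.sum()
        rows[sample] = {
            "richness": int(np.count_nonzero(x)),
            "shannon": shannon(p),
            "evar": evar(x),
            "group": table.sample_map.loc[sample, "group"],
        }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    metrics = per_sample[["richness", "shannon", "evar"]].astype(float)
    grouped = metrics.groupby(per_sample["group"])
    per_group = pd.concat(
        {"mean": grouped.mean(), "se": grouped.sem(ddof=1)}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1)
    return DiversitySummary(per_sample=per_sample, per_group=per_group)


def extinctions(
    table: AsvTable, reference_group: str, target_group: str
) -> tuple[int, list[str]]:
    """ASVs present in the reference group but absent from the target group.

    Presence means >= 1 read in >= 1 replicate of a group (apply
    :func:`filter_table` first to mirror upstream singleton removal).
    """
    ref = table.group_presence(reference_group)
    tgt = table.group_presence(target_group)
    lost = sorted(ref - tgt)
    return len(lost), lost


def shared_asvs(table: AsvTable, groups: Sequence[str]) -> SharedAsvSummary:
    """Set-algebra accounting of ASV presence across groups."""
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    presence = {g: table.group_presence(g) for g in groups}

    all_asvs = frozenset().union(*presence.values())
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(sorted(groups), r):
            inside = set(subset)
            members = [
                a
                for a in all_asvs
                if all(a in presence[g] for g in inside)
                and all(a not in presence[g] for g in presence if g not in inside)
            ]
            region_counts[subset] = len(members)

    intersection_all = len(frozenset.intersection(*presence.values()))

    pairwise_shared = {}
    pairwise_replicate_mean = {}
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        pairwise_shared[(g1, g2)] = len(presence[g1] & presence[g2])
        counts = []
        for s1 in table.samples_in(g1):
            set1 = set(table.counts.columns[table.counts.loc[s1] > 0])
            for s2 in table.samples_in(g2):
                set2 = set(table.counts.columns[table.counts.loc[s2] > 0])
                counts.append(len(set1 & set2))
        pairwise_replicate_mean[(g1, g2)] = float(np.mean(counts))

    return SharedAsvSummary(
        presence=presence,
        region_counts=region_counts,
        intersection_all=intersection_all,
        pairwise_shared=pairwise_shared,
        pairwise_replicate_mean=pairwise_replicate_mean,
    )


def bray_curtis(table: AsvTable, use_proportions: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between samples.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), on per-sample proportions by
    default (robust to unequal depths) or raw counts.
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total count: {bad}")
    mat = table.counts.to_numpy(dtype=float)
    if use_proportions:
        mat = mat / mat.sum(axis=1, keepdims=True)
    dist = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(
        dist, index=table.counts.index, columns=table.counts.index
    )


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous per-group
    terms; pseudo-F = (SS_among/(g-1)) / (SS_within/(n-g)).  The p-value is
    (count of permuted F >= observed + 1) / (n_permutations + 1) under
    unrestricted random permutation of sample labels.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dist must be a square matrix")
    labels = np.asarray(groups)
    if labels.size != d.shape[0]:
        raise ValueError("groups length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs >= 2 samples")

    d2 = d * d
    f_obs = _pseudo_f(d2, codes, uniq.size)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, uniq.size) >= f_obs:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        df_among=int(uniq.size - 1),
        df_within=int(d.shape[0] - uniq.size),
        p=float(p),
        n_permutations=n_permutations,
    )


def taxon_group_test(
    rel_abund: pd.DataFrame,
    sample_groups: Mapping[str, str] | pd.Series,
    groups: tuple[str, str],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-taxon pooled-variance Student's t-test of percent abundances.

    Parameters
    ----------
    rel_abund : DataFrame
        Samples x taxa percent table (as produced by
        :func:`relative_abundance`).
    sample_groups : mapping sample id -> group label.
    groups : pair of group labels to compare (>= 2 replicates each).
    bonferroni : bool
        Multiply p-values by the number of tested taxa (capped at 1).

    Taxa absent (all-zero) in both groups are excluded from the output.
    """
    ga, gb = groups
    gser = pd.Series(sample_groups)
    samples_a = [s for s in rel_abund.index if gser.get(s) == ga]
    samples_b = [s for s in rel_abund.index if gser.get(s) == gb]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 replicates")

    rows = {}
    for taxon in rel_abund.columns:
        x = rel_abund.loc[samples_a, taxon].to_numpy(dtype=float)
        y = rel_abund.loc[samples_b, taxon].to_numpy(dtype=float)
        if np.all(x == 0) and np.all(y == 0):
            continue
        nx, ny = x.size, y.size
        df = nx + ny - 2
        sp2 = (
            (nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)
        ) / df
        diff = float(x.mean() - y.mean())
        if sp2 == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows[taxon] = {
            f"mean_{ga}": x.mean(),
            f"se_{ga}": x.std(ddof=1) / math.sqrt(nx),
            f"mean_{gb}": y.mean(),
            f"se_{gb}": y.std(ddof=1) / math.sqrt(ny),
            "t": t,
            "df": df,
            "p": p,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    if bonferroni and not out.empty:
        out["p"] = np.minimum(out["p"] * len(out), 1.0)
    return out
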