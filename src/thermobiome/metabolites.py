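"""Metabolite class-fraction, fold-change and group-test analyses."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteTable",
    "class_fractions",
    "fold_change",
    "class_group_test",
]


@dataclass(frozen=True)
class MetaboliteTable:
    """Samples x metabolite concentrations with class and group metadata.

    ``concentrations`` holds non-negative values in internally consistent
    (arbitrary) units; ``class_map`` assigns every metabolite to a class
    such as ``amino_acid``, ``carbohydrate`` or ``other``; ``sample_map``
    has a ``group`` column indexed by sample id.
    """

    concentrations: pd.DataFrame
    class_map: Mapping[str, str]
    sample_map: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.concentrations.to_numpy() < 0).any():
            raise ValueError("concentrations must be >= 0")
        missing = set(self.concentrations.columns) - set(self.class_map)
        if missing:
            raise ValueError(f"metabolites without a class: {sorted(missing)}")
        missing_s = set(self.concentrations.index) - set(self.sample_map.index)
        if missing_s:
            raise ValueError(f"samples without a group: {sorted(missing_s)}")
        if "group" not in self.sample_map.columns:
            raise ValueError("sample_map must have a 'group' column")

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.sample_map["group"]):
            raise KeyError(f"unknown group: {group!r}")
        sel = self.sample_map.index[self.sample_map["group"] == group]
        return [s for s in sel if s in self.concentrations.index]

    def class_sums(self) -> pd.DataFrame:
        """Per-sample total concentration of each class."""
        classes = pd.Series(
            {m: self.class_map[m] for m in self.concentrations.columns}
        )
        return self.concentrations.T.groupby(classes).sum().T


def class_fractions(table: MetaboliteTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent contribution of each metabolite class per sample and group.

    Returns
    -------
    (per_sample, per_group)
        ``per_sample``: samples x classes percentages, rows summing to 100.
        ``per_group``: MultiIndex columns (class, {mean, se}) per group.
    """
    sums = table.class_sums()
    totals = sums.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"samples with zero total concentration: {bad}")
    per_sample = sums.div(totals, axis=0) * 100.0
    groups = table.sample_map.loc[per_sample.index, "group"]
    grouped = per_sample.groupby(groups)
    per_group = pd.concat(
        {"mean": grouped.mean(), "se": grouped.sem(ddof=1)}, axis=1
    ).swaplevel(axis=1).sort_index(axis=1)
    return per_sample, per_group


def fold_change(
    table: MetaboliteTable,
    group_num: str,
    group_den: str,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-metabolite fold change of group mean concentrations.

    FC = (mean(numerator group) + pseudocount) /
    (mean(denominator group) + pseudocount); log2FC = log2(FC).  With the
    default pseudocount of 0, metabolites whose denominator mean is zero
    are reported with ``error='zero_denominator'`` and NaN fold changes
    rather than silently dropped.

    Returns
    -------
    DataFrame indexed by metabolite with columns
    ``mean_num, mean_den, fc, log2fc, error``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num_samples = table.samples_in(group_num)
    den_samples = table.samples_in(group_den)
    if not num_samples or not den_samples:
        raise ValueError("each group needs >= 1 sample")

    rows = {}
    for met in table.concentrations.columns:
        m_num = float(table.concentrations.loc[num_samples, met].mean())
        m_den = float(table.concentrations.loc[den_samples, met].mean())
        num = m_num + pseudocount
        den = m_den + pseudocount
        if den == 0.0:
            rows[met] = {
                "mean_num": m_num,
                "mean_den": m_den,
                "fc": float("nan"),
                "log2fc": float("nan"),
                "error": "zero_denominator",
            }
            continue
        fc = num / den
        rows[met] = {
            "mean_num": m_num,
            "mean_den": m_den,
            "fc": fc,
            "log2fc": math.log2(fc) if fc > 0 else float("-inf"),
            "error": "",
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def class_group_test(
    table: MetaboliteTable, class_label: str, groups: tuple[str, str]
) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA on per-sample class totals of two groups.

    For two groups F equals the square of the pooled t statistic.

    Returns
    -------
    (F, (df_between, df_within), p)
    """
    sums = table.class_sums()
    if class_label not in sums.columns:
        raise KeyError(f"unknown class: {class_label!r}")
    ga, gb = groups
    x = sums.loc[table.samples_in(ga), class_label].to_numpy(dtype=float)
    y = sums.loc[table.samples_in(gb), class_label].to_numpy(dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 samples")
    n = x.size + y.size
    grand = (x.sum() + y.sum()) / n
    ss_between = x.size * (x.mean() - grand) ** 2 + y.size * (y.mean() - grand) ** 2
    ss_within = float(np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2))
    df_b, df_w = 1, n - 2
    if ss_within == 0.0:
        f_val = 0.0 if ss_between <= 1e-24 else float("inf")
        p = 1.0 if ss_between <= 1e-24 else 0.0
    else:
        f_val = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_val, df_b, df_w))
    return float(f_val), (df_b, df_w), p
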