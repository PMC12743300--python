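"""Tab-separated I/O for every table the pipeline reads or writes.

All files are plain TSV with a one-line header. Growth series use columns
sample_id, replicate, temperature_c, day, cells_per_ml; thermal
observations use temperature_c, replicate, growth_rate_per_day; ASV tables
are long format (sample_id, asv_id, count) with sidecar taxonomy and
sample-map TSVs; metabolite tables are long format with class-map and
sample-map sidecars.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .diversity import AsvTable, RANKS
from .growth import GrowthSeries
from .metabolites import MetaboliteTable

__all__ = [
    "write_growth_series",
    "read_growth_series",
    "write_thermal_observations",
    "read_thermal_observations",
    "write_asv_table",
    "read_asv_table",
    "write_metabolite_table",
    "read_metabolite_table",
    "write_tsv",
]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def write_growth_series(series: Iterable[GrowthSeries], path) -> Path:
    rows = [
        {
            "sample_id": s.sample_id,
            "replicate": s.replicate,
            "temperature_c": s.temperature_c,
            "day": day,
            "cells_per_ml": count,
        }
        for s in series
        for day, count in s.observations
    ]
    return write_tsv(pd.DataFrame(rows), path)


def read_growth_series(path) -> list[GrowthSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    keys = ["sample_id", "replicate", "temperature_c"]
    for (sample_id, replicate, temp), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("day")
        out.append(
            GrowthSeries(
                sample_id=str(sample_id),
                replicate=int(replicate),
                temperature_c=float(temp),
                observations=tuple(
                    zip(sub["day"].tolist(), sub["cells_per_ml"].tolist())
                ),
            )
        )
    return out


def write_thermal_observations(df: pd.DataFrame, path) -> Path:
    cols = ["temperature_c", "replicate", "growth_rate_per_day"]
    return write_tsv(df[cols], path)


def read_thermal_observations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_asv_table(
    table: AsvTable, counts_path, taxonomy_path, sample_map_path
) -> tuple[Path, Path, Path]:
    long_rows = (
        table.counts.stack()
        .rename_axis(["sample_id", "asv_id"])
        .rename("count")
        .reset_index()
    )
    long_rows = long_rows[long_rows["count"] > 0]
    p1 = write_tsv(long_rows, counts_path)
    tax = table.taxonomy.rename_axis("asv_id").reset_index()
    p2 = write_tsv(tax[["asv_id", *RANKS]], taxonomy_path)
    smap = table.sample_map.rename_axis("sample_id").reset_index()
    p3 = write_tsv(smap[["sample_id", "group", "replicate"]], sample_map_path)
    return p1, p2, p3


def read_asv_table(counts_path, taxonomy_path, sample_map_path) -> AsvTable:
    long_rows = pd.read_csv(counts_path, sep="\t")
    counts = (
        long_rows.pivot_table(
            index="sample_id", columns="asv_id", values="count", fill_value=0
        )
        .astype(int)
        .rename_axis(index=None, columns=None)
    )
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id").rename_axis(
        None
    )
    sample_map = pd.read_csv(
        sample_map_path, sep="\t", index_col="sample_id"
    ).rename_axis(None)
    # sidecars may list ASVs/samples that were filtered out of the counts
    return AsvTable(counts=counts, taxonomy=taxonomy, sample_map=sample_map)


def write_metabolite_table(
    table: MetaboliteTable, conc_path, class_map_path, sample_map_path
) -> tuple[Path, Path, Path]:
    long_rows = (
        table.concentrations.stack()
        .rename_axis(["sample_id", "metabolite"])
        .rename("concentration")
        .reset_index()
    )
    p1 = write_tsv(long_rows, conc_path)
    cmap = pd.DataFrame(
        {"metabolite": list(table.class_map), "class": list(table.class_map.values())}
    )
    p2 = write_tsv(cmap, class_map_path)
    smap = table.sample_map.rename_axis("sample_id").reset_index()
    p3 = write_tsv(smap, sample_map_path)
    return p1, p2, p3


def read_metabolite_table(conc_path, class_map_path, sample_map_path) -> MetaboliteTable:
    long_rows = pd.read_csv(conc_path, sep="\t")
    conc = long_rows.pivot_table(
        index="sample_id", columns="metabolite", values="concentration"
    ).rename_axis(index=None, columns=None)
    cmap = pd.read_csv(class_map_path, sep="\t")
    class_map = dict(zip(cmap["metabolite"], cmap["class"]))
    sample_map = pd.read_csv(
        sample_map_path, sep="\t", index_col="sample_id"
    ).rename_axis(None)
    return MetaboliteTable(
        concentrations=conc, class_map=class_map, sample_map=sample_map
    )
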