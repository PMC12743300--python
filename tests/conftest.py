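import numpy as np
import pandas as pd
import pytest

from thermobiome.diversity import AsvTable
from thermobiome.metabolites import MetaboliteTable
from thermobiome.tpc import NorbergParams

# the nine assay temperatures of the thermal-response experiment
ASSAY_TEMPS = (16.0, 18.0, 22.0, 24.0, 26.0, 30.0, 34.0, 36.0, 38.0)

# curve parameters recovered by inverting the published ambient-bacteria
# trait row (mu_max=2.09, t_opt=28.74, ct_min=14.2, ct_max=38.19)
AMBIENT_BACTERIA = NorbergParams(a=0.7548, b=0.03704, z=26.195, w=23.99)


@pytest.fixture
def ambient_params() -> NorbergParams:
    return AMBIENT_BACTERIA


@pytest.fixture
def assay_temps() -> tuple[float, ...]:
    return ASSAY_TEMPS


def make_asv_table(counts: dict, groups: dict, taxonomy: dict | None = None) -> AsvTable:
    """Build an AsvTable from plain dicts.

    counts: {sample_id: {asv_id: count}}; groups: {sample_id: group};
    taxonomy: optional {asv_id: {rank: label}} (defaults to one genus per
    ASV nested two-by-two into higher ranks).
    """
    counts_df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    asvs = list(counts_df.columns)
    if taxonomy is None:
        taxonomy = {
            a: {
                "genus": f"Genus_{i + 1}",
                "family": f"Family_{i // 2 + 1}",
                "order": f"Order_{i // 4 + 1}",
                "phylum": f"Phylum_{i // 8 + 1}",
            }
            for i, a in enumerate(asvs)
        }
    tax_df = pd.DataFrame.from_dict(taxonomy, orient="index")
    sample_map = pd.DataFrame(
        {
            "group": pd.Series(groups),
            "replicate": pd.Series({s: i + 1 for i, s in enumerate(counts)}),
        }
    )
    return AsvTable(counts=counts_df, taxonomy=tax_df, sample_map=sample_map)


def make_metabolite_table(conc: dict, class_map: dict, groups: dict) -> MetaboliteTable:
    conc_df = pd.DataFrame.from_dict(conc, orient="index").astype(float)
    sample_map = pd.DataFrame({"group": pd.Series(groups)})
    return MetaboliteTable(
        concentrations=conc_df, class_map=class_map, sample_map=sample_map
    )


@pytest.fixture
def toy_two_group_table() -> AsvTable:
    """3 replicates x 2 groups, 6 ASVs, overlapping presence."""
    counts = {
        "LA_r1": {"A1": 50, "A2": 20, "A3": 10, "A4": 5},
        "LA_r2": {"A1": 55, "A2": 18, "A3": 12, "A4": 0},
        "LA_r3": {"A1": 48, "A2": 25, "A3": 9, "A4": 3},
        "LW_r1": {"A1": 40, "A2": 10, "A5": 30, "A6": 8},
        "LW_r2": {"A1": 45, "A2": 12, "A5": 28, "A6": 5},
        "LW_r3": {"A1": 42, "A2": 9, "A5": 33, "A6": 9},
    }
    groups = {s: s.split("_")[0] for s in counts}
    return make_asv_table(counts, groups)
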