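import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermobiome.diversity import (
    alpha_diversity,
    bray_curtis,
    evar,
    extinctions,
    filter_table,
    permanova,
    relative_abundance,
    shannon,
    shared_asvs,
    taxon_group_test,
)

from .conftest import make_asv_table


def random_table(rng, n_samples=4, n_asvs=5, n_groups=2):
    counts = {
        f"s{i}": {
            f"A{j}": int(rng.integers(0, 50)) for j in range(n_asvs)
        }
        for i in range(n_samples)
    }
    # ensure nonzero totals
    for i in range(n_samples):
        counts[f"s{i}"]["A0"] += 1
    groups = {f"s{i}": f"g{i % n_groups}" for i in range(n_samples)}
    return make_asv_table(counts, groups)


class TestFilterTable:
    def test_singleton_removed(self):
        t = make_asv_table(
            {"s1": {"A1": 1, "A2": 10}, "s2": {"A1": 0, "A2": 5}},
            {"s1": "g", "s2": "g"},
        )
        out = filter_table(t, drop_singletons=True)
        assert list(out.counts.columns) == ["A2"]

    def test_identity_when_nothing_to_drop(self, toy_two_group_table):
        out = filter_table(toy_two_group_table, drop_singletons=True, drop_taxa=())
        pd.testing.assert_frame_equal(out.counts, toy_two_group_table.counts)

    def test_toy_totals(self):
        # dataset-wide totals (1, 1, 2, 5, 9, 100) -> 4 ASVs survive
        counts = {
            "s1": {"A1": 1, "A2": 0, "A3": 1, "A4": 3, "A5": 4, "A6": 60},
            "s2": {"A1": 0, "A2": 1, "A3": 1, "A4": 2, "A5": 5, "A6": 40},
        }
        t = make_asv_table(counts, {"s1": "g", "s2": "g"})
        out = filter_table(t, drop_singletons=True)
        assert sorted(out.counts.columns) == ["A3", "A4", "A5", "A6"]

    def test_drop_taxa_by_label(self):
        taxonomy = {
            "A1": {"genus": "g1", "family": "f1", "order": "o1", "phylum": "p1"},
            "A2": {"genus": "g2", "family": "Mitochondria", "order": "o2", "phylum": "p2"},
        }
        t = make_asv_table(
            {"s1": {"A1": 5, "A2": 5}}, {"s1": "g"}, taxonomy=taxonomy
        )
        out = filter_table(t, drop_singletons=False, drop_taxa={"Mitochondria"})
        assert list(out.counts.columns) == ["A1"]


class TestRelativeAbundance:
    def test_single_asv_is_100(self):
        t = make_asv_table({"s1": {"A1": 42}}, {"s1": "g"})
        per_sample, _ = relative_abundance(t, rank="asv")
        assert per_sample.loc["s1", "A1"] == pytest.approx(100.0)

    def test_genus_aggregation_by_hand(self):
        taxonomy = {
            "A1": {"genus": "G1", "family": "f", "order": "o", "phylum": "p"},
            "A2": {"genus": "G1", "family": "f", "order": "o", "phylum": "p"},
            "A3": {"genus": "G2", "family": "f", "order": "o", "phylum": "p"},
        }
        t = make_asv_table(
            {"s1": {"A1": 30, "A2": 20, "A3": 50}}, {"s1": "g"}, taxonomy=taxonomy
        )
        per_sample, _ = relative_abundance(t, rank="genus")
        assert per_sample.loc["s1", "G1"] == pytest.approx(50.0)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_rows_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng)
        for rank in ("asv", "genus", "family", "order", "phylum"):
            per_sample, _ = relative_abundance(t, rank=rank)
            assert np.allclose(per_sample.sum(axis=1), 100.0, atol=1e-9)

    def test_zero_total_sample_errors(self):
        t = make_asv_table(
            {"s1": {"A1": 0, "A2": 0}, "s2": {"A1": 1, "A2": 4}},
            {"s1": "g", "s2": "g"},
        )
        with pytest.raises(ValueError):
            relative_abundance(t)

    def test_unknown_rank_errors(self, toy_two_group_table):
        with pytest.raises(ValueError):
            relative_abundance(toy_two_group_table, rank="species")


class TestAlphaDiversity:
    def test_uniform_community_identities(self):
        t = make_asv_table(
            {"s1": {"A1": 25, "A2": 25, "A3": 25, "A4": 25}}, {"s1": "g"}
        )
        res = alpha_diversity(t).per_sample
        assert res.loc["s1", "richness"] == 4
        assert res.loc["s1", "shannon"] == pytest.approx(math.log(4), rel=1e-12)
        assert res.loc["s1", "evar"] == pytest.approx(1.0, abs=1e-12)

    def test_single_asv_zero_entropy(self):
        t = make_asv_table({"s1": {"A1": 99}}, {"s1": "g"})
        assert alpha_diversity(t).per_sample.loc["s1", "shannon"] == 0.0

    def test_shannon_direct_formula(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_evar_arctan_one(self):
        # abundances (1, e^2): variance of logs = 1, arctan(1) = pi/4
        assert evar([1.0, math.e**2]) == pytest.approx(0.5, rel=1e-12)

    def test_evar_decreases_with_log_variance(self):
        vals = [evar([1.0, math.exp(s)]) for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_evar_scale_invariant(self):
        x = np.array([3.0, 10.0, 44.0, 210.0])
        assert evar(x) == pytest.approx(evar(x * 17.3), rel=1e-12)

    def test_group_means(self, toy_two_group_table):
        res = alpha_diversity(toy_two_group_table)
        per_group = res.per_group
        sub = res.per_sample[res.per_sample["group"] == "LA"]["richness"]
        assert per_group.loc["LA", ("richness", "mean")] == pytest.approx(sub.mean())
        assert per_group.loc["LA", ("richness", "se")] == pytest.approx(
            sub.std(ddof=1) / math.sqrt(len(sub))
        )

    def test_empty_sample_errors(self):
        t = make_asv_table(
            {"s1": {"A1": 0}, "s2": {"A1": 3}}, {"s1": "g", "s2": "g"}
        )
        with pytest.raises(ValueError):
            alpha_diversity(t)


class TestExtinctionsAndShared:
    def test_simple_loss(self, toy_two_group_table):
        n, lost = extinctions(toy_two_group_table, "LA", "LW")
        assert n == 2
        assert lost == ["A3", "A4"]

    def test_superset_target_gives_zero(self):
        t = make_asv_table(
            {"s1": {"A1": 1, "A2": 2}, "s2": {"A1": 3, "A2": 4}},
            {"s1": "ref", "s2": "tgt"},
        )
        assert extinctions(t, "ref", "tgt")[0] == 0

    def test_single_replicate_presence_counts(self):
        # ASV X present in one reference replicate only and absent from the
        # target group is still an extinction
        counts = {
            "r1": {"X": 1, "C": 10},
            "r2": {"X": 0, "C": 12},
            "r3": {"X": 0, "C": 9},
            "t1": {"X": 0, "C": 11},
            "t2": {"X": 0, "C": 10},
            "t3": {"X": 0, "C": 10},
        }
        groups = {s: ("ref" if s.startswith("r") else "tgt") for s in counts}
        t = make_asv_table(counts, groups)
        n, lost = extinctions(t, "ref", "tgt")
        assert lost == ["X"]

    def test_unknown_group_errors(self, toy_two_group_table):
        with pytest.raises(KeyError):
            extinctions(toy_two_group_table, "LA", "nope")

    def test_shared_set_algebra(self, toy_two_group_table):
        res = shared_asvs(toy_two_group_table, ["LA", "LW"])
        # presence: LA = {A1,A2,A3,A4}, LW = {A1,A2,A5,A6}
        assert res.pairwise_shared[("LA", "LW")] == 2
        assert res.region_counts[("LA",)] == 2
        assert res.region_counts[("LW",)] == 2
        assert res.region_counts[("LA", "LW")] == 2
        assert res.intersection_all == 2

    def test_identical_groups(self):
        counts = {
            "a1": {"A1": 5, "A2": 3},
            "a2": {"A1": 4, "A2": 2},
            "b1": {"A1": 1, "A2": 9},
            "b2": {"A1": 2, "A2": 8},
        }
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = shared_asvs(make_asv_table(counts, groups), ["A", "B"])
        assert res.region_counts[("A", "B")] == 2
        assert res.region_counts[("A",)] == 0
        assert res.region_counts[("B",)] == 0

    def test_requires_two_groups(self, toy_two_group_table):
        with pytest.raises(ValueError):
            shared_asvs(toy_two_group_table, ["LA"])

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_conservation_extinctions_plus_shared(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_samples=6, n_asvs=8, n_groups=2)
        ref_richness = len(t.group_presence("g0"))
        n_lost, _ = extinctions(t, "g0", "g1")
        shared = shared_asvs(t, ["g0", "g1"]).pairwise_shared[("g0", "g1")]
        assert n_lost + shared == ref_richness


class TestBrayCurtis:
    @staticmethod
    def brute_force(x, y):
        num = sum(abs(a - b) for a, b in zip(x, y))
        den = sum(a + b for a, b in zip(x, y))
        return num / den

    def test_identical_samples_zero(self):
        t = make_asv_table(
            {"s1": {"A1": 3, "A2": 7}, "s2": {"A1": 3, "A2": 7}},
            {"s1": "g", "s2": "g"},
        )
        d = bray_curtis(t)
        assert d.loc["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_samples_one(self):
        t = make_asv_table(
            {"s1": {"A1": 5, "A2": 0}, "s2": {"A1": 0, "A2": 9}},
            {"s1": "g", "s2": "g"},
        )
        assert bray_curtis(t).loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_computed_raw_counts(self):
        t = make_asv_table(
            {"s1": {"A1": 2, "A2": 0, "A3": 2}, "s2": {"A1": 1, "A2": 1, "A3": 0}},
            {"s1": "g", "s2": "g"},
        )
        d = bray_curtis(t, use_proportions=False)
        assert d.loc["s1", "s2"] == pytest.approx(4.0 / 6.0, rel=1e-12)

    @given(seed=st.integers(0, 500), n=st.integers(2, 6))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_and_metric_properties(self, seed, n):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_samples=n, n_asvs=6)
        for use_prop in (True, False):
            d = bray_curtis(t, use_proportions=use_prop)
            mat = t.counts.to_numpy(dtype=float)
            if use_prop:
                mat = mat / mat.sum(axis=1, keepdims=True)
            for i, j in itertools.combinations(range(n), 2):
                expected = self.brute_force(mat[i], mat[j])
                assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)
                assert d.iloc[j, i] == d.iloc[i, j]
                assert 0.0 <= d.iloc[i, j] <= 1.0
            assert np.allclose(np.diag(d.to_numpy()), 0.0)

    def test_zero_total_sample_errors(self):
        t = make_asv_table(
            {"s1": {"A1": 0}, "s2": {"A1": 4}}, {"s1": "g", "s2": "g"}
        )
        with pytest.raises(ValueError):
            bray_curtis(t)


class TestPermanova:
    def test_hand_computed_pseudo_f(self):
        # 4 samples, 2 groups of 2; within-pair distance 0.1, between 0.9:
        # SS_total = (2*0.01 + 4*0.81)/4 = 0.815, SS_within = 0.01,
        # pseudo-F = 0.805 / (0.01/2) = 161
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        res = permanova(d, ["a", "a", "b", "b"], n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(161.0, rel=1e-9)
        assert res.df_among == 1
        assert res.df_within == 2

    def test_equal_distances_are_exchangeable(self):
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0.0)
        res = permanova(d, ["a"] * 3 + ["b"] * 3, n_permutations=199, seed=1)
        assert res.p == pytest.approx(1.0)

    def test_label_order_invariance_of_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        labels = ["a", "a", "a", "b", "b", "b"]
        shuffled = ["b", "a", "b", "a", "b", "a"]
        r1 = permanova(d, labels, n_permutations=99, seed=5)
        r2 = permanova(d, shuffled, n_permutations=99, seed=5)
        assert r1.n_permutations == r2.n_permutations
        assert 0 < r1.p <= 1 and 0 < r2.p <= 1

    def test_group_size_validation(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "b"], n_permutations=9, seed=0)

    def test_matches_skbio_pseudo_f(self):
        # independent reference implementation
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 5))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x, metric="braycurtis") / 2 + 0.25)
        labels = ["a"] * 4 + ["b"] * 4
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = sk_permanova(
            DistanceMatrix(d), grouping=labels, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestTaxonGroupTest:
    def test_identical_abundances(self):
        df = pd.DataFrame(
            {"T1": [10.0, 10.0, 10.0, 10.0]}, index=["a1", "a2", "b1", "b2"]
        )
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = taxon_group_test(df, groups, ("A", "B"))
        assert res.loc["T1", "t"] == 0.0

    def test_hand_computed_t(self):
        df = pd.DataFrame(
            {"T1": [10.0, 12.0, 14.0, 40.0, 42.0, 44.0]},
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        groups = {s: ("A" if s.startswith("a") else "B") for s in df.index}
        res = taxon_group_test(df, groups, ("A", "B"))
        assert res.loc["T1", "t"] == pytest.approx(-18.37, abs=5e-3)
        assert res.loc["T1", "df"] == 4

    def test_absent_taxon_excluded(self):
        df = pd.DataFrame(
            {"T1": [10.0, 12.0, 40.0, 42.0], "T2": [0.0, 0.0, 0.0, 0.0]},
            index=["a1", "a2", "b1", "b2"],
        )
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = taxon_group_test(df, groups, ("A", "B"))
        assert "T2" not in res.index

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(1, 2, size=(4, 5)),
            index=["a1", "a2", "b1", "b2"],
            columns=[f"T{i}" for i in range(5)],
        )
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        plain = taxon_group_test(df, groups, ("A", "B"))
        adj = taxon_group_test(df, groups, ("A", "B"), bonferroni=True)
        assert (adj["p"] >= plain["p"] - 1e-15).all()
        assert (adj["p"] <= 1.0).all()

    def test_too_few_replicates_errors(self):
        df = pd.DataFrame({"T1": [1.0, 2.0]}, index=["a1", "b1"])
        with pytest.raises(ValueError):
            taxon_group_test(df, {"a1": "A", "b1": "B"}, ("A", "B"))
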