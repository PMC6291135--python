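"""Paired t-tests, BH adjustment, genomic clustering, bump hunting, and
directional summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylagree import (
    InjectedRegion,
    SimulationParams,
    bh_adjust,
    directional_summary,
    find_bumps,
    global_paired_t,
    make_clusters,
    paired_wilcoxon,
    per_site_paired_t,
    simulate,
)
from methylagree.differential import ClusterParams

from conftest import clustered_annotation, make_dataset


def _ds_with_subject_diffs(diffs):
    """Two methods, two sites; M - A equals *diffs* for every subject/site."""
    diffs = np.asarray(diffs, dtype=float)
    base = np.full((2, diffs.size), 0.5)
    return make_dataset({"M": base + diffs, "A": base})


class TestGlobalPairedT:
    def test_closed_form_on_three_subjects(self):
        res = global_paired_t(_ds_with_subject_diffs([0.01, 0.02, 0.03]), "M", "A")
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        assert res.mean_diff == pytest.approx(0.02)

    def test_identical_matrices(self):
        b = np.random.default_rng(0).uniform(size=(5, 3))
        res = global_paired_t(make_dataset({"M": b, "A": b}), "M", "A")
        assert res.mean_diff == 0.0 and res.p_raw == 1.0

    def test_symmetric_differences_give_zero_t(self):
        res = global_paired_t(_ds_with_subject_diffs([0.1, -0.1]), "M", "A")
        assert res.t == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_antisymmetry_under_method_swap(self, sim_ds):
        r12 = global_paired_t(sim_ds, "M", "A")
        r21 = global_paired_t(sim_ds, "A", "M")
        assert r12.t == pytest.approx(-r21.t)
        assert r12.p_raw == pytest.approx(r21.p_raw)


class TestPerSitePairedT:
    def test_power_ordering_with_injected_effect(self):
        ann = clustered_annotation(20, 10)
        region = InjectedRegion("chr1", 1, 10 * 500, "A", 0.05)
        ds, truth = simulate(
            SimulationParams(n_sites=200, seed=31, injected_regions=(region,)),
            annotation=ann,
        )
        res = per_site_paired_t(ds, "M", "A")
        mask = truth.region_mask["region_0"].to_numpy()
        assert np.median(res["p_raw"][mask]) < 0.1 * np.median(res["p_raw"][~mask])

    def test_null_rarely_reaches_fdr_significance(self, sim_ds):
        res = per_site_paired_t(sim_ds, "M", "A")
        assert (res["p_bh"] < 0.05).sum() == 0

    def test_zero_variance_sites_excluded_from_bh(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0.2, 0.8, size=(4, 3))
        m = b.copy()  # site 0: all differences exactly zero
        m[1:] += rng.uniform(0.005, 0.02, size=(3, 3))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = per_site_paired_t(make_dataset({"M": m, "A": b}), "M", "A")
        assert np.isnan(res["p_raw"].iloc[0]) and np.isnan(res["p_bh"].iloc[0])
        assert res["p_raw"].iloc[1:].notna().all()

    def test_t_antisymmetry(self, sim_ds):
        r12 = per_site_paired_t(sim_ds, "M", "A")
        r21 = per_site_paired_t(sim_ds, "A", "M")
        np.testing.assert_allclose(r12["t"], -r21["t"], atol=1e-10)
        np.testing.assert_allclose(r12["p_raw"], r21["p_raw"], atol=1e-12)


def _bh_brute_force(p):
    """Step-up definition: adj_(i) = min over j >= i of min(1, m*p_(j)/j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, m * p[idx] / rank))
        adj[idx] = running
    return adj


class TestBHAdjust:
    def test_stepup_collapses_arithmetic_sequence(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_definition(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(bh_adjust(p), _bh_brute_force(p), atol=1e-12)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_nan_entries_excluded_from_family(self):
        p = np.array([0.01, np.nan, 0.02])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        np.testing.assert_allclose(adj[[0, 2]], _bh_brute_force(p[[0, 2]]))


class TestMakeClusters:
    def test_gap_above_max_splits(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [100, 900, 2500], "context": "cpg"},
            index=["a", "b", "c"],
        )
        ids = make_clusters(sites, ClusterParams(max_gap=1000))
        assert ids["a"] == ids["b"] != ids["c"]

    def test_gap_exactly_max_stays_together(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [100, 1100], "context": "cpg"},
            index=["a", "b"],
        )
        ids = make_clusters(sites, ClusterParams(max_gap=1000))
        assert ids["a"] == ids["b"]

    def test_chromosome_change_always_splits(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "pos": [100, 101], "context": "cpg"},
            index=["a", "b"],
        )
        ids = make_clusters(sites)
        assert ids["a"] != ids["b"]

    def test_duplicate_positions_share_cluster(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [100, 100, 200], "context": "cpg"},
            index=["a", "b", "c"],
        )
        assert make_clusters(sites).nunique() == 1


class TestFindBumps:
    def test_injected_region_recovered(self):
        ann = clustered_annotation(100, 20)
        region = InjectedRegion("chr1", 1, 20 * 500, "A", 0.05)
        ds, _ = simulate(
            SimulationParams(n_sites=2000, seed=5, injected_regions=(region,)),
            annotation=ann,
        )
        regions = find_bumps(ds, "M", "A", n_boot=50, seed=6)
        top = regions[0]
        assert top.fwer < 0.05
        assert top.direction == "hypo"  # M - A < 0 since A was shifted up
        assert top.start <= 20 * 500 and top.end >= 1

    def test_effects_below_cutoff_give_empty_list(self):
        ds, _ = simulate(
            SimulationParams(n_sites=200, noise_a=-6.0, noise_b=0.0, seed=7),
            annotation=clustered_annotation(10, 20),
        )
        assert find_bumps(ds, "M", "A", n_boot=10, seed=8) == []

    def test_deterministic_under_fixed_seed(self):
        ds, _ = simulate(
            SimulationParams(n_sites=400, seed=9), annotation=clustered_annotation(20, 20)
        )
        r1 = find_bumps(ds, "M", "A", n_boot=20, seed=10)
        r2 = find_bumps(ds, "M", "A", n_boot=20, seed=10)
        assert [(r.start, r.end, r.area, r.fwer) for r in r1] == [
            (r.start, r.end, r.area, r.fwer) for r in r2
        ]

    def test_invariant_to_site_ordering(self):
        ds, _ = simulate(
            SimulationParams(n_sites=400, seed=11), annotation=clustered_annotation(20, 20)
        )
        perm = np.random.default_rng(0).permutation(ds.n_sites)
        shuffled = ds.subset_sites(ds.betas.index[perm])
        r1 = find_bumps(ds, "M", "A", n_boot=20, seed=12)
        r2 = find_bumps(shuffled, "M", "A", n_boot=20, seed=12)
        assert [(r.start, r.end, round(r.area, 12)) for r in r1] == [
            (r.start, r.end, round(r.area, 12)) for r in r2
        ]

    def test_invalid_bootstrap_count_fatal(self, sim_ds):
        with pytest.raises(ValueError, match="n_boot"):
            find_bumps(sim_ds, "M", "A", n_boot=0)


@pytest.fixture(scope="module")
def three_pair_results():
    ds, _ = simulate(SimulationParams(n_sites=2000, seed=13))
    return {
        ("M", "A"): per_site_paired_t(ds, "M", "A"),
        ("M", "O"): per_site_paired_t(ds, "M", "O"),
        ("A", "O"): per_site_paired_t(ds, "A", "O"),
    }


class TestDirectionalSummary:
    def test_null_sign_split_is_balanced(self, three_pair_results):
        out = directional_summary(three_pair_results)
        sign = out["sign"]
        floor_rows = sign[sign["group"] == "p>0.75"]
        for _, row in floor_rows.iterrows():
            m1, m2 = row["pair"].split("vs")
            assert 40 < row[f"{m1}>{m2}"] < 60

    def test_percentages_sum_to_100(self, three_pair_results):
        out = directional_summary(three_pair_results)
        for _, row in out["sign"].iterrows():
            m1, m2 = row["pair"].split("vs")
            total = row[f"{m1}>{m2}"] + row[f"{m1}<{m2}"] + row[f"{m1}={m2}"]
            assert total == pytest.approx(100.0)
        for _, row in out["ranking"].iterrows():
            if row["n_labels"]:
                vals = [v for k, v in row.items() if k.endswith(("lowest", "highest"))]
                assert np.nansum(vals) == pytest.approx(100.0)

    def test_shifted_method_dominates_ranking(self):
        ds, _ = simulate(SimulationParams(n_sites=1000, seed=14, method_bias={"O": 0.05}))
        results = {
            ("M", "A"): per_site_paired_t(ds, "M", "A"),
            ("M", "O"): per_site_paired_t(ds, "M", "O"),
            ("A", "O"): per_site_paired_t(ds, "A", "O"),
        }
        out = directional_summary(results)
        rank = out["ranking"].set_index("group")
        assert rank.loc["p<0.002", "O highest"] > 90

    def test_missing_comparison_is_fatal(self, three_pair_results):
        partial = {k: v for k, v in list(three_pair_results.items())[:2]}
        with pytest.raises(ValueError, match="missing"):
            directional_summary(partial)


class TestPairedWilcoxon:
    def test_shift_detected_and_bonferroni_applied(self, sim_ds):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(
            {"predicted_age": rng.normal(40, 5, sim_ds.n_samples)},
            index=sim_ds.samples.index,
        )
        is_o = (sim_ds.samples["method"] == "O").to_numpy()
        table.loc[is_o, "predicted_age"] += 20
        res = paired_wilcoxon(table, sim_ds.samples)
        res = res.set_index("pair")
        assert res.loc["MvsO", "p_raw"] < 0.01
        assert (res["p_bonferroni"] >= res["p_raw"]).all()
        assert res.loc["MvsA", "p_raw"] > 0.05

    def test_identical_statistics_give_p_one(self, sim_ds):
        table = pd.DataFrame({"frac": np.full(sim_ds.n_samples, 0.4)},
                             index=sim_ds.samples.index)
        res = paired_wilcoxon(table, sim_ds.samples)
        assert (res["p_raw"] == 1.0).all()
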