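"""Differential-methylation statistics: Wald test behaviour, segmentation
rules, two-stage specificity, and region summaries."""

import numpy as np
import pandas as pd
import pytest

from methylphase.diffmeth import (Thresholds, bin_mean_methylation,
                                  call_group_specific, dmc_test,
                                  dmr_set_operations, low_meth_fraction,
                                  pooled_group_means, profile_matrix,
                                  region_group_methylation, segment_dmrs)
from methylphase.synthetic_cohort import PlantSpec, simulate_methylomes

from _oracles import brute_force_any_overlap, wald_oracle_table
from conftest import make_matrix, small_config


class TestPooledGroupMeans:
    def test_pooling_definition(self):
        m = make_matrix([[5, 0, 10]], [[10, 10, 10]], ["g", "g", "g"])
        assert pooled_group_means(m, ["s1"])["mean"][0] == 0.5
        assert pooled_group_means(m, ["s2", "s3"])["mean"][0] == 0.5

    def test_zero_coverage_sample_ignored(self):
        m = make_matrix([[3, 0]], [[4, 0]], ["g", "g"])
        res = pooled_group_means(m, ["s1", "s2"])
        assert res["mean"][0] == 0.75
        assert bool(res["low_coverage"][0])  # pooled total 4 < 10

    def test_empty_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            pooled_group_means(tiny_matrix, [])


class TestDmcTest:
    def test_identical_columns_give_null_result(self):
        col = [[4], [12], [7]]
        meth = np.hstack([col, col, col, col])
        m = make_matrix(meth, np.full((3, 4), 20), ["a", "a", "b", "b"])
        res = dmc_test(m, "a", "b")
        assert np.allclose(res["diff"], 0)
        assert np.allclose(res["wald"], 0)
        assert np.allclose(res["p"], 1)

    def test_symmetry_under_group_swap(self, tiny_matrix):
        fwd = dmc_test(tiny_matrix, "ref", "tum")
        rev = dmc_test(tiny_matrix, "tum", "ref")
        assert np.allclose(fwd["diff"].to_numpy(), -rev["diff"].to_numpy())
        assert np.allclose(fwd["p"].to_numpy(), rev["p"].to_numpy())

    def test_strong_difference_matches_oracle_and_is_significant(self):
        meth = [[9, 8, 10, 1, 2, 0], [5, 5, 5, 5, 5, 5]]
        total = [[10] * 6, [10] * 6]
        m = make_matrix(meth, total, ["a"] * 3 + ["b"] * 3)
        res = dmc_test(m, "a", "b")
        oracle = wald_oracle_table(meth, total, [0, 1, 2], [3, 4, 5])
        assert res["diff"][0] == pytest.approx(-0.8)
        assert res["p"][0] < 0.01
        for col in ("mu_a", "mu_b", "diff", "wald", "p"):
            assert res[col][0] == pytest.approx(oracle[0][col], abs=1e-10)

    def test_min_diff_filter_blocks_small_effects(self, tiny_matrix):
        th = Thresholds(min_diff=0.9)
        res = dmc_test(tiny_matrix, "ref", "tum", th)
        strong = res[res["q"] < th.fdr]
        assert len(strong) > 0 and not strong["is_dmc"].any()

    def test_shared_sample_between_groups_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="share"):
            dmc_test(tiny_matrix, ["s1", "s2"], ["s2", "s3"])

    def test_underpowered_cpgs_skipped_and_counted(self):
        meth = [[5, 5, 5, 5], [5, 0, 5, 5]]
        total = [[10, 10, 10, 10], [10, 0, 10, 10]]
        m = make_matrix(meth, total, ["a", "a", "b", "b"])
        res = dmc_test(m, "a", "b")
        assert len(res) == 1 and res.attrs["n_skipped"] == 1

    def test_monotone_in_thresholds(self, study_cohort, study_analysis):
        _, matrix, _ = study_cohort
        dmcs, _, _ = study_analysis
        stricter = dmc_test(matrix, "CD34", "IDH", Thresholds(min_diff=0.3))
        assert stricter["is_dmc"].sum() <= dmcs["is_dmc"].sum()
        low_fdr = dmc_test(matrix, "CD34", "IDH", Thresholds(fdr=0.01))
        assert low_fdr["is_dmc"].sum() <= dmcs["is_dmc"].sum()


class TestSegmentDmrs:
    def _signal_matrix(self, n_cpgs, spacing=50):
        meth = np.hstack([np.full((n_cpgs, 3), 1), np.full((n_cpgs, 3), 19)])
        total = np.full((n_cpgs, 6), 20)
        return make_matrix(meth, total, ["a"] * 3 + ["b"] * 3,
                           positions=np.arange(n_cpgs) * spacing + 1000)

    def test_no_dmcs_no_dmrs(self, tiny_matrix):
        dmcs = dmc_test(tiny_matrix, "ref", "tum")
        dmcs["is_dmc"] = False
        assert len(segment_dmrs(dmcs, tiny_matrix, "ref", "tum")) == 0

    @pytest.mark.parametrize("n_cpgs,expected", [(10, 0), (11, 1)])
    def test_more_than_ten_cpgs_required(self, n_cpgs, expected):
        m = self._signal_matrix(n_cpgs)
        dmcs = dmc_test(m, "a", "b")
        assert dmcs["is_dmc"].all()
        assert len(segment_dmrs(dmcs, m, "a", "b")) == expected

    def test_gap_splits_chains(self):
        m = self._signal_matrix(24, spacing=50)
        # open a 2 kb hole in the middle: two 12-CpG chains
        m.positions[12:] += 2000
        dmcs = dmc_test(m, "a", "b")
        dmrs = segment_dmrs(dmcs, m, "a", "b", Thresholds(max_gap=1000))
        assert len(dmrs) == 2

    def test_boundaries_are_cpg_anchored(self):
        m = self._signal_matrix(12)
        dmrs = segment_dmrs(dmc_test(m, "a", "b"), m, "a", "b")
        assert dmrs["start"][0] == m.positions[0]
        assert dmrs["end"][0] == m.positions[-1] + 2

    def test_direction_recorded(self):
        m = self._signal_matrix(12)
        hyper = segment_dmrs(dmc_test(m, "a", "b"), m, "a", "b")
        hypo = segment_dmrs(dmc_test(m, "b", "a"), m, "b", "a")
        assert (hyper["direction"] == "hyper").all()
        assert (hypo["direction"] == "hypo").all()

    def test_raising_min_cpgs_never_increases_dmrs(self, study_cohort, study_analysis):
        _, matrix, _ = study_cohort
        dmcs, dmrs, _ = study_analysis
        stricter = segment_dmrs(dmcs, matrix, "CD34", "IDH",
                                Thresholds(min_cpgs_per_dmr=30))
        assert len(stricter) <= len(dmrs)


class TestGroupSpecific:
    def test_target_equals_comparison_rejected(self, study_cohort, study_analysis):
        _, matrix, _ = study_cohort
        _, dmrs, _ = study_analysis
        with pytest.raises(ValueError, match="overlap"):
            call_group_specific(dmrs, matrix, "IDH", ["IDH", "AML"])

    def test_empty_comparison_after_exclusion_rejected(self, study_cohort,
                                                       study_analysis):
        _, matrix, _ = study_cohort
        _, dmrs, _ = study_analysis
        with pytest.raises(ValueError, match="empty"):
            call_group_specific(dmrs, matrix, "IDH", ["TET2"], ["TET2"])

    def test_target_only_regions_pass_stage2(self, small_cohort):
        cfg, matrix, truth = small_cohort
        dmcs = dmc_test(matrix, "CD34", "IDH")
        dmrs = segment_dmrs(dmcs, matrix, "CD34", "IDH")
        specific = call_group_specific(dmrs, matrix, "IDH", ["AML"])
        rep = dmr_set_operations(specific, truth.regions)
        assert rep["fraction_b_in_a"] >= 0.9  # planted regions recovered
        assert rep["fraction_a_in_b"] >= 0.95  # few stray calls
        assert (specific["direction"] == "hyper").all()
        assert (specific["stage"] == "group_specific").all()

    def test_shared_signal_fails_stage2(self):
        cfg = small_config(
            31, planted_dmrs=(),
            planted_shared_hyper=(
                PlantSpec(("IDH", "AML"), 8, (15, 30), 0.4, "cgi_state"),))
        matrix, truth = simulate_methylomes(cfg)
        dmcs = dmc_test(matrix, "CD34", "IDH")
        dmrs = segment_dmrs(dmcs, matrix, "CD34", "IDH")
        rep = dmr_set_operations(dmrs, truth.regions)
        assert rep["fraction_b_in_a"] >= 0.9  # stage 1 sees shared signal
        specific = call_group_specific(dmrs, matrix, "IDH", ["AML"])
        assert len(specific) == 0


class TestDmrSetOperations:
    def test_identity_and_disjoint(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
        assert dmr_set_operations(a, a)["fraction_a_in_b"] == 1.0
        assert dmr_set_operations(a, b)["fraction_a_in_b"] == 0.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            def rand_set(n):
                start = rng.integers(0, 5000, n)
                return pd.DataFrame({
                    "chrom": rng.choice(["chr1", "chr2"], n),
                    "start": start, "end": start + rng.integers(1, 400, n)})
            a, b = rand_set(8), rand_set(6)
            rep = dmr_set_operations(a, b)
            ta = [tuple(r) for r in a.itertuples(index=False)]
            tb = [tuple(r) for r in b.itertuples(index=False)]
            assert rep["a_overlapping_b"] == sum(brute_force_any_overlap(ta, tb))
            assert rep["b_overlapping_a"] == sum(brute_force_any_overlap(tb, ta))


class TestSummaries:
    def test_bin_mean_and_complete_case_drop(self):
        m = make_matrix([[5, 5], [2, 0]], [[10, 10], [10, 0]], ["g", "g"],
                        positions=[100, 1500])
        table, n_dropped = bin_mean_methylation(m, 1000)
        assert n_dropped == 1  # second bin uncovered in sample 2
        assert table.loc[("chr1", 0)].tolist() == [0.5, 0.5]

    def test_region_means_and_low_meth_fraction(self):
        m = make_matrix([[1, 1, 18], [2, 0, 19]], [[10, 10, 20], [10, 0, 20]],
                        ["ref", "ref", "tum"], positions=[100, 200])
        regions = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [50, 5000],
                                "end": [300, 5100]})
        means = region_group_methylation(m, regions, {"ref": ["s1", "s2"],
                                                      "tum": ["s3"]})
        assert means["ref"][0] == pytest.approx(4 / 30)
        assert np.isnan(means["ref"][1])  # empty region flagged
        assert low_meth_fraction(means, "ref", 0.3) == 1.0
        assert low_meth_fraction(means, "ref", 0.01) == 0.0

    def test_region_low_meth_fraction_on_planted_cohort(self, study_cohort,
                                                        study_analysis):
        cfg, matrix, _ = study_cohort
        _, _, specific = study_analysis
        means = region_group_methylation(matrix, specific, {"CD34": "CD34"})
        # planted regions sit at the low baseline mode (0.25 < 0.3)
        assert low_meth_fraction(means, "CD34", 0.3) > 0.95


class TestProfileMatrix:
    def test_uniform_methylation_gives_flat_profile(self):
        n = 200
        m = make_matrix(np.full((n, 2), 10), np.full((n, 2), 20), ["g", "g"],
                        positions=np.arange(n) * 60 + 8000)
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [12000], "end": [13000]})
        prof = profile_matrix(m, regions, ["s1", "s2"], flank=2000, bin_width=100)
        vals = prof.aggregate[np.isfinite(prof.aggregate)]
        assert np.allclose(vals, 0.5)

    def test_planted_regions_peak_at_center(self, study_cohort, study_analysis):
        _, matrix, truth = study_cohort
        prof = profile_matrix(matrix, truth.regions, "IDH", flank=5000)
        n = len(prof.aggregate)
        center = np.nanmean(prof.aggregate[n // 2 - 3:n // 2 + 3])
        edges = np.nanmean(np.r_[prof.aggregate[:5], prof.aggregate[-5:]])
        assert center - edges >= 0.5 * 0.4

    def test_window_truncates_at_chromosome_edge(self):
        m = make_matrix([[5], [5]], [[10], [10]], ["g"], positions=[10, 50])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [60]})
        prof = profile_matrix(m, regions, ["s1"], flank=5000)
        assert np.isfinite(prof.aggregate).any()
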