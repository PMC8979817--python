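"""Annotation operations: state assignment, enhancer rule table, permutation
test, CpG density, superenhancer geometry."""

import numpy as np
import pandas as pd
import pytest

from methylphase.io_formats import MethylationValidationError
from methylphase.regulatory_annotation import (call_superenhancers,
                                               classify_enhancers,
                                               count_dmrs_per_superenhancer,
                                               cpg_density, overlap_fraction,
                                               permutation_overlap_test,
                                               state_enrichment,
                                               state_overlap_distribution,
                                               stitch_peaks)

from _oracles import (brute_force_any_overlap, brute_force_state_assignment,
                      exact_permutation_p)


def iv(*rows, score=False):
    cols = ["chrom", "start", "end", "label"] + (["score"] if score else [])
    return pd.DataFrame(list(rows), columns=cols)


class TestStateOverlap:
    STATES = iv(("chr1", 0, 1000, "A"), ("chr1", 1000, 3000, "B"),
                ("chr1", 3000, 4000, "C"))

    def test_all_regions_in_one_state(self):
        regions = iv(("chr1", 1200, 1300, "."), ("chr1", 2000, 2500, "."))
        dist = state_overlap_distribution(regions, self.STATES)
        assert dist["B"] == 1.0 and dist["A"] == 0.0
        assert dist.sum() == pytest.approx(1.0)

    def test_max_overlap_wins_and_ties_take_lowest_index(self):
        # 600 bp in B vs 400 in A -> B; exact tie 500/500 -> A (earlier state)
        regions = iv(("chr1", 600, 1600, "."), ("chr1", 500, 1500, "."))
        dist = state_overlap_distribution(regions, self.STATES)
        assert dist["A"] == 0.5 and dist["B"] == 0.5

    def test_overlapping_state_map_rejected(self):
        bad = iv(("chr1", 0, 1000, "A"), ("chr1", 500, 1500, "B"))
        with pytest.raises(MethylationValidationError, match="overlap"):
            state_overlap_distribution(iv(("chr1", 10, 20, ".")), bad)

    def test_background_equal_to_regions_gives_unit_enrichment(self):
        regions = iv(("chr1", 100, 200, "."), ("chr1", 3100, 3200, "."))
        enr = state_enrichment(regions, regions, self.STATES)
        assert (enr.dropna() == 1.0).all()

    def test_matches_bruteforce_assignment_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            # random non-overlapping tiling
            edges = np.sort(rng.choice(np.arange(1, 50), size=6, replace=False)) * 100
            states = [("chr1", int(a), int(b), lab) for a, b, lab in
                      zip(edges[:-1], edges[1:],
                          rng.choice(["x", "y", "z"], len(edges) - 1))]
            starts = rng.integers(0, 5000, 8)
            regions = [("chr1", int(s), int(s + rng.integers(1, 600)))
                       for s in starts]
            got = state_overlap_distribution(
                iv(*[r + (".",) for r in regions]), iv(*states))
            expected = brute_force_state_assignment(regions, states)
            assigned = [e for e in expected if e]
            for lab in got.index:
                want = assigned.count(lab) / len(assigned) if assigned else 0.0
                assert got[lab] == pytest.approx(want)


class TestOverlapFraction:
    def test_genome_covering_features_give_one(self):
        regions = iv(("chr1", 10, 20, "."), ("chr1", 500, 900, "."))
        assert overlap_fraction(regions, iv(("chr1", 0, 10_000, ".")))[0] == 1.0

    def test_empty_features_give_zero(self):
        assert overlap_fraction(iv(("chr1", 10, 20, ".")), iv())[0] == 0.0

    def test_min_overlap_bp_respected(self):
        regions = iv(("chr1", 0, 100, "."))
        features = iv(("chr1", 95, 300, "."))
        assert overlap_fraction(regions, features, min_overlap_bp=5)[0] == 1.0
        assert overlap_fraction(regions, features, min_overlap_bp=6)[0] == 0.0


class TestCpGDensity:
    def test_definition_in_cpgs_per_100bp(self):
        chroms = np.array(["chr1"] * 10, dtype=object)
        pos = np.arange(10) * 90 + 1050
        dens, mean = cpg_density(iv(("chr1", 1000, 2000, ".")), chroms, pos)
        assert dens[0] == 1.0 and mean == 1.0

    def test_region_without_cpgs_is_zero(self):
        chroms = np.array(["chr1"], dtype=object)
        dens, _ = cpg_density(iv(("chr2", 0, 500, ".")), chroms, np.array([100]))
        assert dens[0] == 0.0

    def test_dinucleotide_overlap_rule_at_boundaries(self):
        chroms = np.array(["chr1", "chr1"], dtype=object)
        pos = np.array([99, 200])  # [99,101) straddles the region start
        dens, _ = cpg_density(iv(("chr1", 100, 200, ".")), chroms, pos)
        assert dens[0] == pytest.approx(100 * 1 / 100)


class TestEnhancerTruthTable:
    CASES = {  # (k27ac, k4me1, k27me3) -> class
        (0, 0, 0): "none", (0, 0, 1): "none", (0, 1, 0): "weak",
        (0, 1, 1): "none", (1, 0, 0): "active", (1, 0, 1): "poised",
        (1, 1, 0): "active", (1, 1, 1): "poised",
    }

    @pytest.mark.parametrize("combo,expected", sorted(CASES.items()))
    def test_every_overlap_combination(self, combo, expected):
        region = iv(("chr1", 1000, 2000, "."))
        present = iv(("chr1", 1500, 1600, "peak"))
        absent = iv(("chr2", 0, 100, "peak"))
        a, m1, m3 = [present if flag else absent for flag in combo]
        calls = classify_enhancers(region, a, m1, m3)
        assert calls["enhancer_class"][0] == expected


class TestPermutationTest:
    def _universe(self, n=6):
        return iv(*[("chr1", i * 1000, i * 1000 + 500, ".") for i in range(n)])

    def test_query_equal_to_universe_gives_p_one(self):
        uni = self._universe()
        ref = iv(("chr1", 0, 600, "."))
        res = permutation_overlap_test(uni, ref, uni, n_perm=200, seed=1)
        assert res.p == 1.0

    def test_reference_covering_universe_gives_p_one(self):
        uni = self._universe()
        ref = iv(("chr1", 0, 10_000, "."))
        query = uni.iloc[:2]
        res = permutation_overlap_test(query, ref, uni, n_perm=200, seed=1)
        assert res.observed == 2 and res.p == 1.0

    def test_exact_enumeration_matches_itertools_oracle(self):
        uni = self._universe(6)
        ref = iv(("chr1", 0, 1600, "."))  # overlaps members 0 and 1
        for qidx in ([0, 1], [0, 5], [4, 5]):
            query = uni.iloc[qidx]
            res = permutation_overlap_test(query, ref, uni, exact=True)
            flags = [True, True, False, False, False, False]
            obs, p = exact_permutation_p(flags, qidx)
            assert res.observed == obs
            assert res.p == pytest.approx(p)

    def test_monte_carlo_converges_to_exact(self):
        uni = self._universe(8)
        ref = iv(("chr1", 0, 2600, "."))
        query = uni.iloc[[0, 1, 2]]
        exact = permutation_overlap_test(query, ref, uni, exact=True)
        mc = permutation_overlap_test(query, ref, uni, n_perm=20000, seed=3)
        assert abs(mc.p - exact.p) < 0.02

    def test_deterministic_given_seed(self):
        uni = self._universe(20)
        ref = iv(("chr1", 0, 5600, "."))
        a = permutation_overlap_test(uni.iloc[:5], ref, uni, n_perm=500, seed=9)
        b = permutation_overlap_test(uni.iloc[:5], ref, uni, n_perm=500, seed=9)
        assert a.p == b.p

    def test_query_outside_universe_rejected(self):
        uni = self._universe()
        with pytest.raises(ValueError, match="not in universe"):
            permutation_overlap_test(iv(("chr9", 0, 10, ".")), uni, uni,
                                     n_perm=200, seed=1)


class TestSuperenhancers:
    def test_one_dominant_peak_is_the_only_superenhancer(self):
        rows = [("chr1", i * 100_000, i * 100_000 + 500, "p", 1.0)
                for i in range(99)]
        rows.append(("chr2", 0, 500, "big", 100.0))
        ses = call_superenhancers(iv(*rows, score=True))
        called = ses.df[ses.df["is_superenhancer"]]
        assert len(called) == 1 and called["signal"].iloc[0] == 100.0
        assert ses.cutoff_signal == 1.0

    def test_all_equal_signals_yield_no_superenhancers(self):
        rows = [("chr1", i * 100_000, i * 100_000 + 500, "p", 5.0)
                for i in range(50)]
        ses = call_superenhancers(iv(*rows, score=True))
        assert not ses.df["is_superenhancer"].any()

    def test_stitching_merges_and_sums_signal(self):
        rows = [("chr1", 0, 1000, "a", 2.0), ("chr1", 5000, 6000, "b", 3.0),
                ("chr1", 40_000, 41_000, "c", 7.0)]
        stitched = stitch_peaks(iv(*rows, score=True), stitch_distance=12_500)
        assert len(stitched) == 2
        assert stitched["signal"].tolist() == [5.0, 7.0]

    def test_stitching_is_idempotent(self):
        rows = [("chr1", 0, 1000, "a", 2.0), ("chr1", 5000, 6000, "b", 3.0)]
        once = stitch_peaks(iv(*rows, score=True))
        twice = stitch_peaks(once.assign(label="s", score=once["signal"]))
        assert twice[["chrom", "start", "end", "signal"]].equals(
            once[["chrom", "start", "end", "signal"]])

    def test_dmrs_disjoint_from_ses_count_zero(self):
        rows = [("chr1", 0, 500, "p", 1.0), ("chr2", 0, 500, "big", 50.0)]
        ses = call_superenhancers(iv(*rows, score=True))
        counts = count_dmrs_per_superenhancer(ses, iv(("chr1", 9000, 9100, ".")))
        assert (counts == 0).all()


def test_anchor_and_overlap_operations_match_bruteforce():
    rng = np.random.default_rng(13)
    from methylphase.io_formats import LoopSet
    from methylphase.loops_expression import intersect_dmr_anchors
    for _ in range(60):
        def rand(n, width=400):
            start = rng.integers(0, 8000, n)
            return pd.DataFrame({"chrom": rng.choice(["chr1", "chr2"], n),
                                 "start": start,
                                 "end": start + rng.integers(1, width, n)})
        regions, feats = rand(10), rand(6)
        frac, flags = overlap_fraction(regions, feats)
        expected = brute_force_any_overlap(
            [tuple(r) for r in regions.itertuples(index=False)],
            [tuple(f) for f in feats.itertuples(index=False)])
        assert flags.tolist() == expected

        a1, a2 = rand(5), rand(5)
        loops = LoopSet(pd.DataFrame({
            "chrom1": a1["chrom"], "start1": a1["start"], "end1": a1["end"],
            "chrom2": a1["chrom"], "start2": a2["start"] + 20_000,
            "end2": a2["end"] + 20_000}))
        frac, _ = intersect_dmr_anchors(regions, loops)
        anchors = [(c, s, e) for _, _, c, s, e in
                   loops.anchors().itertuples(index=False, name=None)]
        expected_flags = brute_force_any_overlap(
            [tuple(r) for r in regions.itertuples(index=False)], anchors)
        assert frac == pytest.approx(sum(expected_flags) / len(regions))
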