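import numpy as np
import pytest

from clonemate import (
    FusionSet,
    Segment,
    SegmentedProfile,
    TumourPair,
    VariantSet,
)
from clonemate.datatypes import CallLabel
from clonemate import pair_tests as pt

from conftest import make_profile

PAIR = TumourPair("a", "b", is_true_pair=True, patient_id="P1")


class TestEuclideanDistance:
    def test_identical_profiles_zero(self):
        p = make_profile([0.1, -0.2, 0.5])
        assert pt.euclidean_distance(p, p) == 0.0

    def test_pythagorean(self):
        a = make_profile([0.0, 0.0], sample_id="a")
        b = make_profile([3.0, 4.0], sample_id="b")
        assert pt.euclidean_distance(a, b) == pytest.approx(5.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            va, vb = rng.normal(size=(2, 40))
            a, b = make_profile(va, sample_id="a"), make_profile(vb, sample_id="b")
            expected = sum((x - y) ** 2 for x, y in zip(va, vb)) ** 0.5
            assert pt.euclidean_distance(a, b) == pytest.approx(expected)
            assert pt.euclidean_distance(b, a) == pytest.approx(expected)

    def test_distance_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(4)
        profs = [make_profile(rng.normal(size=30), sample_id=f"s{i}")
                 for i in range(6)]
        dm = pt.distance_matrix(profs)
        for i in range(6):
            for j in range(6):
                assert dm[i, j] == pytest.approx(
                    pt.euclidean_distance(profs[i], profs[j]), abs=1e-9
                )


class TestDistanceTest:
    def test_smaller_than_all_artificial_is_clonal(self):
        res = pt.distance_test(PAIR, 0.5, np.linspace(1, 10, 30))
        assert res.call is CallLabel.CLONAL

    def test_median_of_artificial_is_independent(self):
        null = np.linspace(1, 10, 31)
        res = pt.distance_test(PAIR, float(np.median(null)), null)
        assert res.call is CallLabel.INDEPENDENT

    def test_at_percentile_counts_as_clonal(self):
        null = np.arange(1.0, 101.0)
        thr = np.percentile(null, 5)
        assert pt.distance_test(PAIR, thr, null).call is CallLabel.CLONAL

    def test_too_few_artificial_pairs_not_evaluable(self):
        res = pt.distance_test(PAIR, 0.5, np.arange(5.0))
        assert res.call is CallLabel.NOT_EVALUABLE


class TestCherry:
    def patients(self, n):
        return {f"P{i}": (f"P{i}a", f"P{i}b") for i in range(n)}

    def test_separated_pair_is_cherry(self):
        # pair P0 at mutual distance ~1, everything else far away
        vals = {"P0a": 0.0, "P0b": 1.0, "P1a": 50.0, "P1b": 80.0}
        profs = [make_profile([v], sample_id=s) for s, v in vals.items()]
        profs += [make_profile([200.0], sample_id="P2a"),
                  make_profile([300.0], sample_id="P2b")]
        results = pt.cluster_cherry_test(profs, self.patients(3))
        calls = {r.pair.patient_id: r.call for r in results}
        assert calls["P0"] is CallLabel.CLONAL

    def test_nearest_neighbour_elsewhere_breaks_cherry(self):
        vals = {"P0a": 0.0, "P1a": 0.5, "P0b": 30.0, "P1b": 31.0}
        profs = [make_profile([v], sample_id=s) for s, v in vals.items()]
        results = pt.cluster_cherry_test(profs, self.patients(2))
        calls = {r.pair.patient_id: r.call for r in results}
        assert calls["P0"] is CallLabel.INDEPENDENT

    def test_matches_mutual_nearest_neighbour_oracle(self):
        """Under single linkage, (x, y) form a cherry exactly when they are
        mutual nearest neighbours strictly closer to each other than to any
        third sample."""
        rng = np.random.default_rng(7)
        for rep in range(200):
            n_pat = int(rng.integers(2, 7))  # up to 12 samples
            ps = self.patients(n_pat)
            ids = sorted(s for pair in ps.values() for s in pair)
            profs = [make_profile(rng.normal(size=4), sample_id=s) for s in ids]
            dm = pt.distance_matrix(sorted(profs, key=lambda p: p.sample_id))
            idx = {s: i for i, s in enumerate(ids)}
            results = pt.cluster_cherry_test(profs, ps)
            for r in results:
                i, j = idx[r.pair.sample_a], idx[r.pair.sample_b]
                d_ij = dm[i, j]
                others = [k for k in range(len(ids)) if k not in (i, j)]
                oracle = all(d_ij < dm[i, k] and d_ij < dm[j, k] for k in others)
                assert (r.call is CallLabel.CLONAL) == oracle, f"rep {rep}"

    def test_needs_four_samples(self):
        profs = [make_profile([float(i)], sample_id=f"s{i}") for i in range(3)]
        with pytest.raises(ValueError, match="4 samples"):
            pt.cluster_cherry_test(profs, {"P0": ("s0", "s1")})


def seg(chrom, start, end, status, mean=None):
    if mean is None:
        mean = {"gain": 0.6, "loss": -0.6, "normal": 0.0}[status]
    return Segment(chrom, start, end, mean, status)


class TestSharedSegments:
    def test_hand_enumeration_ignores_normal(self):
        a = SegmentedProfile("a", [
            seg("1", 1, 100, "gain"), seg("1", 101, 200, "normal"),
            seg("2", 1, 50, "loss"), seg("2", 51, 90, "normal"),
            seg("3", 1, 10, "gain"),
        ])
        b = SegmentedProfile("b", [
            seg("1", 1, 100, "gain"), seg("1", 101, 200, "normal"),
            seg("2", 1, 50, "loss"), seg("2", 51, 90, "normal"),
            seg("3", 1, 10, "gain"),
        ])
        assert pt.shared_segments(a, b) == 3

    def test_one_bp_breakpoint_shift_breaks_match(self):
        a = SegmentedProfile("a", [seg("1", 1, 100, "gain")])
        b = SegmentedProfile("b", [seg("1", 1, 101, "gain")])
        assert pt.shared_segments(a, b) == 0
        assert pt.shared_segments(a, b, tolerance_bp=1) == 1

    def test_opposite_direction_never_matches(self):
        a = SegmentedProfile("a", [seg("1", 1, 100, "gain")])
        b = SegmentedProfile("b", [seg("1", 1, 100, "loss")])
        assert pt.shared_segments(a, b) == 0

    def test_self_comparison_counts_aberrant_segments(self):
        a = SegmentedProfile("a", [
            seg("1", 1, 100, "gain"), seg("2", 1, 40, "loss"),
            seg("3", 1, 5, "normal"),
        ])
        assert pt.shared_segments(a, a) == 2

    def test_symmetry(self):
        a = SegmentedProfile("a", [seg("1", 1, 100, "gain"), seg("2", 1, 9, "loss")])
        b = SegmentedProfile("b", [seg("1", 1, 100, "gain")])
        assert pt.shared_segments(a, b) == pt.shared_segments(b, a) == 1


class TestSharedSegmentTest:
    def test_above_everything_is_clonal(self):
        res = pt.shared_segment_test(PAIR, 12, np.zeros(40))
        assert res.call is CallLabel.CLONAL

    def test_zero_with_nonzero_spread_is_independent(self):
        res = pt.shared_segment_test(PAIR, 0, np.arange(40.0))
        assert res.call is CallLabel.INDEPENDENT

    def test_exactly_at_percentile_is_independent(self):
        # "above" is strict
        null = np.full(40, 3.0)
        res = pt.shared_segment_test(PAIR, 3, null)
        assert res.call is CallLabel.INDEPENDENT


class TestSharedMutations:
    def test_disjoint_and_subset(self):
        a = VariantSet("a", [("1", 1, "A", "T"), ("2", 5, "C", "G")])
        b = VariantSet("b", [("3", 9, "G", "A")])
        assert pt.shared_mutations(a, b) == 0
        c = VariantSet("c", [("1", 1, "A", "T"), ("2", 5, "C", "G"),
                             ("4", 2, "T", "C")])
        assert pt.shared_mutations(a, c) == len(a.variants)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            mk = lambda sid: VariantSet(sid, {
                ("1", int(p), "A", "T") for p in rng.integers(0, 40, 25)
            })
            a, b = mk("a"), mk("b")
            brute = sum(1 for v in a.variants for w in b.variants if v == w)
            assert pt.shared_mutations(a, b) == brute == pt.shared_mutations(b, a)

    def test_private_variant_never_changes_count(self):
        a = VariantSet("a", [("1", 1, "A", "T")])
        b = VariantSet("b", [("1", 1, "A", "T"), ("2", 2, "C", "G")])
        before = pt.shared_mutations(a, b)
        a2 = VariantSet("a", list(a.variants) + [("9", 999, "G", "C")])
        assert pt.shared_mutations(a2, b) == before

    def test_panel_restriction(self):
        panel = pt.PanelRegions("test", [("1", 1, 100)])
        a = VariantSet("a", [("1", 50, "A", "T"), ("1", 500, "C", "G"),
                             ("2", 10, "G", "A")])
        b = VariantSet("b", [("1", 50, "A", "T"), ("1", 500, "C", "G")])
        assert pt.shared_mutations(a, b) == 2
        assert pt.shared_mutations(a, b, panel) == 1


class TestFusionOverlap:
    def test_identical_single_fusion(self):
        a = FusionSet("a", [("1", 100, "G1", "2", 200, "G2")])
        b = FusionSet("b", [("1", 100, "OTHER", "2", 200, "NAMES")])
        count, shared = pt.fusion_overlap(a, b)
        assert count == 1 and shared == {("1", 100, "2", 200)}

    def test_same_genes_different_breakpoint_no_match(self):
        a = FusionSet("a", [("1", 100, "G1", "2", 200, "G2")])
        b = FusionSet("b", [("1", 100, "G1", "2", 201, "G2")])
        assert pt.fusion_overlap(a, b)[0] == 0

    def test_symmetric(self):
        a = FusionSet("a", [("1", 1, "x", "2", 2, "y"), ("3", 3, "z", "4", 4, "w")])
        b = FusionSet("b", [("3", 3, "q", "4", 4, "r")])
        assert pt.fusion_overlap(a, b)[0] == pt.fusion_overlap(b, a)[0] == 1
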