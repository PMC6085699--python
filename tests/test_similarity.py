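import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonemate import DiscreteProfile, Platform, Probe, Scheme
from clonemate.datatypes import CallLabel
from clonemate import similarity as sim

from conftest import make_profile


def disc(states, scheme=Scheme.CN3, sample_id="S"):
    probes = [Probe(f"p{i}", "1", (i + 1) * 1000) for i in range(len(states))]
    arr = np.array(states) if scheme is not Scheme.METH3 else np.array(states, dtype="<U1")
    return DiscreteProfile(sample_id, scheme, probes, arr, (-0.3, 0.3))


class TestDiscretization:
    @pytest.mark.parametrize(
        "value,expected",
        [(-0.31, -1), (-0.3, 0), (0.30, 0), (0.31, 1), (0.0, 0)],
    )
    def test_copy_number_thresholds_are_strict(self, value, expected):
        prof = make_profile([value])
        assert sim.discretize_copy_number(prof).states[0] == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0.59, 1), (-0.58, 0), (0.58, 0), (math.log2(1.5), 1), (-0.59, -1)],
    )
    def test_expression_fold_change_cutoff(self, value, expected):
        prof = make_profile([value], Platform.EXPRESSION)
        assert sim.discretize_expression(prof).states[0] == expected

    @pytest.mark.parametrize(
        "value,expected",
        [(0.81, "M"), (0.8, "H"), (0.2, "H"), (0.19, "U"), (0.0, "U"), (1.0, "M")],
    )
    def test_methylation_three_state(self, value, expected):
        prof = make_profile([value], Platform.METHYLATION_BETA)
        assert sim.discretize_methylation(prof).states[0] == expected

    def test_platform_checked(self):
        with pytest.raises(ValueError, match="platform"):
            sim.discretize_copy_number(make_profile([0.5], Platform.EXPRESSION))


class TestCountStates:
    def test_hand_enumerated_example(self):
        counts = sim.count_states(disc([1, 0, -1, 1, 0]), disc([1, 1, 1, 0, 0]))
        assert (counts.n_shared, counts.n_unique, counts.n_opposite,
                counts.n_neutral) == (1, 2, 1, 1)
        assert sim.similarity_index(counts) == 0.25

    def test_identical_nonzero_profiles(self):
        counts = sim.count_states(disc([1, -1, 1]), disc([1, -1, 1]))
        assert counts.n_shared == 3 and counts.si == 1.0

    def test_all_neutral_gives_undefined_si(self):
        counts = sim.count_states(disc([0, 0]), disc([0, 0]))
        assert counts.n_neutral == 2 and counts.si is None

    def test_meth3_directed_to_si_met(self):
        with pytest.raises(ValueError, match="similarity_index_met"):
            sim.count_states(disc(list("MU"), Scheme.METH3),
                             disc(list("MU"), Scheme.METH3))

    def test_scheme_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sim.count_states(disc([0, 1]), disc([0, 1], Scheme.EXPR3))

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from([-1, 0, 1]),
                              st.sampled_from([-1, 0, 1])),
                    min_size=1, max_size=30))
    def test_agrees_with_per_probe_brute_force(self, pairs):
        """Vectorised tallies match an explicit per-probe classifier."""
        a = disc([p[0] for p in pairs])
        b = disc([p[1] for p in pairs])
        shared = unique = opposite = neutral = 0
        for x, y in pairs:
            if x == 0 and y == 0:
                neutral += 1
            elif x != 0 and y != 0:
                if x == y:
                    shared += 1
                else:
                    opposite += 1
            else:
                unique += 1
        counts = sim.count_states(a, b)
        assert (counts.n_shared, counts.n_unique, counts.n_opposite,
                counts.n_neutral) == (shared, unique, opposite, neutral)
        # symmetry
        rev = sim.count_states(b, a)
        assert (rev.n_shared, rev.n_unique, rev.n_opposite) == (
            counts.n_shared, counts.n_unique, counts.n_opposite
        )
        if counts.si is not None:
            assert 0.0 <= counts.si <= 1.0


class TestSiMet:
    def test_hand_example(self):
        a = disc(list("MHUM"), Scheme.METH3)
        b = disc(list("MUUH"), Scheme.METH3)
        assert sim.similarity_index_met(a, b) == 0.5

    def test_identical_and_disjoint(self):
        a = disc(list("MHUM"), Scheme.METH3)
        assert sim.similarity_index_met(a, a) == 1.0
        b = disc(list("UMHU"), Scheme.METH3)
        assert sim.similarity_index_met(a, b) == 0.0

    def test_hemi_methylated_matches_count(self):
        # unlike the SI, a shared middle state counts as agreement
        a = disc(list("HH"), Scheme.METH3)
        assert sim.similarity_index_met(a, a) == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from("UHM"), st.sampled_from("UHM")),
                    min_size=1, max_size=20))
    def test_symmetric_and_bounded(self, pairs):
        a = disc([p[0] for p in pairs], Scheme.METH3)
        b = disc([p[1] for p in pairs], Scheme.METH3)
        v = sim.similarity_index_met(a, b)
        assert v == sim.similarity_index_met(b, a)
        assert 0.0 <= v <= 1.0


class TestPermutationScoring:
    def test_p_si_reconstructs_cohort_consistent_values(self):
        # one cohort-wide null mean must map SI values onto their
        # permutation percentages consistently
        null = np.full(20, 0.194)
        scored = sim.score_against_null(0.580, null)
        assert scored.p_si == pytest.approx(100 * (0.580 - 0.194) / 0.580)
        assert scored.p_si == pytest.approx(66.55, abs=0.05)

    def test_p_si_zero_at_or_below_null_mean(self):
        null = np.full(10, 0.804)
        assert sim.score_against_null(0.685, null).p_si == 0.0
        assert sim.score_against_null(0.804, null).p_si == 0.0

    def test_p_si_strictly_increasing_above_null_mean(self):
        null = np.full(10, 0.3)
        values = np.linspace(0.31, 0.99, 25)
        p = [sim.score_against_null(v, null).p_si for v in values]
        assert all(b > a for a, b in zip(p, p[1:]))

    def test_empirical_p_is_one_when_null_ties_observed(self):
        null = np.full(7, 0.5)
        scored = sim.score_against_null(0.5, null)
        assert scored.p_empirical == 1.0

    def test_add_one_pseudocount(self):
        null = np.array([0.1, 0.2, 0.3, 0.9])
        scored = sim.score_against_null(0.5, null)
        assert scored.p_empirical == pytest.approx((1 + 1) / (1 + 4))

    def test_undefined_si_not_evaluable(self):
        scored = sim.score_against_null(None, np.array([0.1, 0.2]))
        assert scored.call is CallLabel.NOT_EVALUABLE

    def test_si_permutation_end_to_end(self):
        from clonemate.datatypes import enumerate_pairs

        ps = {"P1": ("a", "b"), "P2": ("c", "d")}
        profiles = {
            "a": disc([1, -1, 0, 1], sample_id="a"),
            "b": disc([1, -1, 0, 0], sample_id="b"),
            "c": disc([-1, 1, 0, 0], sample_id="c"),
            "d": disc([-1, 0, 1, 0], sample_id="d"),
        }
        true_pairs, artificial = enumerate_pairs(ps)
        res = sim.si_permutation(true_pairs[0], profiles, ps)
        assert len(res.null_si) == 4
        assert res.observed == pytest.approx(2 / 3)
        with pytest.raises(ValueError, match="2 patients"):
            sim.si_permutation(true_pairs[0], profiles, {"P1": ("a", "b")})


class TestBetaVariability:
    def test_constant_betas_have_zero_spread(self):
        prof = make_profile([0.5] * 25, Platform.METHYLATION_BETA)
        assert sim.beta_variability(prof) == 0.0

    def test_uniform_grid_spread(self):
        prof = make_profile(np.linspace(0, 1, 101), Platform.METHYLATION_BETA)
        assert sim.beta_variability(prof) == pytest.approx(0.9, abs=0.01)

    def test_single_outlier_barely_moves_inner_quantiles(self):
        values = [0.5] * 99 + [1.0]
        prof = make_profile(values, Platform.METHYLATION_BETA)
        assert sim.beta_variability(prof) == pytest.approx(0.0, abs=0.03)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            sim.beta_variability(make_profile([0.5] * 5, Platform.METHYLATION_BETA))


class TestAberrationFrequency:
    def test_unanimous_gain_is_recurrent(self):
        profs = [disc([1, 0], sample_id=f"s{i}") for i in range(4)]
        df = sim.compute_aberration_frequency(profs)
        assert df.loc[0, "gain_freq"] == 1.0 and bool(df.loc[0, "recurrent"])

    def test_rare_loss_not_recurrent_at_quarter(self):
        profs = [disc([-1], sample_id="s0")] + [
            disc([0], sample_id=f"s{i}") for i in range(1, 10)
        ]
        df = sim.compute_aberration_frequency(profs)
        assert df.loc[0, "loss_freq"] == pytest.approx(0.1)
        assert not bool(df.loc[0, "recurrent"])

    def test_hotspot_frequency_recovered_within_binomial_noise(self):
        rng = np.random.default_rng(11)
        freq, n = 0.4, 200
        profs = [
            disc([1 if rng.random() < freq else 0], sample_id=f"s{i}")
            for i in range(n)
        ]
        df = sim.compute_aberration_frequency(profs)
        sd = math.sqrt(freq * (1 - freq) / n)
        assert abs(df.loc[0, "gain_freq"] - freq) < 3 * sd
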