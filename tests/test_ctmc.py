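"""State space, rate mapping, constrained rate matrices, and P(t)."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import traitpaths as tp
from traitpaths.ctmc import (
    DUAL_TRANSITIONS,
    GENERAL,
    ModelError,
    ModelSpec,
    N_RATES,
    RATE_TRANSITIONS,
    CompositeState,
    spec_by_name,
)

rates_strategy = st.lists(
    st.floats(0.01, 5.0, allow_nan=False), min_size=8, max_size=8
).map(np.array)


class TestRateMapping:
    def test_mapping_rederived_from_naming_constraints(self):
        """The q1..q8 numbering is forced by the model-naming scheme.

        Constraints used: (i) eq13/eq25/eq47/eq68 tie a transition to its
        reverse; (ii) eq57/eq24/eq16/eq38 tie the same single-trait move
        across the two contexts of the other trait; (iii) rates 7,6,2,3
        compose head-to-tail into a directed cycle; anchor: rate 3 is
        solitary-cryptic -> group-cryptic.  Brute force over all 8!
        assignments of indices to the eight permitted transitions leaves
        exactly one solution, the package constant.
        """
        edges = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 3), (3, 1), (2, 3), (3, 2)]
        colour = lambda s: s in (1, 3)
        group = lambda s: s in (2, 3)
        sym_pairs = [(1, 3), (2, 5), (4, 7), (6, 8)]
        ind_pairs = [(5, 7), (2, 4), (1, 6), (3, 8)]
        solutions = []
        for perm in permutations(edges):
            t = {i + 1: perm[i] for i in range(8)}
            if t[3] != (0, 2):
                continue
            if not all(t[a] == (t[b][1], t[b][0]) for a, b in sym_pairs):
                continue

            def same_move(a, b):
                (s1, d1), (s2, d2) = t[a], t[b]
                changes_colour = colour(s1) != colour(d1)
                if changes_colour != (colour(s2) != colour(d2)):
                    return False
                if changes_colour:
                    return colour(s1) == colour(s2) and group(s1) != group(s2)
                return group(s1) == group(s2) and colour(s1) != colour(s2)

            if not all(same_move(a, b) for a, b in ind_pairs):
                continue
            chain = [7, 6, 2, 3]
            if not all(t[chain[i]][1] == t[chain[(i + 1) % 4]][0] for i in range(4)):
                continue
            solutions.append(t)
        assert len(solutions) == 1
        assert solutions[0] == {
            i: (int(src), int(dst)) for i, (src, dst) in RATE_TRANSITIONS.items()
        }

    def test_state_index_bijection(self):
        pairs = {(s.colour, s.grouping) for s in CompositeState}
        assert len(pairs) == 4
        assert [int(s) for s in CompositeState] == [0, 1, 2, 3]


class TestBuildRateMatrix:
    def test_general_structure(self):
        Q = tp.build_rate_matrix(np.ones(8), GENERAL)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        for row in range(4):
            off = [Q[row, c] for c in range(4) if c != row]
            assert sum(x > 0 for x in off) == 2  # two single-trait exits per state

    def test_dual_transitions_structurally_zero(self, q_random):
        Q = tp.build_rate_matrix(q_random)
        for src, dst in DUAL_TRANSITIONS:
            assert Q[src, dst] == 0.0

    def test_n3_forbids_solitary_cryptic_to_group(self, q_random):
        Q = tp.build_rate_matrix(q_random, spec_by_name("n3"))
        assert Q[CompositeState.SC, CompositeState.GC] == 0.0

    def test_eq47_ties_group_colour_rates(self, q_random):
        Q = tp.build_rate_matrix(q_random, spec_by_name("eq47"))
        assert Q[CompositeState.GA, CompositeState.GC] == pytest.approx(
            Q[CompositeState.GC, CompositeState.GA]
        )

    def test_negative_rate_rejected(self):
        q = np.ones(8)
        q[2] = -0.1
        with pytest.raises(ModelError):
            tp.build_rate_matrix(q)

    def test_unknown_model_name_rejected(self):
        for bad in ("n0", "n9", "eq99", "nn1", "frank", "n"):
            with pytest.raises(ModelError):
                spec_by_name(bad)

    @settings(max_examples=30, deadline=None)
    @given(q=rates_strategy)
    def test_rows_sum_to_zero_under_every_named_constraint(self, q):
        for name in ("general", "n1", "n34", "n2345678", "eq47", "eq16"):
            Q = tp.build_rate_matrix(q, spec_by_name(name))
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, q_random):
        Q = tp.build_rate_matrix(q_random)
        np.testing.assert_allclose(tp.transition_probabilities(Q, 0.0), np.eye(4),
                                   atol=1e-14)

    def test_negative_time_rejected(self, q_random):
        with pytest.raises(ModelError):
            tp.transition_probabilities(tp.build_rate_matrix(q_random), -0.5)

    def test_rows_stochastic(self, q_random):
        P = tp.transition_probabilities(tp.build_rate_matrix(q_random), 0.7)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= -1e-12) and np.all(P <= 1 + 1e-12)

    def test_long_time_reaches_stationary(self, q_random):
        Q = tp.build_rate_matrix(q_random)
        pi, unique = tp.stationary_distribution(Q)
        assert unique
        P = tp.transition_probabilities(Q, 500.0)
        for row in range(4):
            np.testing.assert_allclose(P[row], pi, atol=1e-8)

    def test_symmetric_two_state_closed_form(self):
        # freeze grouping, symmetric colour flips: P(stay) = 1/2 + exp(-2qt)/2
        q_rate = 0.8
        q = np.zeros(8)
        q[4] = q[1] = q_rate  # q5 = q2 = q
        Q = tp.build_rate_matrix(q)
        for t in (0.0, 0.1, 1.0, 3.7):
            P = tp.transition_probabilities(Q, t)
            expected = 0.5 + 0.5 * np.exp(-2 * q_rate * t)
            assert P[0, 0] == pytest.approx(expected, abs=1e-10)
            assert P[1, 1] == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(q=rates_strategy, s=st.floats(0.0, 10.0), t=st.floats(0.0, 10.0))
    def test_semigroup_property(self, q, s, t):
        Q = tp.build_rate_matrix(q)
        lhs = tp.transition_probabilities(Q, s + t)
        rhs = tp.transition_probabilities(Q, s) @ tp.transition_probabilities(Q, t)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_dual_transition_probability_positive(self, q_random):
        # rate constraints are not probability constraints: two single
        # steps compose, so SC -> GA has positive probability over time
        P = tp.transition_probabilities(tp.build_rate_matrix(q_random), 0.5)
        assert P[CompositeState.SC, CompositeState.GA] > 0
        assert P[CompositeState.SA, CompositeState.GC] > 0


class TestStationary:
    def test_all_rates_equal_gives_uniform(self):
        pi, unique = tp.stationary_distribution(tp.build_rate_matrix(np.ones(8)))
        assert unique
        np.testing.assert_allclose(pi, 0.25, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(q=rates_strategy)
    def test_fixed_point_of_long_time_kernel(self, q):
        Q = tp.build_rate_matrix(q)
        pi, _ = tp.stationary_distribution(Q)
        np.testing.assert_allclose(pi @ tp.transition_probabilities(Q, 50.0), pi,
                                   atol=1e-8)

    def test_reducible_chain_flagged(self):
        # forbidding both directions of SC<->GC strands no state here,
        # but zeroing every exit from SC does:
        q = np.ones(8)
        q[2] = q[4] = 0.0  # q3 = q5 = 0: SC absorbs
        pi, unique = tp.stationary_distribution(tp.build_rate_matrix(q))
        assert not unique


class TestModelSpec:
    def test_general_k8(self):
        assert GENERAL.k == 8
        assert GENERAL.zero_set == frozenset()

    def test_k_accounting(self):
        assert spec_by_name("n1").k == 7
        assert spec_by_name("n34").k == 6
        assert spec_by_name("eq47").k == 7

    def test_json_round_trip(self):
        for name in ("general", "n34", "eq47"):
            spec = spec_by_name(name)
            again = ModelSpec.from_json(spec.to_json())
            assert again == spec

    def test_expand_project_inverse(self, q_random):
        spec = spec_by_name("eq25")
        free = spec.project(q_random)
        q = spec.expand(free)
        np.testing.assert_allclose(spec.project(q), free)
        assert spec.satisfied_by(q)

    def test_invalid_partition_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(name="bad", zero_set=frozenset({1}),
                      equality_partition=((1, 2), (3, 4, 5, 6, 7, 8)))
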