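"""Marginal ancestral states vs exact enumeration and sampling."""

import numpy as np
import pytest

import traitpaths as tp
from traitpaths.ancestral import marginal_ancestral_states, reconstruct_under_best
from traitpaths.ctmc import N_STATES, _EdgeKernel, spec_by_name
from traitpaths.likelihood import _root_weights, tip_partials
from traitpaths.models import build_aic_table

from conftest import random_instance


def _marginal_by_enumeration(tree, states, Q, policy):
    """Exact joint-assignment marginals for every internal node."""
    from itertools import product as iproduct

    L = tip_partials(tree, states)
    P = _EdgeKernel(Q)(tree.branch_length)
    internal = tree.internal_indices()
    post = np.zeros((tree.n_nodes, N_STATES))
    weights_cache = {}
    for combo in iproduct(range(N_STATES), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        prob = 1.0
        for i in internal:
            for c in tree.children[i]:
                if c in assign:
                    prob *= P[c][assign[i], assign[c]]
                else:
                    prob *= float(P[c][assign[i]] @ L[c])
        root_state = assign[tree.root]
        weights_cache[combo] = (prob, root_state)
    # root-policy weights from the conditional root likelihoods
    cond = np.zeros(N_STATES)
    for prob, root_state in weights_cache.values():
        cond[root_state] += prob
    w = _root_weights(policy, Q, cond)
    for combo, (prob, root_state) in weights_cache.items():
        for node, s in zip(internal, combo):
            post[node, s] += prob * w[root_state]
    post[internal] /= post[internal].sum(axis=1, keepdims=True)
    return post


class TestMarginals:
    def test_observed_tips_are_one_hot(self, quartet, q_random):
        Q = tp.build_rate_matrix(q_random)
        rec = marginal_ancestral_states(quartet, {"A": 0, "B": 1, "C": 3, "D": 2}, Q)
        a = quartet.tip_indices()[0]
        label = quartet.labels[a]
        expected = np.zeros(4)
        expected[{"A": 0, "B": 1, "C": 3, "D": 2}[label]] = 1.0
        np.testing.assert_allclose(rec.probs[a], expected, atol=1e-12)

    def test_vectors_normalized(self, q_random):
        tree = tp.simulate_yule_tree(30, seed=3, scale_depth=1.0)
        Q = tp.build_rate_matrix(q_random)
        tips, _ = tp.simulate_traits(tree, Q, seed=4)
        rec = marginal_ancestral_states(tree, tips, Q)
        np.testing.assert_allclose(rec.probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(rec.probs >= 0) and np.all(rec.probs <= 1)

    def test_no_data_flat_root_gives_uniform_root(self, quartet, q_random):
        Q = tp.build_rate_matrix(q_random)
        states = {lbl: tp.UNKNOWN for lbl in quartet.tip_labels()}
        rec = marginal_ancestral_states(quartet, states, Q, tp.RootPolicy.FLAT)
        np.testing.assert_allclose(rec.root_vector(quartet), 0.25, atol=1e-10)

    def test_matches_enumeration_on_100_random_instances(self):
        rng = np.random.default_rng(20240918)
        for _ in range(100):
            tree, Q, states = random_instance(rng)
            policy = list(tp.RootPolicy)[int(rng.integers(3))]
            rec = marginal_ancestral_states(tree, states, Q, policy)
            exact = _marginal_by_enumeration(tree, states, Q, policy)
            for node in tree.internal_indices():
                np.testing.assert_allclose(rec.probs[node], exact[node], atol=1e-9)

    def test_matches_sampled_joint_frequencies(self):
        # stochastic cross-check: marginals against 50,000 weighted draws
        rng = np.random.default_rng(99)
        tree, Q, states = random_instance(rng, max_tips=5)
        policy = tp.RootPolicy.FLAT
        exact = _marginal_by_enumeration(tree, states, Q, policy)
        rec = marginal_ancestral_states(tree, states, Q, policy)
        from itertools import product as iproduct

        internal = tree.internal_indices()
        combos = list(iproduct(range(N_STATES), repeat=len(internal)))
        from traitpaths.likelihood import tip_partials as tP

        L = tP(tree, states)
        P = _EdgeKernel(Q)(tree.branch_length)
        weights = []
        for combo in combos:
            assign = dict(zip(internal, combo))
            prob = 0.25  # flat root weight
            for i in internal:
                for c in tree.children[i]:
                    if c in assign:
                        prob *= P[c][assign[i], assign[c]]
                    else:
                        prob *= float(P[c][assign[i]] @ L[c])
            weights.append(prob)
        weights = np.array(weights)
        draws = rng.choice(len(combos), size=50_000, p=weights / weights.sum())
        freq = np.zeros((tree.n_nodes, N_STATES))
        for d in draws:
            for node, s in zip(internal, combos[d]):
                freq[node, s] += 1
        freq[internal] /= 50_000
        for node in internal:
            np.testing.assert_allclose(freq[node], rec.probs[node], atol=1e-2)
            np.testing.assert_allclose(rec.probs[node], exact[node], atol=1e-9)

    def test_invariant_to_tip_ordering(self, q_random):
        Q = tp.build_rate_matrix(q_random)
        a = tp.read_newick("((A:0.3,B:0.5):0.4,(C:0.6,D:0.2):0.3);")
        b = tp.read_newick("((D:0.2,C:0.6):0.3,(B:0.5,A:0.3):0.4);")
        states = {"A": 0, "B": 1, "C": 3, "D": 2}
        ra = marginal_ancestral_states(a, states, Q)
        rb = marginal_ancestral_states(b, states, Q)
        np.testing.assert_allclose(ra.root_vector(a), rb.root_vector(b), atol=1e-10)


class TestReconstructUnderBest:
    def test_uses_table_head_not_general(self, q_random):
        tree = tp.simulate_yule_tree(10, seed=21, scale_depth=1.0)
        Q = tp.build_rate_matrix(q_random)
        tips, _ = tp.simulate_traits(tree, Q, seed=22)
        settings = tp.OptimizerSettings(n_restarts=1, seed=0, max_iter=600)
        fits = {
            name: tp.fit_model(tree, tips, spec_by_name(name), settings)
            for name in ("general", "n1")
        }
        # force n1 to the top regardless of the data
        fits["n1"].aic = -1e6
        table = build_aic_table(list(fits.values()))
        rec = reconstruct_under_best(tree, tips, table, fits)
        assert rec.model_name == "n1"

    def test_empty_table_rejected(self, quartet):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            reconstruct_under_best(quartet, {}, pd.DataFrame(), {})

    def test_serialization_round_trip(self, tmp_path, q_random):
        tree = tp.simulate_yule_tree(12, seed=31, scale_depth=1.0)
        Q = tp.build_rate_matrix(q_random)
        tips, _ = tp.simulate_traits(tree, Q, seed=32)
        rec = marginal_ancestral_states(tree, tips, Q)
        path = tmp_path / "anc.tsv"
        rec.to_tsv(tree, path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert len(df) == tree.n_nodes
        back = df[[f"p_{s}" for s in tp.STATE_NAMES]].to_numpy()
        order = tree.postorder()
        np.testing.assert_allclose(back, rec.probs[order], atol=1e-12)

    def test_root_recovery_when_simulated_from_known_root(self):
        """Modal root reconstruction matches a fixed simulated root state
        in most replicates when the tree carries enough signal."""
        q = np.array([0.4, 0.5, 0.4, 0.5, 0.4, 0.5, 0.4, 0.5])
        Q = tp.build_rate_matrix(q)
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            tree = tp.simulate_yule_tree(150, seed=1000 + r, scale_depth=1.0)
            tips, _ = tp.simulate_traits(tree, Q, root_state=tp.CompositeState.SA,
                                         seed=2000 + r)
            rec = marginal_ancestral_states(tree, tips, Q)
            if int(np.argmax(rec.root_vector(tree))) == int(tp.CompositeState.SA):
                hits += 1
        assert hits >= 0.7 * n_rep
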