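"""Marginal ancestral-state estimation at internal nodes.

For each node v the marginal posterior P(v = s | tip data) combines the
downward partial likelihood of the subtree below v with the "outside"
likelihood of everything else, both under the fitted generator.  This
is the per-node relative-likelihood display familiar from corHMM's
plotRECON pies: marginal, not joint, reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import N_STATES, STATE_NAMES
from .fitting import FitResult
from .likelihood import RootPolicy, TipStates, _pruned_partials, _root_weights
from .tree_io import PhyloTree

__all__ = ["AncestralReconstruction", "marginal_ancestral_states", "reconstruct_under_best"]


@dataclass
class AncestralReconstruction:
    """Per-node state probabilities under one fitted model.

    ``probs`` has one row per node (tree node index order); rows for
    internal nodes sum to one, tip rows are their (possibly unknown)
    observation vectors normalized.  Nodes are identified externally by
    postorder rank plus sorted descendant tip labels, which is stable
    across serializations of the same tree.
    """

    probs: np.ndarray
    model_name: str
    root_policy: str
    node_ids: list[str] = field(default_factory=list)

    def root_vector(self, tree: PhyloTree) -> np.ndarray:
        return self.probs[tree.root]

    def to_frame(self, tree: PhyloTree) -> pd.DataFrame:
        rows = []
        for rank, i in enumerate(tree.postorder()):
            tips = tree.descendant_tips(i)
            rows.append(
                {
                    "node_id": f"pn{rank}",
                    "is_tip": tree.is_tip(i),
                    "descendant_tips": ";".join(tips),
                    **{f"p_{s}": self.probs[i, j] for j, s in enumerate(STATE_NAMES)},
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, tree: PhyloTree, path) -> None:
        self.to_frame(tree).to_csv(path, sep="\t", index=False)

    def annotate_tree(self, tree: PhyloTree) -> PhyloTree:
        """Copy of the tree with per-node probability comments attached."""
        out = tree.scaled(1.0)
        for i in range(tree.n_nodes):
            parts = ",".join(
                f"p_{s}={self.probs[i, j]:.6g}" for j, s in enumerate(STATE_NAMES)
            )
            out.annotations[i] = parts
        return out


def marginal_ancestral_states(
    tree: PhyloTree,
    states: TipStates,
    Q: np.ndarray,
    root: RootPolicy = RootPolicy.FLAT,
) -> AncestralReconstruction:
    """Marginal P(node = s | data) at every node.

    Downward partials come from the pruning pass; a preorder pass then
    propagates outside likelihoods G: at the root G is the root-policy
    weight vector, and for a child c of v,

        G_c(s') = sum_s G_v(s) * [prod over siblings b of (P_b L_b)(s)]
                  * P_c(t_c)[s, s']

    The marginal at any node is the normalized product G * L; per-node
    normalization cancels all rescaling constants.
    """
    L, _, P = _pruned_partials(tree, states, Q)
    w = _root_weights(root, Q, L[tree.root])
    n = tree.n_nodes
    G = np.zeros((n, N_STATES))
    G[tree.root] = w
    for v in tree.preorder():
        kids = tree.children[v]
        if not kids:
            continue
        # messages from each child subtree into v
        msgs = {c: P[c] @ L[c] for c in kids}
        for c in kids:
            sib = G[v].copy()
            for b in kids:
                if b != c:
                    sib *= msgs[b]
            G[c] = sib @ P[c]
        # guard against total numerical washout deep in big trees
        for c in kids:
            m = G[c].max()
            if not np.isfinite(m):
                raise ArithmeticError(f"non-finite outside likelihood at node {c}")
            if m > 0:
                G[c] /= m

    probs = G * L
    totals = probs.sum(axis=1, keepdims=True)
    if np.any(~np.isfinite(totals)) or np.any(totals <= 0):
        bad = int(np.nonzero(~np.isfinite(totals.ravel()) | (totals.ravel() <= 0))[0][0])
        raise ArithmeticError(f"degenerate marginal at node {bad}")
    probs /= totals
    node_ids = [f"pn{r}" for r in range(n)]
    return AncestralReconstruction(
        probs=probs, model_name="", root_policy=root.value, node_ids=node_ids
    )


def reconstruct_under_best(
    tree: PhyloTree,
    states: TipStates,
    aic_table: pd.DataFrame,
    fits: "dict[str, FitResult]",
    root: RootPolicy = RootPolicy.FLAT,
) -> AncestralReconstruction:
    """Reconstruction under the AIC-best model of a completed sweep."""
    from .ctmc import build_rate_matrix

    if aic_table is None or len(aic_table) == 0:
        raise ValueError("empty AIC table: run model selection first")
    best_name = str(aic_table.iloc[0]["model"])
    if best_name not in fits:
        raise KeyError(f"no FitResult for AIC-best model {best_name!r}")
    Q = build_rate_matrix(fits[best_name].mle_rates)
    rec = marginal_ancestral_states(tree, states, Q, root)
    rec.model_name = best_name
    return rec
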