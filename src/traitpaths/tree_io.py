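"""Rooted phylogenetic trees: Newick I/O, validation, traversal.

Trees are stored in a flat, index-addressed form (parent pointers,
children lists, branch lengths) that the likelihood machinery can walk
without object overhead.  Parsing is delegated to dendropy; writing is a
small recursive serializer so that annotated output stays under our
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeError",
    "NewickParseError",
    "TreeValidationError",
    "read_newick",
    "write_newick",
    "is_ultrametric",
]


class TreeError(Exception):
    """Base class for tree construction and I/O failures."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the (line, column) of the offence."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class TreeValidationError(TreeError):
    """Structurally invalid tree (duplicate tips, bad branch lengths, ...)."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, stored as parallel arrays.

    Attributes
    ----------
    parent : int array, -1 for the root
    children : list of lists of child indices (empty for tips)
    branch_length : float array, length of the edge above each node
        (0.0 for the root)
    labels : list of node labels; nonempty and unique for tips, optional
        for internal nodes
    root : index of the root node
    """

    parent: np.ndarray
    children: list[list[int]]
    branch_length: np.ndarray
    labels: list[str | None]
    root: int
    # per-node annotation strings rendered as [&...] comments on write
    annotations: dict[int, str] = field(default_factory=dict)

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices()]  # type: ignore[misc]

    def internal_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices())

    def postorder(self) -> list[int]:
        """Node indices with every child before its parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for i in self.preorder():
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.branch_length[i]
        return depth

    def height(self) -> float:
        d = self.depths()
        return float(max(d[i] for i in self.tip_indices()))

    def descendant_tips(self, node: int) -> list[str]:
        """Sorted tip labels below (and including) ``node``."""
        out: list[str] = []
        stack = [node]
        while stack:
            i = stack.pop()
            if self.is_tip(i):
                out.append(self.labels[i])  # type: ignore[arg-type]
            else:
                stack.extend(self.children[i])
        return sorted(out)

    def scaled(self, factor: float) -> "PhyloTree":
        """Return a copy with all branch lengths multiplied by ``factor``."""
        return PhyloTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            branch_length=self.branch_length * factor,
            labels=list(self.labels),
            root=self.root,
            annotations=dict(self.annotations),
        )

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n = self.n_nodes
        roots = [i for i in range(n) if self.parent[i] < 0]
        if roots != [self.root]:
            raise TreeValidationError(
                f"expected a single root {self.root}, found parentless nodes {roots}"
            )
        for i in range(n):
            p = self.parent[i]
            if p >= 0 and i not in self.children[p]:
                raise TreeValidationError(f"node {i} missing from its parent's child list")
        tips = self.tip_labels()
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if any(t is None or t == "" for t in tips):
            raise TreeValidationError("every tip must carry a nonempty label")
        if np.any(self.branch_length < 0):
            bad = np.nonzero(self.branch_length < 0)[0].tolist()
            raise TreeValidationError(f"negative branch lengths at nodes {bad}")
        for i in range(n):
            if self.children[i] and len(self.children[i]) < 2 and i != self.root:
                raise TreeValidationError(f"internal node {i} has a single child")


def read_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Branch lengths are required on every non-root edge (a silently
    defaulted length would corrupt any likelihood computed on the tree);
    a missing root edge length is treated as 0.  Quoted labels and
    square-bracket comments are accepted and stripped.

    Raises
    ------
    NewickParseError
        On malformed input, reporting the offending line and column.
    TreeValidationError
        On duplicate tip labels or missing branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_leaf_node_taxa=True,  # duplicate labels reported by us, with a list
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(
            str(exc),
            line=getattr(exc, "line_num", None),
            column=getattr(exc, "col_num", None),
        ) from exc

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    n = len(dnodes)
    parent = np.full(n, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    lengths = np.zeros(n)
    labels: list[str | None] = [None] * n

    for i, nd in enumerate(dnodes):
        labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise TreeValidationError(
                    f"missing branch length on the edge above "
                    f"{labels[i] if labels[i] else f'node {i}'}"
                )
            lengths[i] = float(nd.edge.length)
        else:
            lengths[i] = float(nd.edge.length or 0.0)

    tree = PhyloTree(parent=parent, children=children, branch_length=lengths,
                     labels=labels, root=0)
    tree.validate()
    return tree


def _format_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: PhyloTree, include_annotations: bool = False) -> str:
    """Serialize to Newick; round-trips topology, labels and lengths.

    With ``include_annotations=True``, per-node annotation strings are
    emitted as ``[&...]`` comments after the node, which BEAST-family
    viewers understand.
    """

    def render(i: int) -> str:
        if tree.is_tip(i):
            core = _quote(tree.labels[i] or "")
        else:
            inner = ",".join(render(c) for c in tree.children[i])
            core = f"({inner})" + (_quote(tree.labels[i]) if tree.labels[i] else "")
        if include_annotations and i in tree.annotations:
            core += f"[&{tree.annotations[i]}]"
        if i != tree.root:
            core += f":{_format_length(tree.branch_length[i])}"
        return core

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return render(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def _quote(label: str) -> str:
    if label and any(ch in label for ch in "()[]{}:;,= \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def is_ultrametric(tree: PhyloTree, tolerance: float = 1e-9) -> bool:
    """True iff all root-to-tip path lengths agree within ``tolerance``."""
    d = tree.depths()
    tip_depths = [d[i] for i in tree.tip_indices()]
    return (max(tip_depths) - min(tip_depths)) <= tolerance


def node_table(tree: PhyloTree) -> "list[dict]":
    """Stable per-node identification: postorder index + sorted tip set.

    Newick child order is not canonical, so downstream outputs key nodes
    by their postorder position together with the sorted labels of the
    tips they subtend.
    """
    rows = []
    for rank, i in enumerate(tree.postorder()):
        rows.append(
            {
                "node": i,
                "postorder_rank": rank,
                "is_tip": tree.is_tip(i),
                "tips": ";".join(tree.descendant_tips(i)),
            }
        )
    return rows
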