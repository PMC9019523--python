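"""Shared helpers on rooted, branch-length-annotated phylogenies.

The package represents a phylogeny as a :class:`dendropy.Tree`.  Trees are
rooted; edge lengths are in Myr; the root carries no edge (its ``edge.length``
may be ``None`` or hold a stem length for clades extracted with their stem).
Polytomies are permitted everywhere.

This module adds the small amount of machinery the rest of the package needs
on top of dendropy: depth/age maps, ultrametricity checks, monophyly-aware
clade lookup, tip pruning with degree-2 suppression, fair-proportion
evolutionary distinctness, and a flat array index (:class:`IndexedTree`) used
by the sequential PD computations.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "clone",
    "parse_newick",
    "to_newick",
    "leaf_names",
    "node_depths",
    "tree_height",
    "is_ultrametric",
    "find_mrca",
    "prune_tips",
    "retain_tips",
    "fair_proportion",
    "IndexedTree",
]


def clone(tree: dendropy.Tree) -> dendropy.Tree:
    """Deep-copy a tree (taxon namespace shared)."""
    return tree.clone(depth=1)


def parse_newick(text: str, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=taxon_namespace,
    )


def to_newick(tree: dendropy.Tree) -> str:
    """Single-line Newick with unquoted underscore labels."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree, include_stem: bool = False) -> dict[dendropy.Node, float]:
    """Distance of every node from the root (root depth 0).

    With ``include_stem`` the seed node's own edge length (if any) is added,
    so depths are measured from the top of the stem edge.
    """
    depths: dict[dendropy.Node, float] = {}
    root = tree.seed_node
    base = 0.0
    if include_stem and root.edge.length is not None:
        base = float(root.edge.length)
    depths[root] = base
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        length = node.edge.length
        if length is None:
            length = 0.0
        depths[node] = depths[node.parent_node] + float(length)
    return depths


def tree_height(tree: dendropy.Tree, include_stem: bool = False) -> float:
    """Maximum root-to-tip distance (optionally including the stem edge)."""
    depths = node_depths(tree, include_stem=include_stem)
    return max(depths[lf] for lf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = node_depths(tree)
    tip_depths = [depths[lf] for lf in tree.leaf_node_iter()]
    hi, lo = max(tip_depths), min(tip_depths)
    if hi <= 0:
        return len(tip_depths) == 1
    return (hi - lo) / hi <= rel_tol


def find_mrca(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the named tips.

    Raises ``KeyError`` for tips not in the tree.
    """
    wanted = set(taxa)
    if not wanted:
        raise ValueError("taxa set is empty")
    tip_nodes = {}
    for lf in tree.leaf_node_iter():
        if lf.taxon.label in wanted:
            tip_nodes[lf.taxon.label] = lf
    missing = wanted - set(tip_nodes)
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    if len(tip_nodes) == 1:
        return next(iter(tip_nodes.values()))
    # walk each tip to the root once; the MRCA is the deepest node whose
    # ancestor-path count equals the number of target tips
    counts: dict[dendropy.Node, int] = {}
    for node in tip_nodes.values():
        cur = node
        while cur is not None:
            counts[cur] = counts.get(cur, 0) + 1
            cur = cur.parent_node
    n = len(tip_nodes)
    mrca = tree.seed_node
    depths = node_depths(tree)
    for node, c in counts.items():
        if c == n and depths[node] >= depths[mrca]:
            mrca = node
    return mrca


def _suppress_unifurcation(tree: dendropy.Tree, node: dendropy.Node) -> None:
    """Remove a degree-2 internal node, summing the two incident edge lengths.

    If the unifurcation is at the root, the single child becomes the new root
    and its (now dangling) stem edge is dropped.
    """
    children = node.child_nodes()
    if len(children) != 1:
        return
    child = children[0]
    parent = node.parent_node
    if parent is None:
        node.remove_child(child)
        child.edge.length = None
        tree.seed_node = child
        child.parent_node = None
        return
    added = node.edge.length or 0.0
    node.remove_child(child)
    parent.remove_child(node)
    parent.add_child(child)
    child.edge.length = (child.edge.length or 0.0) + added


def prune_tips(tree: dendropy.Tree, names: Iterable[str]) -> dendropy.Tree:
    """Remove named tips in place; suppress resulting degree-2 nodes.

    Pairwise path lengths among retained tips are preserved exactly (merged
    edges are summed).  Returns the tree for convenience.
    """
    drop = set(names)
    if not drop:
        return tree
    for lf in list(tree.leaf_node_iter()):
        if lf.taxon is not None and lf.taxon.label in drop:
            parent = lf.parent_node
            if parent is None:
                raise ValueError("cannot prune the only tip of a tree")
            parent.remove_child(lf)
            _suppress_unifurcation(tree, parent)
    remaining = [lf for lf in tree.leaf_node_iter()]
    if not remaining or (len(remaining) == 1 and remaining[0].taxon is None):
        raise ValueError("pruning removed every tip of the tree")
    return tree


def retain_tips(tree: dendropy.Tree, names: Iterable[str]) -> dendropy.Tree:
    keep = set(names)
    drop = [n for n in leaf_names(tree) if n not in keep]
    return prune_tips(tree, drop)


def fair_proportion(tree: dendropy.Tree) -> dict[str, float]:
    """Fair-proportion evolutionary distinctness per tip.

    Each edge's length is divided equally among the tips descending from it;
    a tip's score is the sum of its shares along its root-to-tip path.
    """
    n_desc: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_desc[node] = 1
        else:
            n_desc[node] = sum(n_desc[c] for c in node.child_nodes())
    share: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        share[node] = share[node.parent_node] + float(length) / n_desc[node]
    return {lf.taxon.label: share[lf] for lf in tree.leaf_node_iter()}


class IndexedTree:
    """Flat array view of a tree for fast repeated PD computations.

    Nodes are numbered in preorder; ``parent[i]`` is the parent index (-1 at
    the root) and ``edge_length[i]`` the length of the edge above node *i*
    (0 at the root — PD never includes a root edge).
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        index = {node: i for i, node in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.edge_length = np.zeros(n, dtype=np.float64)
        self.tip_index: dict[str, int] = {}
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                self.parent[i] = index[node.parent_node]
                self.edge_length[i] = float(node.edge.length or 0.0)
            if node.is_leaf():
                self.tip_index[node.taxon.label] = i
        self.n_nodes = n
        self.n_tips = len(self.tip_index)
        self.total_pd = float(self.edge_length.sum())

    def tip_indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.tip_index[nm] for nm in names], dtype=np.int64)

    def tip_depths(self) -> dict[str, float]:
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return {nm: float(depth[i]) for nm, i in self.tip_index.items()}

    def pd_of(self, names: Iterable[str]) -> float:
        """PD of the subtree spanned by the named tips plus the root.

        Sum of edge lengths on the union of root-to-tip paths.  This is the
        'known PD' of a set of described species on the full tree.
        """
        visited = np.zeros(self.n_nodes, dtype=bool)
        parent = self.parent
        elen = self.edge_length
        total = 0.0
        for nm in names:
            j = self.tip_index[nm]
            while j != -1 and not visited[j]:
                total += elen[j]
                visited[j] = True
                j = parent[j]
        return total

    def contribution_sequence(self, order: np.ndarray) -> np.ndarray:
        """Marginal PD contribution of each tip, added in ``order``.

        ``order`` holds node indices of tips, earliest discovery first.  The
        contribution of a tip is the path length from the tip up to its
        attachment point on the subtree spanned by earlier tips plus the
        root; the first tip is credited its full root-to-tip depth.
        Contributions sum exactly (up to float addition) to ``total_pd``
        when every tip appears once.
        """
        visited = np.zeros(self.n_nodes, dtype=bool)
        parent = self.parent
        elen = self.edge_length
        out = np.zeros(len(order), dtype=np.float64)
        for k, j0 in enumerate(order):
            s = 0.0
            j = int(j0)
            while j != -1 and not visited[j]:
                s += elen[j]
                visited[j] = True
                j = parent[j]
            out[k] = s
        return out
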