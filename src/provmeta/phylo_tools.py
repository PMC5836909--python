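"""Tree ingestion and the phylogenetic correlation machinery.

Trees are dendropy ``Tree`` objects read from Newick.  The workflow mirrors
standard comparative practice: prune to the study species, resolve
multichotomies (seeded), assign Grafen branch lengths (node height
proportional to descendant-tip count minus one, scaled to unit depth), and
derive the species correlation matrix whose (i, j) entry is the depth of
the most recent common ancestor measured from the root (0) towards the
tips (1).  Pagel's lambda rescales the off-diagonal of that matrix.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pandas as pd

ULTRAMETRIC_TOL = 1e-10

__all__ = [
    "read_tree",
    "write_tree",
    "tip_labels",
    "prune",
    "resolve_polytomies",
    "is_binary",
    "is_ultrametric",
    "grafen_lengths",
    "phylo_corr",
    "lambda_transform",
]


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune(tree: dendropy.Tree, species) -> dendropy.Tree:
    """Induced subtree on ``species``; degree-2 internals suppressed."""
    species = set(species)
    present = set(tip_labels(tree))
    absent = sorted(species - present)
    if absent:
        raise ValueError(f"species not in tree: {absent}")
    sub = tree.extract_tree_with_taxa_labels(
        labels=species, suppress_unifurcations=True
    )
    sub.is_rooted = True
    return sub


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Randomly resolve multichotomies to a binary tree (seeded).

    Inserted edges get length 0, so until branch lengths are recomputed the
    resolved tree encodes the same path lengths as the polytomy.
    """
    out = tree.clone(depth=1)
    out.resolve_polytomies(rng=random.Random(seed))
    for edge in out.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return out


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(node.child_nodes()) == 2
        for node in tree.preorder_node_iter()
        if not node.is_leaf()
    )


def _leaf_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    stack = [(tree.seed_node, 0.0)]
    while stack:
        node, d = stack.pop()
        for child in node.child_nodes():
            stack.append((child, d + (child.edge.length or 0.0)))
        if node.is_leaf():
            depths[node.taxon.label] = d
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-8) -> bool:
    depths = list(_leaf_depths(tree).values())
    return max(depths) - min(depths) <= tol * max(max(depths), 1.0)


def grafen_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Grafen's branch lengths: ultrametric, unit depth.

    Node height above the tips is ((d - 1) / (N - 1))**rho where d is the
    node's descendant-tip count and N the total tip count; tips sit at
    height 0, the root at height 1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    out = tree.clone(depth=1)
    n_total = len(out.leaf_nodes())
    if n_total < 2:
        raise ValueError("need at least 2 tips")
    heights = {}
    for node in out.postorder_node_iter():
        if node.is_leaf():
            node._ntips = 1
            heights[node] = 0.0
        else:
            node._ntips = sum(c._ntips for c in node.child_nodes())
            heights[node] = ((node._ntips - 1) / (n_total - 1)) ** rho
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
    out.seed_node.edge.length = None
    return out


def phylo_corr(tree: dendropy.Tree) -> pd.DataFrame:
    """Species correlation matrix from an ultrametric unit-depth tree.

    Entry (i, j) is the root-to-MRCA depth of tips i and j; the diagonal is
    1.  Rows/columns are sorted tip labels.
    """
    if not is_ultrametric(tree):
        raise ValueError(
            "tree is not ultrametric; apply grafen_lengths() first"
        )
    depths = _leaf_depths(tree)
    total = float(np.mean(list(depths.values())))
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"tree depth {total:.6g} != 1; apply grafen_lengths() first"
        )
    labels = sorted(depths)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    corr = np.zeros((n, n))

    # Postorder sweep: at each internal node, tips in different child
    # subtrees have that node as their MRCA.
    node_depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node_depth[node] = node_depth[node.parent_node] + (
                node.edge.length or 0.0
            )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [idx[node.taxon.label]]
            continue
        children = [c._tipset for c in node.child_nodes()]
        d = node_depth[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        corr[i, j] = corr[j, i] = d
        node._tipset = [t for ch in children for t in ch]
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=labels, columns=labels)


def lambda_transform(C: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Pagel's lambda rescaling: off-diagonals multiplied by lam."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = C.to_numpy(dtype=float, copy=True) * lam
    np.fill_diagonal(out, np.diag(C.to_numpy()))
    return pd.DataFrame(out, index=C.index, columns=C.columns)
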