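"""Phylogeny utilities: Newick IO, ultrametricity checks, and the
Brownian-motion covariance matrix.

Under Brownian trait evolution along a rooted ultrametric tree, the
covariance between species i and j is proportional to the root-to-tip
path length they share, i.e. the depth of their most recent common
ancestor. The resulting matrix backs the phylogenetic random effect of
the mixed models.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .errors import DataError

ULTRAMETRIC_TOL = 1e-6


def read_tree(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree):
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree):
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            edge = node.edge.length if node.edge.length is not None else 0.0
            depths[node] = depths[node.parent_node] + edge
    return depths


def check_ultrametric(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> float:
    """Return the tree depth; raise if tip depths differ beyond tolerance.

    Tolerance is relative to the tree depth (absolute for depth < 1).
    """
    depths = _node_depths(tree)
    tip_depths = np.array([depths[leaf] for leaf in tree.leaf_node_iter()])
    depth = float(tip_depths.max())
    scale = max(depth, 1.0)
    if np.ptp(tip_depths) > tol * scale:
        raise DataError(
            f"tree is not ultrametric: tip depths span "
            f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}]"
        )
    return depth


def phylo_covariance(tree: dendropy.Tree, scale_to_unit: bool = False):
    """Shared-path-length covariance matrix of an ultrametric tree.

    ``C[i, j]`` is the depth (from the root) of the most recent common
    ancestor of tips i and j; the diagonal equals the tree depth.
    Returns ``(labels, C)``. With ``scale_to_unit`` the matrix is divided
    by the tree depth so that the diagonal is one, which makes the
    phylogenetic variance component comparable across trees.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise DataError("phylogenetic covariance requires at least 2 tips")
    labels = [leaf.taxon.label for leaf in leaves]
    if len(set(labels)) != len(labels):
        raise DataError("duplicate tip labels")
    depth = check_ultrametric(tree)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    depths = _node_depths(tree)
    n = len(leaves)
    C = np.zeros((n, n))
    # postorder: record tip sets per node; pairs split across children of a
    # node have that node as their MRCA
    tipsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node]]
            continue
        children = [tipsets[ch] for ch in node.child_nodes()]
        d = depths[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tipsets[node] = [i for ch in children for i in ch]
    np.fill_diagonal(C, depth)
    if scale_to_unit:
        if depth <= 0:
            raise DataError("tree depth is zero; cannot scale covariance")
        C = C / depth
    return labels, C


def covariance_for(tree: dendropy.Tree, species, scale_to_unit: bool = True) -> np.ndarray:
    """Covariance matrix restricted and ordered to ``species``.

    Raises if any requested species is missing from the tree.
    """
    labels, C = phylo_covariance(tree, scale_to_unit=scale_to_unit)
    pos = {lab: i for i, lab in enumerate(labels)}
    missing = [s for s in species if s not in pos]
    if missing:
        raise DataError(f"species absent from tree: {missing}")
    idx = np.array([pos[s] for s in species])
    return C[np.ix_(idx, idx)]
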