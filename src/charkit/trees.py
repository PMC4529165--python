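"""Distance-based tree building shared by the SSR and ITS stages.

UPGMA (size-weighted arithmetic-mean agglomeration, ultrametric output) is
delegated to scipy's hierarchical clustering and converted to a scikit-bio
``TreeNode``.  BioNJ — neighbor joining with variance-weighted branch
combining (Gascuel 1997) — is implemented here; like NJ it is exact on
additive distance matrices.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "upgma",
    "bionj",
    "write_newick",
    "read_newick",
    "midpoint_root",
    "bipartitions",
    "is_ultrametric",
]


def _check_matrix(d: DistanceMatrix) -> None:
    if not np.all(np.isfinite(d.data)):
        raise ValueError("distance matrix contains non-finite entries")


def upgma(d: DistanceMatrix) -> TreeNode:
    """Ultrametric tree by unweighted pair-group average-linkage clustering.

    Branch lengths place every leaf at depth ``merge height / 2`` from the
    node joining it, so root-to-leaf depths are equal.
    """
    _check_matrix(d)
    ids = list(d.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    linkage = hierarchy.linkage(squareform(d.data, checks=False), method="average")
    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i], length=0.0) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    for step, (a, b, dist, _) in enumerate(linkage):
        a, b = int(a), int(b)
        h = dist / 2.0
        left, right = nodes.pop(a), nodes.pop(b)
        left.length = h - heights[a]
        right.length = h - heights[b]
        new = TreeNode(children=[left, right], length=0.0)
        nodes[n + step] = new
        heights[n + step] = h
    (root,) = nodes.values()
    root.length = None
    return root


def bionj(d: DistanceMatrix) -> TreeNode:
    """Unrooted BioNJ tree.

    Standard neighbor-joining selection (Q criterion); when nodes i and j
    are joined, the reduced distances use a variance-minimizing weight
    ``lambda`` instead of NJ's fixed 1/2, with first-order variances
    initialised to the distances themselves.
    """
    _check_matrix(d)
    ids = list(d.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = d.data.astype(float).copy()
    V = D.copy()  # variance estimates
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        bj = dij - bi
        # variance-weighted combining
        others = [k for k in active if k not in (i, j)]
        vij = V[i, j]
        if vij > 0:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (2 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, bi)
        child_j.length = max(0.0, bj)
        new = TreeNode(children=[child_i, child_j])
        newD = np.append(D, np.zeros((1, D.shape[1])), axis=0)
        newD = np.append(newD, np.zeros((newD.shape[0], 1)), axis=1)
        newV = np.append(V, np.zeros((1, V.shape[1])), axis=0)
        newV = np.append(newV, np.zeros((newV.shape[0], 1)), axis=1)
        u = newD.shape[0] - 1
        for k in others:
            newD[u, k] = newD[k, u] = lam * D[i, k] + (1 - lam) * D[j, k] - lam * bi - (1 - lam) * bj
            newV[u, k] = newV[k, u] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij
        D, V = newD, newV
        nodes.append(new)
        active = others + [u]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(0.0, ln)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a newick string (labels quoted where needed)."""
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))


def midpoint_root(tree: TreeNode) -> TreeNode:
    return tree.root_at_midpoint()


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree.

    Each internal edge is represented by the smaller-or-lexicographically-
    first side of the leaf-label split, making the set rooting-invariant.
    """
    all_leaves = frozenset(n.name for n in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), sorted(s)))
        parts.add(canon)
    return parts


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return max(depths) - min(depths) < tol


def distance_matrix(labels: Sequence[str], data: np.ndarray) -> DistanceMatrix:
    """Labelled symmetric distance matrix (validates symmetry/diagonal)."""
    return DistanceMatrix(data, ids=list(labels))
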