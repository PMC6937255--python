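"""Neighbor-joining trees and size-based cluster definition.

A desk-scale tree builder used to validate sub-class clusters: classical
neighbor joining on a symmetric distance matrix (identity distances by
default), newick output, and a recursive clade-splitting rule that turns a
tree into cluster assignments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


def nj_tree(dist: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Classical neighbor joining.

    Requires a symmetric matrix with a zero diagonal and at least 3 taxa.
    Deterministic: equal-Q joins resolve by taxon index order.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] != len(ids):
        raise ValueError("ids must match matrix dimension")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    d = (d + d.T) / 2.0  # remove float-level asymmetry
    np.fill_diagonal(d, 0.0)
    return nj(DistanceMatrix(d, list(ids)))


def to_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    s = str(tree).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def from_newick(source: str | Path) -> TreeNode:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return TreeNode.read([text.strip()])


def tip_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Patristic (path-length) distances between all tips."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data.copy()


def _tips(node: TreeNode) -> list[str]:
    if node.is_tip():
        return [node.name]
    return [t.name for t in node.tips()]


def define_clusters(tree: TreeNode, min_support_size: int = 2) -> dict[str, str]:
    """Partition leaves into clades of at least ``min_support_size`` leaves.

    The tree is midpoint-rooted and descended from the root: at each node,
    every child clade holding >= ``min_support_size`` leaves is split out and
    recursed into; a node with no such child becomes one cluster.  Child
    clades below the size floor at a splitting node are kept intact as their
    own (small) clusters rather than scattered.

    ``min_support_size`` therefore acts as the expected minimum cluster
    size: 1 dissolves the tree into leaves, a value above the leaf count
    returns a single all-leaf cluster.
    """
    if min_support_size < 1:
        raise ValueError("min_support_size must be >= 1")
    work = tree.copy()
    try:
        work = work.root_at_midpoint()
    except Exception:
        pass  # zero-length or degenerate trees: keep original rooting
    clusters: dict[str, str] = {}
    counter = [0]

    def emit(leaves: list[str]) -> None:
        counter[0] += 1
        cid = f"C{counter[0]}"
        for leaf in leaves:
            clusters[leaf] = cid

    def rec(node: TreeNode) -> None:
        if node.is_tip():
            emit([node.name])
            return
        kids = list(node.children)
        big = [c for c in kids if len(_tips(c)) >= min_support_size]
        if not big:
            emit(_tips(node))
            return
        for c in kids:
            if c in big:
                rec(c)
            else:
                emit(_tips(c))

    rec(work)
    return clusters
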