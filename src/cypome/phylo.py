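"""Distance-based phylogeny of P450 protein sequences.

Pairwise distances are ``1 - identity/100`` from the global aligner, and trees
are built with Saitou-Nei neighbor joining.  Neighbor joining is exact on
additive distance matrices and fully deterministic here: at every step the
pair with the smallest Q criterion is joined, ties broken by (lexicographic)
label order, and negative branch-length estimates are clamped to zero.  The
resulting tree is unrooted (the root is a degree-3 internal vertex) and is
consumed downstream only through nearest-named-leaf queries, which resolve
subfamily calls whose identity sits on the 55% borderline.

Trees are :class:`skbio.TreeNode` objects, so Newick round-trips and path
lengths come from scikit-bio.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .config import AlignScoring
from .io import ProteinRecord
from .nomenclature import percent_identity


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over labelled sequences."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")


def distance_matrix(records: Sequence[ProteinRecord],
                    scoring: AlignScoring = AlignScoring()) -> DistanceMatrix:
    """All-pairs identity distances, d(i,j) = 1 - identity(i,j)/100."""
    if len(records) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    labels = [r.id for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = percent_identity(records[i].sequence,
                                     records[j].sequence, scoring)
            d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(labels, d)


def _three_point_lengths(d: np.ndarray) -> tuple[float, float, float]:
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    return max(la, 0.0), max(lb, 0.0), max(lc, 0.0)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Requires >= 3 taxa.  Returns an unrooted binary tree whose root is the
    final degree-3 join.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.copy()
    nodes = [TreeNode(name=label) for label in dm.labels]
    # tie-break label for each working node: minimum leaf label beneath it
    tie_labels = list(dm.labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None  # (q, label_pair, i, j)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((tie_labels[i], tie_labels[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best[0], best[1], best[2]
        dij = d[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_row = np.array([
            max((d[i, k] + d[j, k] - dij) / 2.0, 0.0) for k in keep
        ])
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]
        tie_labels = [tie_labels[k] for k in keep] + [
            min(tie_labels[i], tie_labels[j])
        ]

    la, lb, lc = _three_point_lengths(d)
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
    return TreeNode(children=list(nodes))


def to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick), format="newick")


def nearest_named_leaf(tree: TreeNode, query_id: str,
                       named_ids: Sequence[str]) -> str:
    """Named leaf with the smallest path length to the query leaf.

    Ties are broken by lexicographic label order.  Raises if the query is not
    a leaf of the tree or if no named id is present.
    """
    if not named_ids:
        raise ValueError("named_ids is empty")
    try:
        query = tree.find(query_id)
    except Exception as exc:
        raise ValueError(f"query {query_id!r} not found in tree") from exc
    present = [name for name in named_ids if name != query_id]
    best_name, best_dist = None, None
    for name in sorted(present):
        try:
            node = tree.find(name)
        except Exception:
            continue
        dist = query.distance(node)
        if best_dist is None or dist < best_dist:
            best_name, best_dist = name, dist
    if best_name is None:
        raise ValueError("no named leaf present in tree")
    return best_name


def path_length_matrix(tree: TreeNode,
                       labels: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths in the order of ``labels``."""
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = tips[labels[i]].distance(tips[labels[j]])
            out[i, j] = out[j, i] = dist
    return out
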