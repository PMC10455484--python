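"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written without reference to the package
implementation: a quadratic-space Gotoh dynamic program for affine-gap global
alignment scores, a recompute-from-scratch average-linkage clusterer, a
random additive-tree generator, and the explicit triage decision table.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from skbio import TreeNode

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_NEG = -1e9


def gotoh_score(a: str, b: str, open_: float = 10.0,
                ext: float = 1.0) -> float:
    """Optimal global affine-gap alignment score (gap of length L costs
    open + (L-1)*ext), computed by explicit dynamic programming."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (a residue unmatched)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = -open_ - (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_, X[i - 1, j] - ext,
                          Y[i - 1, j] - open_)
            Y[i, j] = max(M[i, j - 1] - open_, Y[i, j - 1] - ext,
                          X[i, j - 1] - open_)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def average_linkage_heights(data: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, recomputing every
    cluster-to-cluster distance from the raw leaf matrix at each step
    (no Lance-Williams shortcut).  Ties break on the smallest cluster-index
    pair, matching the package's convention."""
    n = data.shape[0]
    members = {i: [i] for i in range(n)}
    next_id = n
    heights = []
    while len(members) > 1:
        keys = sorted(members)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                dist = float(np.mean([
                    np.linalg.norm(data[x] - data[y])
                    for x in members[a] for y in members[b]
                ]))
                if best is None or dist < best[0] - 1e-12:
                    best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        members[next_id] = members.pop(a) + members.pop(b)
        next_id += 1
    return heights


def random_additive_tree(rng: np.random.Generator, n_leaves: int,
                         length_range=(0.01, 0.5)):
    """A random binary tree with uniform branch lengths; returns
    (tree, sorted leaf labels, leaf-to-leaf path-length matrix)."""
    nodes = [TreeNode(name=f"T{i:02d}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(*length_range))
        b.length = float(rng.uniform(*length_range))
        nodes.append(TreeNode(children=[a, b]))
    tree = nodes[0]
    labels = sorted(t.name for t in tree.tips())
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    dist = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            d = tips[labels[x]].distance(tips[labels[y]])
            dist[x, y] = dist[y, x] = d
    return tree, labels, dist


def triage_decision_table():
    """All 12 combinations of motif count x length bin x reference-identity
    bin, with the category each must produce."""
    cases = []
    for n_motifs in (0, 1, 2):
        for long_enough in (False, True):
            for identity in (10.0, 25.0):
                if n_motifs == 2:
                    expected = "P450" if long_enough else "FRAGMENT"
                elif n_motifs == 1:
                    expected = "FRAGMENT"
                elif identity >= 20.0:
                    expected = "FALSE_POSITIVE"
                else:
                    expected = "NO_HIT"
                cases.append((n_motifs, long_enough, identity, expected))
    return cases


def make_candidate(n_motifs: int, length: int) -> str:
    """A candidate sequence carrying exactly the requested motif count.

    Poly-alanine carries neither motif; an EALR block provides ExxR and a
    CAG block in the final third provides the heme CxG.
    """
    chars = ["A"] * length
    if n_motifs >= 1:
        chars[10:14] = list("EALR")
    if n_motifs >= 2:
        pos = length - 10
        chars[pos:pos + 3] = list("CAG")
    return "".join(chars)
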