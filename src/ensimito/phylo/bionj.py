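"""BioNJ: variance-weighted neighbor joining (Gascuel's agglomeration).

BioNJ follows the neighbor-joining Q-criterion to pick the pair to
agglomerate, estimates branch lengths with the standard NJ formulas,
and then — unlike plain NJ — propagates a first-order variance model
of the distance estimates, choosing the reduction weight lambda that
minimizes the variance of the new distances.  On noiseless additive
matrices it returns the generating tree exactly.  Ties are broken
toward the lowest taxon-index pair, making the construction
deterministic.
"""

from __future__ import annotations

import numpy as np

from .tree import Node, Tree

__all__ = ["bionj"]


def bionj(taxa: list[str], distances: np.ndarray, variances: np.ndarray | None = None) -> Tree:
    """Build an unrooted tree from a distance matrix by BioNJ.

    ``variances`` defaults to the distances themselves (the standard
    BioNJ choice for sequence-derived estimates).
    """
    D = np.asarray(distances, float).copy()
    n = len(taxa)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    V = np.asarray(variances, float).copy() if variances is not None else D.copy()

    nodes = [Node(name=t) for t in taxa]
    active = list(range(n))
    if n == 2:
        root = Node()
        a, b = nodes
        a.length = b.length = D[0, 1] / 2
        root.add(a)
        root.add(b)
        return Tree(root)

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        S = sub.sum(axis=1)
        # Q criterion; lowest-index tie-break via argmin over the upper triangle
        best = None
        for ai in range(r):
            for bi in range(ai + 1, r):
                q = (r - 2) * sub[ai, bi] - S[ai] - S[bi]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        bi_len = 0.5 * dij + (S[ai] - S[bi]) / (2 * (r - 2))
        bj_len = dij - bi_len
        bi_len = max(bi_len, 0.0)
        bj_len = max(bj_len, 0.0)
        # lambda minimizing the variance of the reduced distances
        others = [k for k in active if k != i and k != j]
        if V[i, j] > 1e-12 and others:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (
                2.0 * (r - 2) * V[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        parent = Node()
        nodes[i].length = bi_len
        nodes[j].length = bj_len
        parent.add(nodes[i])
        parent.add(nodes[j])
        # reuse slot i for the new node
        for k in others:
            newd = lam * (D[i, k] - bi_len) + (1 - lam) * (D[j, k] - bj_len)
            newv = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * V[i, j]
            D[i, k] = D[k, i] = max(newd, 0.0)
            V[i, k] = V[k, i] = max(newv, 0.0)
        nodes[i] = parent
        active.remove(j)

    root = Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for k, ln in zip((a, b, c), (la, lb, lc)):
            nodes[k].length = max(ln, 0.0)
            root.add(nodes[k])
    else:  # n == 3 handled above; n cannot be < 3 here
        for k in active:
            root.add(nodes[k])
    return Tree(root)
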