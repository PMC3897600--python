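"""Pairwise sequence distances feeding the BioNJ starting tree."""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["p_distance", "jc_distance", "gtr_distance", "distance_matrix",
           "SATURATION_CAP"]

SATURATION_CAP = 5.0

_VALID = set("ACGT")


def _comparable(seq1: str, seq2: str):
    s1, s2 = seq1.upper().replace("U", "T"), seq2.upper().replace("U", "T")
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    pairs = [(a, b) for a, b in zip(s1, s2) if a in _VALID and b in _VALID]
    if not pairs:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    return pairs


def p_distance(seq1: str, seq2: str) -> float:
    """Fraction of differing comparable sites."""
    pairs = _comparable(seq1, seq2)
    return sum(a != b for a, b in pairs) / len(pairs)


def jc_distance(seq1: str, seq2: str, cap: float = SATURATION_CAP) -> float:
    """Jukes-Cantor distance -3/4 ln(1 - 4p/3), capped at saturation."""
    p = p_distance(seq1, seq2)
    if p >= 0.75:
        warnings.warn("saturated pair (p >= 0.75); distance capped")
        return cap
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return min(d, cap)


def gtr_distance(seq1: str, seq2: str, params, cap: float = SATURATION_CAP) -> float:
    """Pairwise ML distance under a fixed GTR(+I+Γ) parameter block.

    Maximizes sum_sites ln(pi_x P_xy(t)) over the separation t by
    bounded scalar search; the mixture categories of ``params`` are
    integrated out per site.
    """
    from scipy.optimize import minimize_scalar

    from .model import BASE_INDEX, GTRModel

    pairs = _comparable(seq1, seq2)
    counts = np.zeros((4, 4))
    for a, b in pairs:
        counts[BASE_INDEX[a], BASE_INDEX[b]] += 1
    model = GTRModel(params)
    w = model.category_weights

    def neg_lnl(t: float) -> float:
        P = np.tensordot(w, model.transition_matrices(t), axes=1)
        M = np.clip(model.pi[:, None] * P, 1e-300, None)
        return -float((counts * np.log(M)).sum())

    res = minimize_scalar(neg_lnl, bounds=(1e-8, cap), method="bounded",
                          options={"xatol": 1e-8})
    d = float(res.x)
    if d >= cap - 1e-6:
        warnings.warn("pairwise GTR distance hit the saturation cap")
    return min(d, cap)


def distance_matrix(taxa: list[str], rows: list[str], method: str = "jc",
                    params=None) -> np.ndarray:
    """Symmetric pairwise distance matrix over alignment rows."""
    if method == "gtr":
        fn = lambda a, b: gtr_distance(a, b, params)
    else:
        fn = {"jc": jc_distance, "p": p_distance}[method]
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(rows[i], rows[j])
    return D
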