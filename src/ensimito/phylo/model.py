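"""GTR+I+Γ substitution model: rate matrix, discrete gamma, transition matrices.

The general time-reversible (GTR) model parameterizes the instantaneous
rate matrix as Q_ij = s_ij * pi_j (i != j) with six symmetric
exchangeabilities s_ij (G<->T fixed to 1 for identifiability) and
stationary base frequencies pi.  Rate heterogeneity across sites is a
mixture of a proportion p_inv of invariant sites (rate 0) and a
discrete gamma distribution with shape alpha (equal-probability
categories, category means by the incomplete-gamma formula).  The
mixture is renormalized so the expected rate over categories is 1,
making branch lengths expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaincinv, gammainc
from scipy.stats import gamma as _gamma_dist

__all__ = ["GTRParams", "discrete_gamma_rates", "GTRModel", "BASES", "BASE_INDEX"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: order of the six exchangeabilities
EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass(frozen=True)
class GTRParams:
    """Parameter block for GTR+I+Γ.

    ``exchangeabilities`` follow the order AC, AG, AT, CG, CT, GT with
    GT conventionally 1.  ``p_inv`` is the proportion of invariant
    sites, ``alpha`` the gamma shape, ``n_categories`` the number of
    discrete gamma categories.
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    p_inv: float = 0.0
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        pi = np.asarray(self.base_freqs, float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("base_freqs must be 4 positive values summing to 1")
        ex = np.asarray(self.exchangeabilities, float)
        if ex.shape != (6,) or np.any(ex <= 0):
            raise ValueError("exchangeabilities must be 6 positive values")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, mean 1).

    Category boundaries are the distribution quantiles; each category's
    rate is its conditional mean, computed from the incomplete gamma
    function, so the rates average exactly 1.
    """
    if k == 1:
        return np.ones(1)
    bounds = gammaincinv(alpha, np.arange(1, k) / k) / alpha
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, alpha * bounds[1:]))
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


class GTRModel:
    """Cached eigendecomposition of a GTR+I+Γ parameter block.

    Provides transition matrices P(t) per rate category and the
    mixture weights/rates.  The rate matrix is scaled so the expected
    substitution rate over the +I+Γ mixture is 1.
    """

    def __init__(self, params: GTRParams):
        self.params = params
        pi = np.asarray(params.base_freqs, float)
        ex = params.exchangeabilities
        S = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), s in zip(pairs, ex):
            S[i, j] = S[j, i] = s
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))  # mean rate of the unscaled matrix
        Q /= mu
        self.pi = pi
        self.Q = Q  # mean rate 1 before the +I+Gamma mixture scaling
        # symmetrize for a stable eigendecomposition:  B = D^1/2 Q D^-1/2
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2)
        self.eigval = w
        self.U = V / sq[:, None] * 1.0  # right transform: P = D^-1/2 V e^{wt} V^T D^1/2
        self.U = (1.0 / sq)[:, None] * V
        self.Uinv = V.T * sq[None, :]
        # mixture: invariant category + k gamma categories, mean rate 1
        k = params.n_categories
        g = discrete_gamma_rates(params.alpha, k)
        if params.p_inv > 0:
            self.category_rates = np.concatenate([[0.0], g / (1.0 - params.p_inv)])
            self.category_weights = np.concatenate(
                [[params.p_inv], np.full(k, (1.0 - params.p_inv) / k)]
            )
        else:
            self.category_rates = g
            self.category_weights = np.full(k, 1.0 / k)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) under the scaled rate matrix at one category rate."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.U * np.exp(self.eigval * rate * t)) @ self.Uinv
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t) over all mixture categories, shape (k, 4, 4)."""
        return np.stack([self.transition_matrix(t, r) for r in self.category_rates])


def gtr_transition_matrix(params: GTRParams, t: float, rate: float = 1.0) -> np.ndarray:
    """Convenience wrapper: one transition matrix from a parameter block."""
    return GTRModel(params).transition_matrix(t, rate)
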