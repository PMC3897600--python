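"""Felsenstein pruning under GTR+I+Γ, with branch and model optimization.

The log-likelihood of an alignment on an unrooted tree is computed by
the pruning algorithm over compressed site patterns, with per-node
rescaling to avoid underflow and the +I+Γ rate mixture summed per
site.  Gaps and ambiguity codes are treated as missing data (partial
likelihood 1 for every compatible state), so the likelihood is
invariant under re-rooting (pulley principle) and taxon order.

Branch lengths are optimized one edge at a time by bounded scalar
search on the exact one-dimensional likelihood profile: with the
eigendecomposition P(t) = U e^{Lambda r t} U^-1, the site likelihood
along one edge is a 4-term exponential sum whose coefficients come
from the partials on either side of the edge, so each trial length
costs O(patterns x 4) only.

``log_likelihood_bruteforce`` sums over all internal-node state
assignments and serves as an independent oracle for small trees.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .model import BASE_INDEX, GTRModel, GTRParams
from .tree import Node, Tree

__all__ = [
    "SiteData",
    "PruningEngine",
    "log_likelihood",
    "log_likelihood_bruteforce",
    "optimize_branch_lengths",
    "optimize_model",
    "empirical_base_freqs",
]

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0

_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}


class SiteData:
    """Pattern-compressed alignment with per-taxon tip partials."""

    def __init__(self, taxa: list[str], rows: list[str]):
        if len(taxa) != len(set(taxa)):
            raise ValueError("duplicate taxon names")
        if len({len(r) for r in rows}) > 1:
            raise ValueError("alignment rows differ in length")
        self.taxa = list(taxa)
        codes = np.zeros((len(rows), len(rows[0])), dtype=np.uint8)
        keys = {}
        for sym, states in _AMBIG.items():
            mask = 0
            for s in states:
                mask |= 1 << BASE_INDEX[s]
            keys[sym] = mask
        for i, row in enumerate(rows):
            try:
                codes[i] = [keys[ch] for ch in row.upper()]
            except KeyError as exc:
                raise ValueError(f"unknown state {exc} in row for {taxa[i]}")
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.weights = weights.astype(float)
        self.n_sites = len(rows[0])
        self.n_patterns = patterns.shape[1]
        self.tip_partials = {}
        for i, name in enumerate(taxa):
            part = np.zeros((self.n_patterns, 4))
            for b in range(4):
                part[:, b] = (patterns[i] >> b) & 1
            self.tip_partials[name] = part

    @classmethod
    def from_mapping(cls, seqs: dict[str, str]) -> "SiteData":
        names = list(seqs)
        return cls(names, [seqs[n] for n in names])


class PruningEngine:
    """Pruning likelihood on one tree, with cached partials per category."""

    def __init__(self, data: SiteData, tree: Tree, params: GTRParams,
                 model: GTRModel | None = None):
        self.data = data
        self.tree = tree
        self.params = params
        self.model = model if model is not None else GTRModel(params)
        if set(tree.taxa) != set(data.taxa):
            raise ValueError("taxa of tree and alignment differ")
        self.nodes = tree.postorder()
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.ncat = len(self.model.category_rates)
        npat = data.n_patterns
        self.D = [None] * len(self.nodes)          # down partials (ncat, npat, 4)
        self.Dscale = [None] * len(self.nodes)     # log scalers (ncat, npat)
        self.B = [None] * len(self.nodes)          # above partials for edges
        self.Bscale = [None] * len(self.nodes)
        self._P_cache: dict[int, np.ndarray] = {}

    # -- transition matrices -----------------------------------------
    def _P(self, node: Node) -> np.ndarray:
        key = id(node)
        cached = self._P_cache.get(key)
        if cached is not None and cached[0] == node.length:
            return cached[1]
        P = self.model.transition_matrices(max(node.length, 0.0))
        self._P_cache[key] = (node.length, P)
        return P

    # -- pruning passes ----------------------------------------------
    def compute_down(self) -> None:
        npat = self.data.n_patterns
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                tip = self.data.tip_partials[node.name]
                self.D[i] = np.broadcast_to(tip, (self.ncat, npat, 4))
                self.Dscale[i] = None  # zeros, elided
            else:
                part = None
                scale = None
                for child in node.children:
                    j = self.index[id(child)]
                    P = self._P(child)
                    msg = self.D[j] @ P.transpose(0, 2, 1)
                    part = msg if part is None else part * msg
                    if self.Dscale[j] is not None:
                        scale = self.Dscale[j] if scale is None else scale + self.Dscale[j]
                mx = part.max(axis=2)
                mx[mx == 0.0] = 1.0
                part /= mx[:, :, None]
                lg = np.log(mx)
                self.D[i] = part
                self.Dscale[i] = lg if scale is None else scale + lg

    def compute_up(self) -> None:
        """Above partials B[v] (rest-of-tree at the parent end of edge v)."""
        pi = self.model.pi
        npat = self.data.n_patterns
        root_i = self.index[id(self.tree.root)]
        A = [None] * len(self.nodes)
        Ascale = [None] * len(self.nodes)
        A[root_i] = np.broadcast_to(pi, (self.ncat, npat, 4))
        Ascale[root_i] = 0.0
        for node in reversed(self.nodes):  # pre-order
            if node.is_leaf:
                continue
            i = self.index[id(node)]
            msgs = []
            for child in node.children:
                j = self.index[id(child)]
                P = self._P(child)
                msgs.append((j, self.D[j] @ P.transpose(0, 2, 1),
                             0.0 if self.Dscale[j] is None else self.Dscale[j]))
            for j, _, _ in msgs:
                B = A[i]
                Bscale = Ascale[i]
                for k, msg, msc in msgs:
                    if k == j:
                        continue
                    B = B * msg
                    Bscale = Bscale + msc
                if B is A[i]:
                    B = B.copy()
                mx = B.max(axis=2)
                mx[mx == 0.0] = 1.0
                B /= mx[:, :, None]
                Bscale = Bscale + np.log(mx)
                self.B[j] = B
                self.Bscale[j] = Bscale
                child = self.nodes[j]
                if not child.is_leaf:
                    P = self._P(child)
                    A[j] = B @ P
                    Ascale[j] = Bscale

    # -- likelihoods -------------------------------------------------
    def log_likelihood(self) -> float:
        self.compute_down()
        root_i = self.index[id(self.tree.root)]
        pi = self.model.pi
        site = self.D[root_i] @ pi
        logw = np.log(self.model.category_weights)[:, None]
        scale = self.Dscale[root_i]
        if scale is None:
            scale = 0.0
        with np.errstate(divide="ignore"):
            lse = logsumexp(np.log(site) + scale + logw, axis=0)
        return float(np.dot(lse, self.data.weights))

    def edge_profile(self, node: Node):
        """Return f(t) giving the lnL as a function of this edge's length.

        Requires compute_down() and compute_up() to be current.
        """
        i = self.index[id(node)]
        U, Uinv, eig = self.model.U, self.model.Uinv, self.model.eigval
        rates = self.model.category_rates
        F = (self.B[i] @ U) * (self.D[i] @ Uinv.T)
        dscale = 0.0 if self.Dscale[i] is None else self.Dscale[i]
        base_scale = self.Bscale[i] + dscale + np.log(
            self.model.category_weights
        )[:, None]
        w = self.data.weights

        def f(t: float) -> float:
            e = np.exp(np.outer(rates, eig) * t)  # (ncat, 4)
            site = np.einsum("cpk,ck->cp", F, e)
            site = np.clip(site, 1e-300, None)
            lse = logsumexp(np.log(site) + base_scale, axis=0)
            return float(np.dot(lse, w))

        return f

    def optimize_edge(self, node: Node) -> float:
        f = self.edge_profile(node)
        res = minimize_scalar(
            lambda x: -f(x), bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
            options={"xatol": 1e-6},
        )
        if -res.fun >= f(node.length):
            node.length = float(res.x)
        self._P_cache.pop(id(node), None)
        return f(node.length)


def log_likelihood(data, tree: Tree, params: GTRParams) -> float:
    """Pruning log-likelihood of an alignment on a tree under GTR+I+Γ."""
    data = _as_sitedata(data)
    return PruningEngine(data, tree, params).log_likelihood()


def _as_sitedata(data) -> SiteData:
    if isinstance(data, SiteData):
        return data
    if isinstance(data, dict):
        return SiteData.from_mapping(data)
    # supermatrix-like: taxa + rows attributes
    return SiteData(list(data.taxa), list(data.rows))


def log_likelihood_bruteforce(data, tree: Tree, params: GTRParams) -> float:
    """Exhaustive sum over internal-node states; oracle for small trees."""
    data = _as_sitedata(data)
    model = GTRModel(params)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    if len(internals) > 6:
        raise ValueError("brute force is for small trees only")
    mix = np.zeros((len(model.category_rates), data.n_patterns))
    for c, rate in enumerate(model.category_rates):
        P = {id(n): model.transition_matrix(n.length, rate) for n in nodes
             if n is not tree.root}
        site = np.zeros(data.n_patterns)
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, states)}
            term = np.full(data.n_patterns, model.pi[assign[id(tree.root)]])
            for n in nodes:
                if n is tree.root:
                    continue
                ps = assign[id(n.parent)]
                if n.is_leaf:
                    term = term * (data.tip_partials[n.name] * P[id(n)][ps, :]).sum(axis=1)
                else:
                    term = term * P[id(n)][ps, assign[id(n)]]
            site += term
        mix[c] = site
    site_l = model.category_weights @ mix
    return float(np.dot(np.log(site_l), data.weights))


def optimize_branch_lengths(
    tree: Tree,
    data,
    params: GTRParams,
    max_sweeps: int = 5,
    tol: float = 1e-4,
) -> tuple[Tree, float]:
    """Coordinate-wise branch-length optimization; lnL never decreases.

    Each sweep refreshes the two pruning passes once and then
    optimizes every edge on its (slightly stale) one-dimensional
    profile; a sweep that fails to improve the exact likelihood is
    redone with per-edge refreshes, so the reported likelihood is
    monotone non-decreasing across sweeps.
    """
    data = _as_sitedata(data)
    tree = tree.copy()
    engine = PruningEngine(data, tree, params)
    edges = [n for n in engine.nodes if n is not tree.root]
    last = engine.log_likelihood()
    for _ in range(max_sweeps):
        saved = [e.length for e in edges]
        engine.compute_down()
        engine.compute_up()
        for node in edges:
            f = engine.edge_profile(node)
            res = minimize_scalar(lambda x: -f(x), bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded", options={"xatol": 1e-6})
            if -res.fun > f(node.length):
                node.length = float(res.x)
                engine._P_cache.pop(id(node), None)
        current = engine.log_likelihood()
        if current < last - 1e-9:
            # stale profiles misled the sweep: restore and refresh per edge
            for e, ln in zip(edges, saved):
                e.length = ln
            engine._P_cache.clear()
            for node in edges:
                engine.compute_down()
                engine.compute_up()
                engine.optimize_edge(node)
            current = engine.log_likelihood()
            if current < last - 1e-9:  # numerically stuck; keep previous state
                for e, ln in zip(edges, saved):
                    e.length = ln
                current = last
        if current - last < tol:
            last = max(current, last)
            break
        last = current
    return tree, last


def empirical_base_freqs(data) -> tuple[float, float, float, float]:
    data = _as_sitedata(data)
    counts = np.zeros(4)
    for name, part in data.tip_partials.items():
        resolved = part.sum(axis=1) == 1
        counts += (part[resolved] * data.weights[resolved, None]).sum(axis=0)
    if counts.sum() == 0:
        return (0.25, 0.25, 0.25, 0.25)
    freqs = counts / counts.sum()
    freqs = np.clip(freqs, 1e-4, None)
    freqs /= freqs.sum()
    return tuple(float(x) for x in freqs)


def optimize_model(
    tree: Tree,
    data,
    params: GTRParams,
    optimize_freqs: bool = False,
    maxiter: int = 60,
) -> tuple[GTRParams, float]:
    """ML estimation of exchangeabilities, alpha and p_inv on a fixed tree.

    Base frequencies stay at their (empirical or supplied) values
    unless ``optimize_freqs`` is set; GT exchangeability is fixed to 1.
    """
    data = _as_sitedata(data)

    def unpack(x: np.ndarray) -> GTRParams:
        ex = tuple(np.exp(x[:5])) + (1.0,)
        alpha = float(np.exp(x[5]))
        p_inv = float(1.0 / (1.0 + np.exp(-x[6])))
        p_inv = min(p_inv, 0.99)
        kw = dict(exchangeabilities=ex, alpha=alpha, p_inv=p_inv)
        if optimize_freqs:
            f = np.exp(x[7:10])
            f = np.concatenate([f, [1.0]])
            f /= f.sum()
            kw["base_freqs"] = tuple(f)
        return replace(params, **kw)

    ex0 = np.asarray(params.exchangeabilities, float)
    x0 = list(np.log(np.clip(ex0[:5] / ex0[5], 1e-6, None)))
    x0.append(np.log(params.alpha))
    p0 = min(max(params.p_inv, 1e-3), 0.98)
    x0.append(np.log(p0 / (1 - p0)))
    if optimize_freqs:
        f = np.asarray(params.base_freqs, float)
        x0.extend(np.log(f[:3] / f[3]))
    x0 = np.asarray(x0)

    def objective(x: np.ndarray) -> float:
        try:
            p = unpack(x)
        except ValueError:
            return 1e12
        return -log_likelihood(data, tree, p)

    start = -objective(x0)
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxfev": maxiter * 3, "xatol": 5e-3, "fatol": 1e-2})
    if -res.fun >= start:
        return unpack(res.x), float(-res.fun)
    return replace(params), float(start)
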