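"""ML tree search: BioNJ start, NNI hill-climbing, bootstrap resampling.

The search strategy mirrors standard ML phylogenetics practice: a
BioNJ tree on pairwise distances seeds the search; branch lengths and
model parameters are optimized on it; then nearest-neighbor
interchanges are applied greedily, accepting only strict likelihood
improvements, until no rearrangement helps.  Bootstrap support comes
from column-wise resampling with full search reruns, and the replicate
trees are summarized by majority-rule consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .bionj import bionj
from .distance import distance_matrix
from .likelihood import (
    PruningEngine,
    SiteData,
    empirical_base_freqs,
    log_likelihood,
    optimize_branch_lengths,
    optimize_model,
)
from .model import GTRModel, GTRParams
from .tree import Tree, majority_consensus, nni_neighbors

__all__ = ["MLResult", "nni_search", "ml_tree", "bootstrap", "bootstrap_support"]


@dataclass
class MLResult:
    tree: Tree
    params: GTRParams
    log_likelihood: float


def nni_search(
    start: Tree,
    data,
    params: GTRParams,
    tol: float = 1e-4,
    max_rounds: int = 50,
    branch_sweeps: int = 2,
) -> tuple[Tree, float]:
    """Greedy NNI hill-climbing from a starting tree.

    Each candidate rearrangement is scored after re-optimizing only the
    rearranged edge (a tight, cheap bound); the best improving
    candidate is then fully re-optimized and accepted.  Terminates when
    no interchange improves the likelihood; the final lnL is >= the
    starting lnL.
    """
    from .likelihood import _as_sitedata

    data = _as_sitedata(data)
    current, cur_lnl = optimize_branch_lengths(start, data, params, max_sweeps=branch_sweeps)
    for _ in range(max_rounds):
        best_nb, best_lnl = None, cur_lnl
        for nb, focal in nni_neighbors(current, with_focal=True):
            engine = PruningEngine(data, nb, params)
            engine.compute_down()
            engine.compute_up()
            lnl = engine.optimize_edge(focal)
            if lnl > best_lnl + tol:
                best_nb, best_lnl = nb, lnl
        if best_nb is None:
            break
        current, cur_lnl = optimize_branch_lengths(
            best_nb, data, params, max_sweeps=branch_sweeps
        )
    return current, cur_lnl


def default_params(data: SiteData) -> GTRParams:
    """Empirical-frequency GTR+I+Γ defaults used to seed optimization."""
    return GTRParams(
        base_freqs=empirical_base_freqs(data),
        exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
        p_inv=0.1,
        alpha=0.5,
        n_categories=4,
    )


def ml_tree(
    taxa: list[str],
    rows: list[str],
    params: Optional[GTRParams] = None,
    optimize_params: bool = True,
    model_rounds: int = 2,
) -> MLResult:
    """Full ML pipeline: distances -> BioNJ -> branch/model opt -> NNI."""
    data = SiteData(taxa, rows)
    if params is None:
        params = default_params(data)
    D = distance_matrix(taxa, rows)
    tree = bionj(taxa, D)
    tree.unroot()
    tree, lnl = optimize_branch_lengths(tree, data, params, max_sweeps=3)
    if optimize_params:
        for _ in range(model_rounds):
            params, _ = optimize_model(tree, data, params)
            tree, lnl = optimize_branch_lengths(tree, data, params, max_sweeps=2)
    tree, lnl = nni_search(tree, data, params)
    return MLResult(tree=tree, params=params, log_likelihood=lnl)


def _resample_columns(rows: list[str], rng: np.random.Generator, block: int = 1) -> list[str]:
    L = len(rows[0])
    if block == 1:
        idx = rng.integers(0, L, size=L)
    else:
        n_blocks = L // block
        starts = rng.integers(0, n_blocks, size=n_blocks) * block
        idx = np.concatenate([np.arange(s, s + block) for s in starts])
    arr = np.array([list(r) for r in rows])
    return ["".join(r) for r in arr[:, idx]]


def bootstrap(
    taxa: list[str],
    rows: list[str],
    n_replicates: int,
    seed: int,
    params: Optional[GTRParams] = None,
    codon_block: bool = False,
) -> list[Tree]:
    """Nonparametric bootstrap: resample columns, rerun the full search.

    Resampling is column-wise by default (codon-blind); ``codon_block``
    resamples aligned codon triplets instead.  Model parameters are
    estimated once on the original data and held fixed across
    replicates; the per-replicate search (BioNJ + branch optimization
    + NNI) is rerun from scratch.  Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if params is None:
        base = ml_tree(taxa, rows, optimize_params=True)
        params = base.params
    trees = []
    for _ in range(n_replicates):
        sampled = _resample_columns(rows, rng, block=3 if codon_block else 1)
        data = SiteData(taxa, sampled)
        D = distance_matrix(taxa, sampled)
        t0 = bionj(taxa, D)
        t0.unroot()
        t, _ = nni_search(t0, data, params, branch_sweeps=1)
        trees.append(t)
    return trees


def bootstrap_support(ml: Tree, replicates: list[Tree]) -> Tree:
    """Attach bootstrap percentages to the ML tree's internal edges."""
    counts: dict[frozenset, int] = {}
    for t in replicates:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    out = ml.copy()
    all_taxa = frozenset(out.taxa)
    ref = min(all_taxa)
    leafsets = {}
    for node in out.postorder():
        if node.is_leaf:
            leafsets[id(node)] = frozenset([node.name])
        else:
            leafsets[id(node)] = frozenset().union(*(leafsets[id(c)] for c in node.children))
            if node is out.root:
                continue
            s = leafsets[id(node)]
            side = all_taxa - s if ref in s else s
            if 1 < len(side) < len(all_taxa) - 1:
                node.support = 100.0 * counts.get(side, 0) / max(len(replicates), 1)
    return out
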