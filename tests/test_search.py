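"""NNI search, bootstrap resampling, consensus and RF distances."""

import numpy as np
import pytest

from ensimito.phylo import (
    GTRParams,
    Tree,
    bootstrap,
    bootstrap_support,
    enumerate_topologies,
    log_likelihood,
    majority_consensus,
    ml_tree,
    nni_search,
    optimize_branch_lengths,
    rf_distance,
)
from ensimito.phylo.likelihood import SiteData
from ensimito.phylo.tree import nni_neighbors
from ensimito.synthetic import simulate_alignment

PARAMS = GTRParams(
    base_freqs=(0.35, 0.15, 0.12, 0.38),
    exchangeabilities=(1.5, 6.0, 1.2, 1.0, 8.0, 1.0),
    p_inv=0.1,
    alpha=0.8,
)


class TestNniNeighbors:
    def test_count_is_two_per_internal_edge(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert len(nni_neighbors(t)) == 2 * len(t.internal_edges())

    def test_neighbors_differ_from_start(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        for nb in nni_neighbors(t):
            assert rf_distance(nb, t) > 0


class TestNniSearch:
    def test_start_at_optimum_unchanged(self):
        truth = Tree.from_newick("((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15,E:0.2);")
        rows, _ = simulate_alignment(truth, PARAMS, 4000, seed=8)
        best, lnl = nni_search(truth, rows, PARAMS)
        assert rf_distance(best, truth) == 0

    def test_final_lnl_at_least_start(self):
        truth = Tree.from_newick("((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15,E:0.2);")
        wrong = Tree.from_newick("((A:0.2,C:0.2):0.15,(B:0.2,D:0.2):0.15,E:0.2);")
        rows, _ = simulate_alignment(truth, PARAMS, 4000, seed=8)
        start_lnl = log_likelihood(rows, wrong, PARAMS)
        best, lnl = nni_search(wrong, rows, PARAMS)
        assert lnl >= start_lnl

    def test_all_fifteen_starts_reach_generating_topology(self):
        """5-taxon, long internal branches: the ML optimum is the truth
        (verified by exhaustive topology enumeration), and NNI reaches
        it from every one of the 15 unrooted starting topologies."""
        truth = Tree.from_newick("((A:0.3,B:0.3):0.25,(C:0.3,D:0.3):0.25,E:0.3);")
        rows, _ = simulate_alignment(truth, PARAMS, 5000, seed=13)
        data = SiteData(sorted(rows), [rows[t] for t in sorted(rows)])
        # exhaustive ML over all topologies
        scored = []
        for topo in enumerate_topologies(list("ABCDE")):
            for n in topo.postorder():
                if n is not topo.root:
                    n.length = 0.1
            opt, lnl = optimize_branch_lengths(topo, data, PARAMS, max_sweeps=10)
            scored.append((lnl, opt))
        best_lnl, best_tree = max(scored, key=lambda x: x[0])
        assert rf_distance(best_tree, truth) == 0
        for topo in enumerate_topologies(list("ABCDE")):
            for n in topo.postorder():
                if n is not topo.root:
                    n.length = 0.1
            found, lnl = nni_search(topo, data, PARAMS)
            assert rf_distance(found, truth) == 0
            _, lnl_conv = optimize_branch_lengths(found, data, PARAMS, max_sweeps=10)
            assert lnl_conv == pytest.approx(best_lnl, abs=0.5)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        truth = Tree.from_newick("((A:0.2,B:0.2):0.2,C:0.2,D:0.2);")
        rows, _ = simulate_alignment(truth, PARAMS, 1000, seed=21)
        taxa = sorted(rows)
        mat = [rows[t] for t in taxa]
        reps1 = bootstrap(taxa, mat, 5, seed=99, params=PARAMS)
        reps2 = bootstrap(taxa, mat, 5, seed=99, params=PARAMS)
        assert [t.to_newick() for t in reps1] == [t.to_newick() for t in reps2]
        reps3 = bootstrap(taxa, mat, 5, seed=100, params=PARAMS)
        assert [t.to_newick() for t in reps1] != [t.to_newick() for t in reps3]

    def test_resampled_width_preserved(self):
        from ensimito.phylo.search import _resample_columns

        rng = np.random.default_rng(0)
        rows = ["ACGTACGTA", "TGCATGCAT"]
        out = _resample_columns(rows, rng)
        assert all(len(r) == 9 for r in out)
        out3 = _resample_columns(rows, rng, block=3)
        assert all(len(r) == 9 for r in out3)

    def test_strong_signal_support(self):
        """4 taxa, 10k sites: the true split gets >= 95% support."""
        truth = Tree.from_newick("((A:0.2,B:0.2):0.15,C:0.2,D:0.2);")
        rows, _ = simulate_alignment(truth, PARAMS, 10_000, seed=31)
        taxa = sorted(rows)
        mat = [rows[t] for t in taxa]
        reps = bootstrap(taxa, mat, 100, seed=7, params=PARAMS)
        ml = ml_tree(taxa, mat, params=PARAMS, optimize_params=False)
        with_support = bootstrap_support(ml.tree, reps)
        supports = [n.support for n in with_support.internal_edges()
                    if n.support is not None]
        assert len(supports) == 1
        assert supports[0] >= 95.0

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap(["A", "B"], ["AC", "AG"], 0, seed=1)


class TestConsensus:
    def test_identical_trees_full_support(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        cons = majority_consensus([t.copy() for _ in range(4)])
        assert cons.splits() == t.splits()
        supports = [n.support for n in cons.postorder()
                    if n.support is not None]
        assert all(s == 100.0 for s in supports)

    def test_two_of_three_majority(self):
        t1 = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = Tree.from_newick("((A:1,B:1):1,(C:1,E:1):1,D:1);")
        cons = majority_consensus([t1, t1.copy(), t2])
        # the A|B split appears in all three trees, C|D in two of three,
        # C|E in only one: the consensus topology equals t1
        assert cons.splits() == t1.splits()
        supports = sorted(n.support for n in cons.postorder()
                          if n.support is not None)
        assert supports[0] == pytest.approx(200 / 3)
        assert supports[-1] == pytest.approx(100.0)

    def test_matches_dendropy_consensus(self):
        """Independent cross-check of the retained split set."""
        import dendropy

        rng = np.random.default_rng(17)
        from ensimito.synthetic import random_topology

        trees = [random_topology(list("ABCDEF"), seed=int(rng.integers(2**31)))
                 for _ in range(7)]
        mine = majority_consensus(trees, threshold=0.5)
        tns = dendropy.TaxonNamespace()
        dtrees = dendropy.TreeList(
            [dendropy.Tree.get(data=t.to_newick(), schema="newick",
                               taxon_namespace=tns) for t in trees])
        dcons = dtrees.consensus(min_freq=0.5)
        dcons.encode_bipartitions()
        theirs = Tree.from_newick(dcons.as_string(schema="newick"))
        assert mine.splits() == theirs.splits()

    def test_taxon_mismatch_rejected(self):
        t1 = Tree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = Tree.from_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError):
            majority_consensus([t1, t2])


class TestRfDistance:
    def test_self_distance_zero(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert rf_distance(t, t.copy()) == 0

    def test_matches_dendropy(self):
        import dendropy

        from ensimito.synthetic import random_topology

        rng = np.random.default_rng(23)
        for _ in range(10):
            t1 = random_topology(list("ABCDEFG"), seed=int(rng.integers(2**31)))
            t2 = random_topology(list("ABCDEFG"), seed=int(rng.integers(2**31)))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            expect = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expect


def _leaves(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out
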