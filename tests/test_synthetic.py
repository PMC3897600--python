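"""Synthetic generators: planted genomes, tRNAs, simulated alignments."""

import numpy as np
import pytest

from ensimito.genome import GeneClass, adjacency_ledger
from ensimito.io import load_reference_annotation
from ensimito.phylo import GTRParams, Tree
from ensimito.phylo.model import GTRModel
from ensimito.synthetic import (
    RecipeError,
    TrnaTemplate,
    default_recipe,
    ensifera_demo_tree,
    generate_mitogenome,
    generate_trna,
    random_topology,
    simulate_alignment,
    template_for_length,
)


class TestGenomeGenerator:
    def test_default_layout_mirrors_reference(self, bundle):
        ref = load_reference_annotation()
        assert [g.name for g in bundle.table] == [g.name for g in ref]
        assert [g.strand for g in bundle.table] == [g.strand for g in ref]
        L = bundle.genome.length
        assert L == ref.genome_length == 16144
        assert [g.length(L) for g in bundle.table] == [
            g.length(L) for g in ref
        ]

    def test_ledger_mirrors_reference(self, bundle):
        ref = load_reference_annotation()
        L = ref.genome_length
        mine = [(r.upstream, r.downstream, r.spacer)
                for r in adjacency_ledger(bundle.table, L)]
        theirs = [(r.upstream, r.downstream, r.spacer)
                  for r in adjacency_ledger(ref, L)]
        assert mine == theirs
        spacers = {(u, d): s for u, d, s in mine}
        assert spacers[("atp8", "atp6")] == -7

    def test_codon_assignments_planted(self, bundle):
        pcgs = {g.name: (g.init_codon, g.term_codon)
                for g in bundle.table.of_class(GeneClass.PCG)}
        assert pcgs["atp8"] == ("GTG", "TAG")
        assert pcgs["cox1"] == ("ATC", "T")
        single_t = [n for n, (_, t) in pcgs.items() if t == "T"]
        assert sorted(single_t) == ["cox1", "cox2", "cytb", "nad2", "nad4", "nad5"]

    def test_deterministic_per_seed(self):
        g1 = generate_mitogenome(default_recipe(seed=42))
        g2 = generate_mitogenome(default_recipe(seed=42))
        assert g1.genome.seq == g2.genome.seq
        g3 = generate_mitogenome(default_recipe(seed=43))
        assert g3.genome.seq != g1.genome.seq

    def test_planted_sequences_consistent(self, bundle):
        from ensimito.genome import region_sequence

        for g in bundle.table.of_class(GeneClass.PCG):
            cds = region_sequence(bundle.genome, g)
            assert cds.startswith(g.init_codon)
            assert cds.endswith(g.term_codon)

    def test_unsatisfiable_recipe_raises(self):
        recipe = default_recipe(seed=0)
        bad = {k: v for k, v in recipe.pcg_codons.items()}
        bad["nad2"] = ("ATA", "TAA")  # full stop inconsistent with length 1027
        recipe.pcg_codons = bad
        with pytest.raises(RecipeError):
            generate_mitogenome(recipe)


class TestTrnaGenerator:
    def test_no_defects_all_wc(self):
        from ensimito.trna import pairing_census

        seq, truth = generate_trna(template_for_length(66), seed=0)
        census = pairing_census(truth, seq)["total"]
        assert census["wobble"] == 0 and census["mismatch"] == 0

    def test_planted_wobbles_counted(self):
        from ensimito.trna import pairing_census

        seq, truth = generate_trna(
            template_for_length(68),
            defects=[("acceptor", 1, "wobble"), ("TpsiC", 2, "wobble")],
            seed=1,
        )
        assert pairing_census(truth, seq)["total"]["wobble"] == 2

    def test_defect_outside_stem_rejected(self):
        with pytest.raises(RecipeError):
            generate_trna(template_for_length(66), defects=[("DHU", 9, "wobble")],
                          seed=0)

    def test_fixed_positions_respected(self):
        seq, _ = generate_trna(template_for_length(66),
                               fixed_positions={0: "G", 1: "A"}, seed=2)
        assert seq[:2] == "GA"


class TestAlignmentSimulator:
    def test_zero_branches_identical_rows(self):
        t = Tree.from_newick("((A:0.0,B:0.0):0.0,C:0.0,D:0.0);")
        rows, _ = simulate_alignment(t, GTRParams(), 100, seed=1)
        assert len(set(rows.values())) == 1

    def test_deterministic_per_seed(self):
        t = ensifera_demo_tree()
        r1, c1 = simulate_alignment(t, GTRParams(), 500, seed=5)
        r2, c2 = simulate_alignment(t, GTRParams(), 500, seed=5)
        assert r1 == r2 and (c1 == c2).all()

    def test_base_frequencies_converge_to_pi(self):
        params = GTRParams(base_freqs=(0.35, 0.17, 0.11, 0.37),
                           exchangeabilities=(1.5, 6, 1.2, 1, 8, 1),
                           alpha=0.5, p_inv=0.2)
        t = ensifera_demo_tree()
        rows, _ = simulate_alignment(t, params, 100_000, seed=6)
        allbases = "".join(rows.values())
        freqs = np.array([allbases.count(b) for b in "ACGT"], float)
        freqs /= freqs.sum()
        assert np.allclose(freqs, params.base_freqs, atol=0.01)

    def test_invariant_sites_category(self):
        """Category 0 sites never change state along the tree."""
        params = GTRParams(alpha=0.5, p_inv=0.3)
        t = ensifera_demo_tree()
        rows, cats = simulate_alignment(t, params, 5000, seed=7)
        mat = np.array([list(r) for r in rows.values()])
        invariant_cols = (mat == mat[0]).all(axis=0)
        assert invariant_cols[cats == 0].all()

    def test_large_alpha_rates_concentrate(self):
        from ensimito.phylo.model import discrete_gamma_rates

        rates = discrete_gamma_rates(500.0, 4)
        assert rates.var() < 0.05


class TestTrees:
    def test_random_topology_shape(self):
        t = random_topology([f"t{i}" for i in range(17)], seed=1)
        assert len(t.taxa) == 17
        assert t.n_edges() == 2 * 17 - 3

    def test_demo_tree_topology(self):
        t = ensifera_demo_tree()
        splits = t.splits()
        assert frozenset({"Hagloidea", "Rhaphidophoroidea"}) in splits
        assert frozenset({"Tettigonioidea", "Hagloidea", "Rhaphidophoroidea"}) in splits
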