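"""PCG boundary rules: starts, full vs incomplete stops, refinement."""

import pytest

from ensimito.annotation import (
    BoundaryPolicy,
    NoStartError,
    UnresolvableBoundaryError,
    assign_initiation,
    assign_termination,
    refine_boundaries,
    scan_orfs,
    translate,
)
from ensimito.genome import CircularGenome, GeneClass, GeneRecord, AnnotationTable
from ensimito.synthetic import default_recipe, generate_mitogenome, perturb_to_draft


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,expect",
        [
            ("ATGTTTTAA", "MF*"),
            ("TGA", "W"),        # Trp under the invertebrate mito code
            ("AGAAGG", "SS"),    # AGA/AGG are Ser, not stops, in code 5
            ("ATTGTG", "IV"),
        ],
    )
    def test_invertebrate_mito_code(self, cds, expect):
        assert translate(cds, code=5) == expect

    def test_incomplete_trailing_bases_dropped(self):
        assert translate("ATGTT", incomplete_stop_policy=True) == "M"
        with pytest.raises(ValueError):
            translate("ATGTT", incomplete_stop_policy=False)

    def test_too_short(self):
        with pytest.raises(ValueError):
            translate("AT")


def _toy_genome(seq):
    return CircularGenome(seq=seq, id="toy")


def _trna(name, start, end, strand="J"):
    return GeneRecord(name, GeneClass.TRNA, strand, start, end, anticodon="CAT")


class TestScanOrfs:
    def test_planted_gene_found(self):
        # gene at 11..25: ATG AAA CCC GGG TAA inside padding without stops
        seq = "C" * 10 + "ATGAAACCCGGGTAA" + "C" * 10
        cands = scan_orfs(_toy_genome(seq), "J", min_codons=4)
        hits = [c for c in cands if c.start == 11 and c.end == 25]
        assert len(hits) == 1
        assert hits[0].init_codon == "ATG" and hits[0].term_codon == "TAA"

    def test_no_allowed_start_no_candidates(self):
        seq = "CCCCCCCCCCCCCCCTAACCC"
        assert scan_orfs(_toy_genome(seq), "J", min_codons=2) == []

    def test_wrap_around_orf_found_once(self):
        # ORF spanning the origin: starts near the end, stop after wrap
        core = "ATGAAACCCGGGTAA"
        seq = core[9:] + "CCCTAACCCCCCTAACCC" + core[:9]
        cands = scan_orfs(_toy_genome(seq), "J", min_codons=4)
        wrapped = [c for c in cands if c.start > c.end]
        assert len(wrapped) == 1
        assert wrapped[0].init_codon == "ATG"


class TestAssignInitiation:
    def test_minimizes_absolute_spacer(self):
        up = _trna("t1", 1, 60)
        # candidates at 64 (gap 3) and 70 (gap 9)
        p, codon = assign_initiation([(70, "ATG"), (64, "ATT")], up, "J", 200)
        assert (p, codon) == (64, "ATT")

    def test_tie_prefers_gap_then_canonical_start(self):
        up = _trna("t1", 1, 60)
        # spacers +2 (p=63) and -2 (p=59): equal magnitude, gap preferred
        p, _ = assign_initiation([(59, "ATG"), (63, "ATA")], up, "J", 200)
        assert p == 63
        # equal spacer, ATG outranks ATA
        p, codon = assign_initiation([(63, "ATA"), (63, "ATG")], up, "J", 200)
        assert codon == "ATG"

    def test_single_candidate_returned(self):
        up = _trna("t1", 1, 60)
        assert assign_initiation([(64, "GTG")], up, "J", 200) == (64, "GTG")

    def test_overlap_forbidden_when_policy_set(self):
        up = _trna("t1", 1, 60)
        policy = BoundaryPolicy(forbid_start_overlap=True)
        with pytest.raises(NoStartError):
            assign_initiation([(55, "ATG")], up, "J", 200, policy)


class TestAssignTermination:
    def test_full_stop_with_free_space(self):
        #          start=11      TAA at 26..28, tRNA far downstream
        seq = "C" * 10 + "ATGAAACCCGGGCCCTAA" + "C" * 30
        term, end = assign_termination(_toy_genome(seq), "J", 11, _trna("t", 40, 55))
        assert (term, end) == ("TAA", 28)

    def test_truncation_to_single_T(self):
        # gene body then T, with the tRNA abutting right after: the
        # in-frame stop falls inside the tRNA, so truncate to ...T
        body = "ATG" + "AAA" * 4
        seq = "C" * 10 + body + "T" + "AATAAGGG" + "C" * 20
        trna_start = 10 + len(body) + 2  # 1-based first position of tRNA
        genome = _toy_genome(seq)
        term, end = assign_termination(genome, "J", 11, _trna("t", trna_start, trna_start + 15))
        assert (term, end) == ("T", trna_start - 1)

    def test_full_stop_kept_over_downstream_pcg(self):
        seq = "C" * 10 + "ATGAAACCCGGGCCCTAA" + "C" * 30
        pcg = GeneRecord("next", GeneClass.PCG, "J", 27, 50,
                         init_codon="ATG", term_codon="TAA")
        term, end = assign_termination(_toy_genome(seq), "J", 11, pcg)
        assert (term, end) == ("TAA", 28)  # overlap with a PCG is allowed

    def test_unresolvable_raises(self):
        # stop inside tRNA but trailing base before the tRNA is not T
        body = "ATG" + "AAA" * 4
        seq = "C" * 10 + body + "G" + "AATAAGGG" + "C" * 20
        trna_start = 10 + len(body) + 2
        with pytest.raises(UnresolvableBoundaryError):
            assign_termination(_toy_genome(seq), "J", 11,
                               _trna("t", trna_start, trna_start + 15))


class TestRefineBoundaries:
    def test_roundtrip_recovers_planted_truth(self):
        for seed in (0, 1, 2, 3, 4):
            bundle = generate_mitogenome(default_recipe(seed=seed))
            draft = perturb_to_draft(bundle, seed=seed + 100)
            refined = refine_boundaries(draft, bundle.genome)
            for g, r in zip(bundle.table.genes, refined.genes):
                assert (g.start, g.end, g.init_codon, g.term_codon) == (
                    r.start, r.end, r.init_codon, r.term_codon), g.name

    def test_idempotent(self, bundle):
        once = refine_boundaries(bundle.table, bundle.genome)
        twice = refine_boundaries(once, bundle.genome)
        for a, b in zip(once.genes, twice.genes):
            assert (a.start, a.end, a.init_codon, a.term_codon) == (
                b.start, b.end, b.init_codon, b.term_codon)

    def test_stop_codon_legality(self, bundle):
        """No incomplete-stop gene's hypothetical full stop stays over a tRNA;
        PCG-PCG overlaps keep full stops."""
        refined = refine_boundaries(bundle.table, bundle.genome)
        L = bundle.genome.length
        genes = refined.genes
        for i, g in enumerate(genes):
            if g.klass is not GeneClass.PCG:
                continue
            # frame consistency: gene length mod 3 matches stop length mod 3
            assert g.length(L) % 3 == len(g.term_codon) % 3
            nxt = genes[(i + 1) % len(genes)] if g.strand == "J" else genes[(i - 1) % len(genes)]
            if g.term_codon in ("TAA", "TAG"):
                continue
            # truncated stops abut the downstream tRNA exactly
            assert nxt.klass is GeneClass.TRNA
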