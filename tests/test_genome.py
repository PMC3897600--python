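"""Circular coordinate arithmetic, adjacency ledger, and table IO."""

import pytest
from hypothesis import given, settings, strategies as st

from ensimito.genome import (
    AnnotationTable,
    CircularGenome,
    CoordinateError,
    GeneClass,
    GeneRecord,
    adjacency_ledger,
    circular_spacer,
    length_on_circle,
    region_sequence,
    reverse_complement,
    summarize_annotation,
)
from ensimito.io import (
    FeatureTableError,
    feature_table_to_string,
    read_feature_table,
    read_genbank_minimal,
)


class TestLengthOnCircle:
    @pytest.mark.parametrize(
        "start,end,L,expect",
        [
            (12651, 13990, 16144, 1340),  # rrnL span
            (5, 5, 16144, 1),
            (16143, 4, 16144, 6),  # wraps through the origin
            (1, 16144, 16144, 16144),
        ],
    )
    def test_examples(self, start, end, L, expect):
        assert length_on_circle(start, end, L) == expect

    def test_wrap_matches_enumeration(self):
        L = 20
        for start in (18, 19, 20):
            for end in (1, 2, 3):
                positions = []
                p = start
                while True:
                    positions.append(p)
                    if p == end:
                        break
                    p = p % L + 1
                assert length_on_circle(start, end, L) == len(positions)

    def test_out_of_range_raises(self):
        with pytest.raises(CoordinateError):
            length_on_circle(0, 5, 10)
        with pytest.raises(CoordinateError):
            length_on_circle(1, 11, 10)

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(0, 499))
    @settings(max_examples=100, deadline=None)
    def test_rotation_invariance(self, start, end, shift):
        """Renumbering coordinates from any origin preserves lengths."""
        L = 500
        rot = lambda p: (p - 1 + shift) % L + 1
        assert length_on_circle(start, end, L) == length_on_circle(rot(start), rot(end), L)


class TestAdjacencyLedger:
    def test_published_spacers(self, reference_table):
        L = reference_table.genome_length
        ledger = {(r.upstream, r.downstream): r.spacer
                  for r in adjacency_ledger(reference_table, L)}
        assert ledger[("trnR", "trnN")] == 25  # largest intergenic region
        assert ledger[("atp8", "atp6")] == -7  # bicistronic overlap
        assert ledger[("cox1", "trnL_UUR")] == 0  # abutting
        assert ledger[("control_region", "trnI")] == 0  # closes the circle

    def test_closure_invariant(self, reference_table):
        L = reference_table.genome_length
        ledger = adjacency_ledger(reference_table, L)
        total = sum(g.length(L) for g in reference_table) + sum(r.spacer for r in ledger)
        assert total == L

    def test_closure_on_synthetic(self, bundle):
        L = bundle.genome.length
        ledger = adjacency_ledger(bundle.table, L)
        assert sum(g.length(L) for g in bundle.table) + sum(r.spacer for r in ledger) == L

    def test_empty_table_raises(self):
        with pytest.raises(Exception):
            adjacency_ledger(AnnotationTable(genes=[]), 100)


class TestRegionSequence:
    def test_majority_strand_verbatim(self):
        g = CircularGenome(seq="ACGTACGTAA", id="x")
        rec = GeneRecord("a", GeneClass.RRNA, "J", 1, 4)
        assert region_sequence(g, rec) == "ACGT"

    def test_minority_strand_reverse_complement(self):
        g = CircularGenome(seq="AAGCTTTTTT", id="x")
        rec = GeneRecord("a", GeneClass.RRNA, "N", 1, 4)
        assert region_sequence(g, rec) == "GCTT"

    def test_wrap_matches_doubled_sequence(self):
        seq = "ACGTACGTAA"
        g = CircularGenome(seq=seq, id="x")
        rec = GeneRecord("a", GeneClass.RRNA, "J", 9, 2)
        assert region_sequence(g, rec) == (seq + seq)[8:12]

    def test_strand_symmetry(self, bundle):
        for gene in list(bundle.table)[:6]:
            fwd = region_sequence(bundle.genome, gene)
            flip = GeneRecord(gene.name, gene.klass,
                              "N" if gene.strand == "J" else "J",
                              gene.start, gene.end,
                              anticodon=gene.anticodon,
                              init_codon=gene.init_codon,
                              term_codon=gene.term_codon)
            assert region_sequence(bundle.genome, flip) == reverse_complement(fwd)


class TestSummary:
    def test_published_statistics(self, reference_table):
        rep = summarize_annotation(reference_table)
        assert rep.counts == {"tRNA": 22, "PCG": 13, "rRNA": 2, "control": 1}
        assert (rep.min_trna_length, rep.max_trna_length) == (63, 70)
        assert rep.max_positive_spacer == 25
        assert rep.genome_length == 16144
        assert rep.gene_lengths["rrnL"] == 1340
        assert rep.gene_lengths["rrnS"] == 783
        assert rep.gene_lengths["control_region"] == 1301

    def test_single_gene_table(self):
        t = AnnotationTable(
            genes=[GeneRecord("solo", GeneClass.RRNA, "J", 11, 40)], genome_length=100
        )
        rep = summarize_annotation(t)
        assert rep.max_positive_spacer == 100 - 30


class TestFeatureTableIO:
    def test_round_trip_identity(self, reference_table):
        text = feature_table_to_string(reference_table)
        again = feature_table_to_string(read_feature_table(text))
        assert text == again

    def test_round_trip_on_synthetic(self, bundle):
        text = feature_table_to_string(bundle.table, bundle.genome.length)
        assert feature_table_to_string(read_feature_table(text)) == text

    def test_empty_input_raises(self):
        with pytest.raises(FeatureTableError):
            read_feature_table("")

    def test_malformed_row_names_line(self):
        text = "#genome_length=100\ngene\tklass\tstrand\tstart\tend\tsize\tanticodon\tinit_codon\tterm_codon\tspacer\nbad row here\n"
        with pytest.raises(FeatureTableError, match="line 3"):
            read_feature_table(text)

    def test_duplicate_names_rejected(self):
        rec = GeneRecord("x", GeneClass.RRNA, "J", 1, 5)
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationTable(genes=[rec, GeneRecord("x", GeneClass.RRNA, "J", 6, 9)])


class TestGenBankReader:
    def test_complement_feature_and_codons(self, tmp_path):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio import SeqIO

        # 60 bp toy genome with one forward CDS (ATG..TAA) and one
        # reverse-strand tRNA; reverse CDS coordinates mimic complement()
        cds = "ATGAAACCCGGGTTTTAA"
        seq = cds + "ACGT" * 8 + "ACGTACGTAC"
        record = SeqRecord(Seq(seq), id="toy", annotations={"molecule_type": "DNA"})
        record.features = [
            SeqFeature(SimpleLocation(0, len(cds), strand=1), type="CDS",
                       qualifiers={"gene": ["nad0"]}),
            SeqFeature(SimpleLocation(30, 50, strand=-1), type="tRNA",
                       qualifiers={"gene": ["trnX"], "anticodon": ["(pos:40..42,aa:Xle,seq:cat)"]}),
        ]
        path = tmp_path / "toy.gb"
        SeqIO.write(record, str(path), "genbank")
        genome, table = read_genbank_minimal(path)
        assert genome.length == len(seq)
        nad0 = table.get("nad0")
        assert (nad0.start, nad0.end, nad0.strand) == (1, len(cds), "J")
        assert nad0.init_codon == "ATG" and nad0.term_codon == "TAA"
        trnx = table.get("trnX")
        assert (trnx.start, trnx.end, trnx.strand) == (31, 50, "N")
        assert trnx.anticodon == "CAT"


class TestGeneRecordInvariants:
    def test_anticodon_only_for_trna(self):
        with pytest.raises(ValueError):
            GeneRecord("x", GeneClass.PCG, "J", 1, 9, anticodon="CAT",
                       init_codon="ATG", term_codon="TAA")

    def test_codons_required_for_pcg(self):
        with pytest.raises(ValueError):
            GeneRecord("x", GeneClass.PCG, "J", 1, 9)

    def test_bad_term_codon(self):
        with pytest.raises(ValueError):
            GeneRecord("x", GeneClass.PCG, "J", 1, 9, init_codon="ATG",
                       term_codon="TGA")
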