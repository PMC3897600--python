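"""Core data model for circular mitochondrial genomes.

A metazoan mitogenome is a single circular DNA molecule (~16 kb in
insects) carrying 13 protein-coding genes, 22 tRNAs, 2 rRNAs and one
non-coding control region.  This module holds the coordinate arithmetic
on the circle, the typed annotation table, and the gene-adjacency
ledger (intergenic gaps / overlaps between consecutive features).

Conventions
-----------
* Coordinates are 1-based and inclusive at both ends, on the majority
  strand ("J"); a feature whose ``end`` is smaller than its ``start``
  wraps through the origin of the circle.
* Strand "J" is the strand as deposited (the sense strand of most
  genes); "N" is its complement.  A strand-N feature still records its
  majority-strand coordinate interval; its 5' end sits at ``end``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "GeneClass",
    "CircularGenome",
    "GeneRecord",
    "AnnotationTable",
    "AdjacencyRecord",
    "SummaryReport",
    "CoordinateError",
    "length_on_circle",
    "circular_spacer",
    "adjacency_ledger",
    "region_sequence",
    "reverse_complement",
    "summarize_annotation",
]

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")

VALID_BASES = set("ACGTN")
AMBIGUITY_BASES = set("RYSWKMBDHV")


class CoordinateError(ValueError):
    """A coordinate falls outside [1, genome_length]."""


class GeneClass(str, enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularGenome:
    """The majority-strand sequence of a circular genome, 5'->3'."""

    seq: str
    id: str = "genome"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.seq) - VALID_BASES - AMBIGUITY_BASES
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Majority-strand slice [start, end], wrapping through the origin."""
        L = self.length
        _check_coord(start, L)
        _check_coord(end, L)
        if end >= start:
            return self.seq[start - 1 : end]
        return self.seq[start - 1 :] + self.seq[:end]


@dataclass
class GeneRecord:
    """One feature row of a Table-1-style annotation.

    ``anticodon`` is present iff the feature is a tRNA; ``init_codon``
    and ``term_codon`` iff it is a PCG.  ``term_codon`` is one of
    TAA/TAG (full stops) or TA/T (incomplete stops completed to TAA by
    post-transcriptional polyadenylation).
    """

    name: str
    klass: GeneClass
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    init_codon: Optional[str] = None
    term_codon: Optional[str] = None

    def __post_init__(self) -> None:
        self.klass = GeneClass(self.klass)
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"{self.name}: coordinates must be >= 1")
        if (self.anticodon is not None) != (self.klass is GeneClass.TRNA):
            raise ValueError(f"{self.name}: anticodon present iff feature is a tRNA")
        is_pcg = self.klass is GeneClass.PCG
        if (self.init_codon is not None) != is_pcg or (self.term_codon is not None) != is_pcg:
            raise ValueError(f"{self.name}: init/term codons present iff feature is a PCG")
        if self.term_codon is not None and self.term_codon not in ("TAA", "TAG", "TA", "T"):
            raise ValueError(f"{self.name}: bad termination codon {self.term_codon!r}")

    def length(self, genome_length: int) -> int:
        return length_on_circle(self.start, self.end, genome_length)


def _check_coord(pos: int, genome_length: int) -> None:
    if not 1 <= pos <= genome_length:
        raise CoordinateError(f"coordinate {pos} outside [1, {genome_length}]")


def length_on_circle(start: int, end: int, genome_length: int) -> int:
    """Length in bp of the inclusive interval [start, end] on the circle.

    ``end < start`` denotes a feature wrapping through the origin.
    """
    _check_coord(start, genome_length)
    _check_coord(end, genome_length)
    if end >= start:
        return end - start + 1
    return genome_length - start + 1 + end


def circular_spacer(upstream_end: int, downstream_start: int, genome_length: int) -> int:
    """Signed gap between two consecutive features around the circle.

    Positive = intergenic nucleotides, negative = overlap, 0 = abutting.
    The result is mapped into (-L/2, L/2] so that short overlaps across
    the origin come out negative rather than as huge gaps.
    """
    _check_coord(upstream_end, genome_length)
    _check_coord(downstream_start, genome_length)
    s = (downstream_start - upstream_end - 1) % genome_length
    if s > genome_length // 2:
        s -= genome_length
    return s


@dataclass
class AdjacencyRecord:
    upstream: str
    downstream: str
    spacer: int


@dataclass
class AnnotationTable:
    """Ordered list of gene features around the circle.

    Order is by first coordinate around the circle starting at the
    declared origin gene (the deposited convention starts at trnI).
    """

    genes: list[GeneRecord]
    genome_length: Optional[int] = None

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names: {dup}")
        if self.genome_length is not None:
            for g in self.genes:
                _check_coord(g.start, self.genome_length)
                _check_coord(g.end, self.genome_length)

    @property
    def origin(self) -> str:
        return self.genes[0].name

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, name: str) -> GeneRecord:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def of_class(self, klass: GeneClass | str) -> list[GeneRecord]:
        klass = GeneClass(klass)
        return [g for g in self.genes if g.klass is klass]

    def neighbors(self, name: str) -> tuple[GeneRecord, GeneRecord]:
        """(previous, next) features in circular table order."""
        idx = [i for i, g in enumerate(self.genes) if g.name == name]
        if not idx:
            raise KeyError(name)
        i = idx[0]
        n = len(self.genes)
        return self.genes[(i - 1) % n], self.genes[(i + 1) % n]


def adjacency_ledger(table: AnnotationTable, genome_length: int) -> list[AdjacencyRecord]:
    """Signed spacers between consecutive features, closing the circle.

    Over a complete circular annotation the ledger satisfies
    ``sum(gene lengths) + sum(spacers) == genome_length`` exactly.
    """
    if len(table) == 0:
        raise ValueError("empty annotation table")
    genes = table.genes
    if len(genes) == 1:  # the whole rest of the circle is the spacer
        g = genes[0]
        return [AdjacencyRecord(g.name, g.name, genome_length - g.length(genome_length))]
    records = []
    for i, up in enumerate(genes):
        down = genes[(i + 1) % len(genes)]
        records.append(
            AdjacencyRecord(up.name, down.name, circular_spacer(up.end, down.start, genome_length))
        )
    return records


def region_sequence(genome: CircularGenome, gene: GeneRecord) -> str:
    """The 5'->3' sequence of a feature (reverse complement for strand N)."""
    raw = genome.slice(gene.start, gene.end)
    return raw if gene.strand == "J" else reverse_complement(raw)


@dataclass
class SummaryReport:
    """Sequence-optional summary statistics of an annotation table."""

    genome_length: int
    counts: dict[str, int]
    gene_lengths: dict[str, int]
    min_trna_length: Optional[int]
    max_trna_length: Optional[int]
    max_positive_spacer: int
    max_positive_spacer_pair: Optional[tuple[str, str]]
    overlaps: list[AdjacencyRecord]
    intergenic_total: int
    overlap_total: int

    def to_dict(self) -> dict:
        d = {
            "genome_length": self.genome_length,
            "counts": dict(self.counts),
            "gene_lengths": dict(self.gene_lengths),
            "min_trna_length": self.min_trna_length,
            "max_trna_length": self.max_trna_length,
            "max_positive_spacer": self.max_positive_spacer,
            "max_positive_spacer_pair": list(self.max_positive_spacer_pair)
            if self.max_positive_spacer_pair
            else None,
            "overlaps": [
                {"upstream": o.upstream, "downstream": o.downstream, "spacer": o.spacer}
                for o in self.overlaps
            ],
            "intergenic_total": self.intergenic_total,
            "overlap_total": self.overlap_total,
        }
        return d


def summarize_annotation(
    table: AnnotationTable, genome: Optional[CircularGenome] = None
) -> SummaryReport:
    """Length / adjacency statistics of an annotation table.

    Everything here is computable from coordinates alone; ``genome`` is
    accepted for API symmetry (composition statistics live in
    :mod:`ensimito.composition`).
    """
    L = genome.length if genome is not None else table.genome_length
    if L is None:
        raise ValueError("genome_length unknown: pass a genome or a table with genome_length")
    counts: dict[str, int] = {}
    gene_lengths: dict[str, int] = {}
    for g in table:
        counts[g.klass.value] = counts.get(g.klass.value, 0) + 1
        gene_lengths[g.name] = g.length(L)
    trna_lengths = [gene_lengths[g.name] for g in table.of_class(GeneClass.TRNA)]
    ledger = adjacency_ledger(table, L)
    positive = [r for r in ledger if r.spacer > 0]
    overlaps = [r for r in ledger if r.spacer < 0]
    if positive:
        best = max(positive, key=lambda r: r.spacer)
        max_pos, max_pair = best.spacer, (best.upstream, best.downstream)
    else:
        max_pos, max_pair = 0, None
    return SummaryReport(
        genome_length=L,
        counts=counts,
        gene_lengths=gene_lengths,
        min_trna_length=min(trna_lengths) if trna_lengths else None,
        max_trna_length=max(trna_lengths) if trna_lengths else None,
        max_positive_spacer=max_pos,
        max_positive_spacer_pair=max_pair,
        overlaps=overlaps,
        intergenic_total=sum(r.spacer for r in positive),
        overlap_total=sum(r.spacer for r in overlaps),
    )
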