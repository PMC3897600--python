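"""Nucleotide composition, codon census, RSCU and amino-acid usage.

Mitogenomes are strongly A+T biased; region-wise A+T percentages and
relative synonymous codon usage (RSCU) are the standard descriptive
statistics.  RSCU of a codon is its observed count divided by the mean
count of its synonymous family, so an unbiased family has RSCU 1.0 for
every member and each occupied family sums to its size.

Conventions: A+T percentages count only unambiguous A/C/G/T (ambiguity
codes are excluded from numerator and denominator); full termination
codons and incomplete trailing bases are excluded from the codon
census; start codons count as their encoded amino acid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

from Bio.Data import CodonTable

from .genome import AnnotationTable, CircularGenome, GeneClass, region_sequence

__all__ = [
    "CodonUsageTable",
    "RscuTable",
    "at_content",
    "codon_census",
    "rscu",
    "amino_acid_usage",
    "synonymous_families",
]

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]


def _round2(x: float) -> float:
    """Round half-up to 2 decimals, matching how such tables are printed."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def at_content(seq: str) -> float:
    """A+T percentage over unambiguous bases, to 2 decimals."""
    seq = seq.upper().replace("U", "T")
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous A/C/G/T bases to compute A+T content")
    return _round2(100.0 * (counts["A"] + counts["T"]) / total)


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    code: int = 5

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            codon = codon.upper().replace("U", "T")
            if codon not in full:
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] += n
        self.counts = full

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        if self.code != other.code:
            raise ValueError("cannot add usage tables under different genetic codes")
        return CodonUsageTable(
            {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}, code=self.code
        )


@dataclass
class RscuTable:
    values: dict[str, float]


def synonymous_families(code: int = 5) -> dict[str, list[str]]:
    """Map amino acid -> codon family (stop codons excluded)."""
    table = CodonTable.unambiguous_dna_by_id[code]
    fam: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = table.forward_table.get(codon)
        if aa is None:  # stop
            continue
        fam.setdefault(aa, []).append(codon)
    return fam


def codon_census(
    table: AnnotationTable, genome: CircularGenome, code: int = 5
) -> CodonUsageTable:
    """Count all complete codons of every PCG on its coding strand.

    Full termination codons (TAA/TAG) are excluded, as are the trailing
    1-2 bases of genes ending in incomplete stops.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for gene in table.of_class(GeneClass.PCG):
        if gene.term_codon is None:
            raise ValueError(f"{gene.name}: PCG lacks a termination codon")
        cds = region_sequence(genome, gene)
        tail = len(gene.term_codon) if gene.term_codon in ("TAA", "TAG") else len(cds) % 3
        body = cds[: len(cds) - tail]
        if len(body) % 3 != 0:
            raise ValueError(
                f"{gene.name}: length {len(cds)} inconsistent with term codon "
                f"{gene.term_codon}"
            )
        for i in range(0, len(body), 3):
            codon = body[i : i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
    return CodonUsageTable(counts, code=code)


def rscu(usage: CodonUsageTable) -> RscuTable:
    """RSCU_c = count_c / mean count over c's synonymous family."""
    values: dict[str, float] = {}
    for aa, family in synonymous_families(usage.code).items():
        total = sum(usage.counts[c] for c in family)
        for c in family:
            values[c] = 0.0 if total == 0 else usage.counts[c] * len(family) / total
    return RscuTable(values=values)


def amino_acid_usage(usage: CodonUsageTable) -> dict[str, float]:
    """Percentage of codons per encoded amino acid (stops excluded)."""
    if usage.total_codons == 0:
        raise ValueError("empty codon usage table")
    out: dict[str, float] = {}
    for aa, family in synonymous_families(usage.code).items():
        out[aa] = _round2(100.0 * sum(usage.counts[c] for c in family) / usage.total_codons)
    return out


def region_at_report(table: AnnotationTable, genome: CircularGenome) -> dict[str, float]:
    """Per-feature and whole-genome A+T percentages."""
    report = {"genome": at_content(genome.seq)}
    for gene in table:
        report[gene.name] = at_content(region_sequence(genome, gene))
    pcg_seq = "".join(region_sequence(genome, g) for g in table.of_class(GeneClass.PCG))
    if pcg_seq:
        report["PCGs_combined"] = at_content(pcg_seq)
    return report
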