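"""Concatenated multi-gene alignments with partition bookkeeping.

A phylogenomic supermatrix concatenates per-gene alignments (here 13
PCGs and 2 rRNAs) into one matrix, recording each gene's half-open
column interval.  Stop codons are excluded before concatenation:
when any ungapped row of a codon alignment ends in a full stop, the
trailing codon column-triplet is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from Bio.Data import CodonTable

__all__ = [
    "GeneAlignment",
    "Supermatrix",
    "strip_stop_codons",
    "concatenate",
    "read_gene_alignment",
    "write_fasta_alignment",
    "export_phylip",
    "export_nexus",
    "export_fasta",
    "read_phylip",
]


@dataclass
class GeneAlignment:
    """One gene's multiple alignment: equal-length gapped rows."""

    gene: str
    taxa: list[str]
    rows: list[str]
    kind: str = "codon"  # codon | rRNA

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.gene}: {len(self.taxa)} taxa but {len(self.rows)} rows")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError(f"{self.gene}: duplicate taxon names")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.gene}: rows differ in length")
        if self.kind not in ("codon", "rRNA"):
            raise ValueError(f"{self.gene}: kind must be codon or rRNA")
        if self.kind == "codon" and self.width % 3 != 0:
            raise ValueError(f"{self.gene}: codon alignment width {self.width} not divisible by 3")
        self.rows = [r.upper() for r in self.rows]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("supermatrix rows differ in length")
        total = self.width
        intervals = sorted(self.partitions.values())
        pos = 0
        for lo, hi in intervals:
            if lo != pos:
                raise ValueError("partitions do not tile the matrix")
            pos = hi
        if intervals and pos != total:
            raise ValueError("partitions do not cover the matrix")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def partition_alignment(self, gene: str) -> GeneAlignment:
        lo, hi = self.partitions[gene]
        return GeneAlignment(gene=gene, taxa=list(self.taxa),
                             rows=[r[lo:hi] for r in self.rows],
                             kind="codon" if (hi - lo) % 3 == 0 else "rRNA")


def strip_stop_codons(aln: GeneAlignment, code: int = 5) -> GeneAlignment:
    """Drop the trailing codon triplet when any ungapped row ends in a stop."""
    if aln.kind != "codon":
        raise TypeError(f"{aln.gene}: stop stripping applies to codon alignments")
    if aln.width < 3:
        return aln
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)
    last = [r[-3:] for r in aln.rows]
    if any(c in stops for c in last):
        return GeneAlignment(aln.gene, list(aln.taxa), [r[:-3] for r in aln.rows], aln.kind)
    return aln


def concatenate(alns: list[GeneAlignment], taxon_order: list[str] | None = None) -> Supermatrix:
    """Concatenate gene alignments; missing taxa become all-gap rows."""
    if not alns:
        raise ValueError("no alignments to concatenate")
    if taxon_order is None:
        seen: list[str] = []
        for a in alns:
            for t in a.taxa:
                if t not in seen:
                    seen.append(t)
        taxon_order = seen
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxon_order}
    pos = 0
    for a in alns:
        if a.gene in parts:
            raise ValueError(f"duplicate gene {a.gene}")
        missing = [t for t in taxon_order if t not in a.taxa]
        if missing:
            warnings.warn(f"{a.gene}: missing taxa filled with gaps: {missing}")
        for t in taxon_order:
            chunks[t].append(a.row(t) if t in a.taxa else "-" * a.width)
        parts[a.gene] = (pos, pos + a.width)
        pos += a.width
    return Supermatrix(
        taxa=list(taxon_order),
        rows=["".join(chunks[t]) for t in taxon_order],
        partitions=parts,
    )


# -- file formats ----------------------------------------------------

def read_gene_alignment(path: Union[str, Path], kind: str = "codon") -> GeneAlignment:
    """Aligned FASTA named <gene>.fasta -> GeneAlignment."""
    from Bio import SeqIO

    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return GeneAlignment(
        gene=path.stem,
        taxa=[r.id for r in records],
        rows=[str(r.seq).upper() for r in records],
        kind=kind,
    )


def write_fasta_alignment(aln: GeneAlignment, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def export_fasta(matrix: Supermatrix, path: Union[str, Path]) -> None:
    if not matrix.rows:
        raise ValueError("empty supermatrix")
    with open(path, "w") as fh:
        for t, r in zip(matrix.taxa, matrix.rows):
            fh.write(f">{t}\n{r}\n")


def export_phylip(matrix: Supermatrix, path: Union[str, Path]) -> None:
    """Relaxed PHYLIP (full names, space-separated)."""
    if not matrix.rows:
        raise ValueError("empty supermatrix")
    names = [t.replace(" ", "_") for t in matrix.taxa]
    if len(set(names)) != len(names):
        raise ValueError("taxon name collision in PHYLIP export")
    pad = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.width}\n")
        for n, r in zip(names, matrix.rows):
            fh.write(n.ljust(pad) + r + "\n")


def read_phylip(path: Union[str, Path]) -> Supermatrix:
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    n, width = map(int, lines[0].split())
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        rows.append(seq.strip())
    if any(len(r) != width for r in rows):
        raise ValueError("PHYLIP row width mismatch")
    return Supermatrix(taxa=taxa, rows=rows, partitions={"all": (0, width)})


def export_nexus(matrix: Supermatrix, path: Union[str, Path]) -> None:
    """NEXUS with a charset block recording the partitions."""
    if not matrix.rows:
        raise ValueError("empty supermatrix")
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.width};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t, r in zip(matrix.taxa, matrix.rows):
            fh.write(f"    {t.replace(' ', '_')}  {r}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, (lo, hi) in matrix.partitions.items():
            fh.write(f"  CHARSET {gene} = {lo + 1}-{hi};\n")
        fh.write("END;\n")
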