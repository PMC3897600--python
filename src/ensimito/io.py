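"""Readers and writers: Table-1-style feature tables, FASTA, GenBank.

The feature-table dialect is a TSV mirroring the columns of a printed
mitogenome annotation table: gene, klass, strand, start, end, size,
anticodon, init_codon, term_codon, spacer.  ``size`` and ``spacer`` are
derived from the coordinates and are recomputed on write (and checked
on read when the genome length is known), so a read/write round trip
is the identity up to trailing whitespace.  A ``#genome_length=N``
header line makes the table self-contained for coordinate statistics.

FASTA and GenBank parsing are delegated to Biopython; the GenBank
reader is minimal on purpose — it extracts the sequence plus
CDS/tRNA/rRNA/D-loop features into an :class:`AnnotationTable`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from .genome import (
    AnnotationTable,
    CircularGenome,
    GeneClass,
    GeneRecord,
    circular_spacer,
    length_on_circle,
    reverse_complement,
)

__all__ = [
    "load_reference_annotation",
    "read_feature_table",
    "write_feature_table",
    "feature_table_to_string",
    "read_fasta",
    "write_fasta",
    "read_genbank_minimal",
    "FeatureTableError",
]

_COLUMNS = [
    "gene",
    "klass",
    "strand",
    "start",
    "end",
    "size",
    "anticodon",
    "init_codon",
    "term_codon",
    "spacer",
]
_NA = "."


def load_reference_annotation() -> AnnotationTable:
    """The published T. diuturnus (GenBank JQ999995) annotation table.

    Transcribed feature coordinates of the deposited 16144 bp
    mitogenome; the sequence itself is not bundled, so only
    coordinate-derived statistics are available from this table.
    """
    from importlib.resources import files

    text = files("ensimito.data").joinpath("jq999995_feature_table.tsv").read_text()
    return read_feature_table(text)


class FeatureTableError(ValueError):
    """Malformed feature-table input (carries the offending line number)."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def read_feature_table(path_or_text: Union[str, Path]) -> AnnotationTable:
    """Parse a feature-table TSV file (or literal text) into a table."""
    p = Path(path_or_text) if path_or_text else Path("/nonexistent")
    try:
        exists = p.is_file()
    except OSError:
        exists = False
    text = p.read_text() if exists else str(path_or_text)
    genome_length: Optional[int] = None
    genes: list[GeneRecord] = []
    saw_header = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#genome_length="):
                try:
                    genome_length = int(line.split("=", 1)[1])
                except ValueError:
                    raise FeatureTableError("bad #genome_length header", lineno)
            continue
        fields = line.split("\t")
        if fields[0] == "gene":
            if fields != _COLUMNS:
                raise FeatureTableError(
                    f"unexpected header columns {fields!r}; expected {_COLUMNS!r}", lineno
                )
            saw_header = True
            continue
        if len(fields) != len(_COLUMNS):
            raise FeatureTableError(
                f"expected {len(_COLUMNS)} tab-separated fields, got {len(fields)}", lineno
            )
        row = dict(zip(_COLUMNS, fields))
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            raise FeatureTableError("start/end must be integers", lineno)
        opt = lambda key: None if row[key] == _NA else row[key]
        try:
            rec = GeneRecord(
                name=row["gene"],
                klass=GeneClass(row["klass"]),
                strand=row["strand"],
                start=start,
                end=end,
                anticodon=opt("anticodon"),
                init_codon=opt("init_codon"),
                term_codon=opt("term_codon"),
            )
        except ValueError as exc:
            raise FeatureTableError(str(exc), lineno)
        if genome_length is not None and row["size"] != _NA:
            expect = length_on_circle(start, end, genome_length)
            if int(row["size"]) != expect:
                raise FeatureTableError(
                    f"{rec.name}: size column {row['size']} != {expect} from coordinates", lineno
                )
        genes.append(rec)
    if not genes:
        raise FeatureTableError("no gene rows found" + ("" if saw_header else " (empty file?)"))
    return AnnotationTable(genes=genes, genome_length=genome_length)


def feature_table_to_string(table: AnnotationTable, genome_length: Optional[int] = None) -> str:
    L = genome_length if genome_length is not None else table.genome_length
    lines = []
    if L is not None:
        lines.append(f"#genome_length={L}")
    lines.append("\t".join(_COLUMNS))
    genes = table.genes
    for i, g in enumerate(genes):
        size = str(g.length(L)) if L is not None else _NA
        if L is not None:
            nxt = genes[(i + 1) % len(genes)]
            spacer = str(circular_spacer(g.end, nxt.start, L))
        else:
            spacer = _NA
        lines.append(
            "\t".join(
                [
                    g.name,
                    g.klass.value,
                    g.strand,
                    str(g.start),
                    str(g.end),
                    size,
                    g.anticodon or _NA,
                    g.init_codon or _NA,
                    g.term_codon or _NA,
                    spacer,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_feature_table(
    table: AnnotationTable, path: Union[str, Path], genome_length: Optional[int] = None
) -> None:
    Path(path).write_text(feature_table_to_string(table, genome_length))


def read_fasta(path: Union[str, Path]) -> list[CircularGenome]:
    """Read a (multi-record) FASTA of nucleotide sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [CircularGenome(seq=str(r.seq), id=r.id) for r in records]


def write_fasta(genomes, path: Union[str, Path], width: int = 70) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


_GB_CLASS = {"CDS": GeneClass.PCG, "tRNA": GeneClass.TRNA, "rRNA": GeneClass.RRNA,
             "D-loop": GeneClass.CONTROL}


def read_genbank_minimal(path: Union[str, Path]) -> tuple[CircularGenome, AnnotationTable]:
    """Extract sequence + CDS/tRNA/rRNA/D-loop features from a GenBank flat file.

    Coordinates are converted to 1-based inclusive; ``complement()``
    locations become strand N.  Initiation codons are read off the
    sequence; termination codons are inferred from the length modulo 3
    (remainder 1 -> T, remainder 2 -> TA, else the final triplet).
    """
    record = SeqIO.read(str(path), "genbank")
    genome = CircularGenome(seq=str(record.seq), id=record.id)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in record.features:
        klass = _GB_CLASS.get(feat.type)
        if klass is None:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [f"{feat.type}_{len(genes)}"])[0]
        name = name.replace(" ", "_")
        if name in seen:  # e.g. a duplicated tRNA isoacceptor without AGN/UCN suffix
            name = f"{name}_{len(genes)}"
        seen.add(name)
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "N" if feat.location.strand == -1 else "J"
        anticodon = init_codon = term_codon = None
        if klass is GeneClass.TRNA:
            anticodon = "NNN"
            ac = quals.get("anticodon")
            if ac:  # e.g. "(pos:..,aa:Ile,seq:gat)"
                seq_part = ac[0].rsplit("seq:", 1)
                if len(seq_part) == 2:
                    anticodon = seq_part[1].strip(")").upper().replace("U", "T")
        elif klass is GeneClass.PCG:
            raw = genome.slice(start, end)
            cds = raw if strand == "J" else reverse_complement(raw)
            init_codon = cds[:3]
            r = len(cds) % 3
            trailing = cds[-3:] if r == 0 else cds[-r:]
            # trust the sequence when it shows a legal (possibly truncated)
            # stop; otherwise fall back on the reading-frame remainder
            if trailing in ("TAA", "TAG", "TA", "T"):
                term_codon = trailing
            else:
                term_codon = "TAA" if r == 0 else ("T" if r == 1 else "TA")
        genes.append(
            GeneRecord(name=name, klass=klass, strand=strand, start=start, end=end,
                       anticodon=anticodon, init_codon=init_codon, term_codon=term_codon)
        )
    return genome, AnnotationTable(genes=genes, genome_length=genome.length)
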