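"""Protein-coding gene boundary assignment on a circular mitogenome.

Mitochondrial PCGs start at ATN or NTG codons and often end in
*incomplete* stop codons: a bare T or TA at the gene's 3' end that is
completed to TAA by post-transcriptional polyadenylation.  The
annotation procedure implemented here mirrors standard mitogenome
curation practice:

* candidate starts are in-frame ATN/NTG codons; the chosen start
  minimizes the absolute spacer (gap or overlap) to the upstream
  neighbor;
* a gene keeps its full TAA/TAG stop unless that stop would overlap a
  downstream tRNA, in which case the gene is truncated to the longest
  of TA/T that removes the overlap;
* full stops are kept in PCG-PCG overlaps (bicistronic pairs such as
  atp8/atp6 and nad4L/nad4);
* tRNA and rRNA boundaries are taken as given and never refined.

Translation uses the invertebrate mitochondrial genetic code
(translation table 5) by default, under which TGA encodes Trp and the
only stops are TAA and TAG.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from Bio.Data import CodonTable

from .genome import (
    AnnotationTable,
    CircularGenome,
    GeneClass,
    GeneRecord,
    circular_spacer,
    reverse_complement,
)

__all__ = [
    "BoundaryPolicy",
    "OrfCandidate",
    "BoundaryError",
    "NoStartError",
    "UnresolvableBoundaryError",
    "scan_orfs",
    "assign_initiation",
    "assign_termination",
    "refine_boundaries",
    "translate",
    "FULL_STOPS",
]

FULL_STOPS = ("TAA", "TAG")

#: canonical-start preference used to break spacer ties
START_PREFERENCE = ("ATG", "ATA", "ATT", "ATC", "GTG", "TTG", "CTG")


class BoundaryError(ValueError):
    pass


class NoStartError(BoundaryError):
    pass


class UnresolvableBoundaryError(BoundaryError):
    pass


@dataclass(frozen=True)
class BoundaryPolicy:
    """Rules governing PCG boundary assignment.

    ``forbid_pcg_trna_overlap`` applies to termination codons (the rule
    that produces incomplete T/TA stops).  Start-codon overlap into an
    upstream feature is admissible by default — published annotations
    contain such starts (e.g. cox1 beginning inside trnY) — and can be
    prohibited with ``forbid_start_overlap``.
    """

    allowed_starts: tuple[str, ...] = START_PREFERENCE
    allow_pcg_pcg_overlap: bool = True
    forbid_pcg_trna_overlap: bool = True
    forbid_start_overlap: bool = False
    genetic_code: int = 5
    start_window_codons: int = 15
    max_scan_codons: int = 4000


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate open reading frame on the circle (majority coordinates)."""

    strand: str
    frame: int
    start: int
    end: int
    init_codon: str
    term_codon: str


class _Oriented:
    """Coordinate arithmetic along a gene's reading direction.

    Oriented offset u counts 0,1,2,... in the 5'->3' direction of the
    given strand, anchored at majority coordinate ``ref``.
    """

    def __init__(self, genome: CircularGenome, strand: str, ref: int):
        self.genome = genome
        self.L = genome.length
        self.strand = strand
        self.ref = ref

    def major(self, u: int) -> int:
        if self.strand == "J":
            return (self.ref - 1 + u) % self.L + 1
        return (self.ref - 1 - u) % self.L + 1

    def offset(self, major: int) -> int:
        if self.strand == "J":
            return (major - self.ref) % self.L
        return (self.ref - major) % self.L

def _oriented_base(genome: CircularGenome, strand: str, major: int) -> str:
    b = genome.seq[major - 1]
    if strand == "J":
        return b
    return reverse_complement(b)


def _codon_table(code: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code]


def translate(cds: str, code: int = 5, incomplete_stop_policy: bool = True) -> str:
    """Translate complete codons; stops render as '*'.

    With ``incomplete_stop_policy`` the trailing 1-2 bases of a gene
    ending in an incomplete stop are ignored; otherwise a length not
    divisible by 3 is an error.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    rem = len(cds) % 3
    if rem and not incomplete_stop_policy:
        raise ValueError(f"length {len(cds)} not divisible by 3")
    table = _codon_table(code)
    out = []
    for i in range(0, len(cds) - rem, 3):
        codon = cds[i : i + 3]
        if codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table.get(codon, "X"))
    return "".join(out)


def scan_orfs(
    genome: CircularGenome,
    strand: str,
    policy: BoundaryPolicy = BoundaryPolicy(),
    min_codons: int = 30,
) -> list[OrfCandidate]:
    """Enumerate allowed-start ORFs in all three frames of one strand.

    Every maximal stop-bounded reading-frame segment is scanned on the
    doubled (linearized) circle so that ORFs spanning the origin are
    found once, with wrapped coordinates.
    """
    L = genome.length
    if L < 6:
        raise ValueError("genome too short to scan")
    seq = genome.seq if strand == "J" else reverse_complement(genome.seq)
    doubled = seq + seq
    out: list[OrfCandidate] = []
    seen: set[tuple] = set()
    for frame in range(3):
        stops = [i for i in range(frame, 2 * L - 2, 3) if doubled[i : i + 3] in FULL_STOPS]
        bounds = [frame - 3] + stops
        for b_prev, b_stop in zip(bounds, bounds[1:]):
            seg_start = b_prev + 3
            if seg_start >= L:  # duplicate of a first-copy segment
                continue
            if b_stop - seg_start > L:  # stop-free wrap longer than the circle
                continue
            for i in range(seg_start, b_stop, 3):
                if i >= L:  # starts in the second copy repeat first-copy ones
                    break
                codon = doubled[i : i + 3]
                if codon not in policy.allowed_starts:
                    continue
                n_codons = (b_stop + 3 - i) // 3
                if n_codons < min_codons:
                    continue
                s0 = i % L
                e0 = (b_stop + 2) % L
                if strand == "J":
                    start, end = s0 + 1, e0 + 1
                else:
                    start, end = L - e0, L - s0
                key = (strand, start, end)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    OrfCandidate(
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        init_codon=codon,
                        term_codon=doubled[b_stop : b_stop + 3],
                    )
                )
    return out


def _start_spacer(p5_major: int, upstream: GeneRecord, strand: str, L: int) -> int:
    """Signed spacer between the upstream neighbor and a candidate 5' start."""
    if strand == "J":
        return circular_spacer(upstream.end, p5_major, L)
    return circular_spacer(p5_major, upstream.start, L)


def assign_initiation(
    candidates: list[tuple[int, str]],
    upstream_gene: GeneRecord,
    strand: str,
    genome_length: int,
    policy: BoundaryPolicy = BoundaryPolicy(),
) -> tuple[int, str]:
    """Choose the start minimizing |spacer| to the upstream neighbor.

    ``candidates`` are (majority 5' coordinate, init codon) pairs that
    share a reading frame and termination.  Ties prefer a gap over an
    overlap, then the canonical start order ATG > ATA > ATT > ATC >
    GTG > TTG > CTG, then the upstream-most position.
    """
    if not candidates:
        raise NoStartError("no admissible start codon")
    scored = []
    for p, codon in candidates:
        s = _start_spacer(p, upstream_gene, strand, genome_length)
        if (
            policy.forbid_start_overlap
            and upstream_gene.klass is GeneClass.TRNA
            and s < 0
        ):
            continue
        pref = START_PREFERENCE.index(codon) if codon in START_PREFERENCE else len(START_PREFERENCE)
        scored.append((abs(s), 0 if s >= 0 else 1, pref, -s, p, codon))
    if not scored:
        raise NoStartError("no admissible start codon under overlap policy")
    scored.sort()
    _, _, _, _, p, codon = scored[0]
    return p, codon


def assign_termination(
    genome: CircularGenome,
    strand: str,
    start5_major: int,
    downstream_gene: Optional[GeneRecord],
    policy: BoundaryPolicy = BoundaryPolicy(),
) -> tuple[str, int]:
    """Find the termination codon and 3' end for an ORF starting at start5.

    Scans in-frame for the first full stop (TAA/TAG).  If that stop
    would overlap a downstream tRNA, the gene is truncated at the tRNA
    boundary to the longest trailing T/TA (incomplete stop).  Full
    stops are kept when the downstream neighbor is another PCG (or an
    rRNA/control region).  Returns (term_codon, majority end
    coordinate of the gene's 3' terminus).
    """
    ori = _Oriented(genome, strand, start5_major)
    stop_u = None
    for k in range(policy.max_scan_codons):
        codon = "".join(_oriented_base(genome, strand, ori.major(3 * k + i)) for i in range(3))
        if codon in FULL_STOPS:
            stop_u = 3 * k
            stop_codon = codon
            break
    if stop_u is None:
        raise UnresolvableBoundaryError("no in-frame stop codon found within scan limit")
    truncate = False
    if (
        downstream_gene is not None
        and downstream_gene.klass is GeneClass.TRNA
        and policy.forbid_pcg_trna_overlap
    ):
        b_major = downstream_gene.start if strand == "J" else downstream_gene.end
        u_b = ori.offset(b_major)
        if stop_u + 2 >= u_b:
            truncate = True
    if not truncate:
        return stop_codon, ori.major(stop_u + 2)
    # truncate to the longest trailing T / TA ending before the tRNA
    for e in (u_b - 1, u_b - 2, u_b - 3):
        r = (e + 1) % 3
        if r == 0 or e < 2:
            continue
        trailing = "".join(
            _oriented_base(genome, strand, ori.major(e - r + 1 + i)) for i in range(r)
        )
        if trailing == "TA"[:r]:
            return trailing, ori.major(e)
    raise UnresolvableBoundaryError(
        "neither T nor TA resolves the stop-codon overlap with the downstream tRNA"
    )


def refine_boundaries(
    draft: AnnotationTable,
    genome: CircularGenome,
    policy: BoundaryPolicy = BoundaryPolicy(),
) -> AnnotationTable:
    """Re-assign every PCG's boundaries; tRNA/rRNA records are fixed.

    The draft provides each PCG's strand and an approximate 5' start
    *within the gene body and in the correct reading frame* (the
    convention of ORF-finder drafts, which overshoot inward).  Each PCG
    is re-bounded by enumerating in-frame allowed starts in a window
    around the draft start that share the gene's termination, choosing
    the spacer-minimizing start, and assigning the full or incomplete
    stop.  Applying the procedure to an already-conforming table is the
    identity.
    """
    L = genome.length
    genes = [replace(g) for g in draft.genes]
    n = len(genes)
    for i, g in enumerate(genes):
        if g.klass is not GeneClass.PCG:
            continue
        strand = g.strand
        d5 = g.start if strand == "J" else g.end
        if strand == "J":
            upstream, downstream = genes[(i - 1) % n], genes[(i + 1) % n]
        else:
            upstream, downstream = genes[(i + 1) % n], genes[(i - 1) % n]
        try:
            ori = _Oriented(genome, strand, d5)
            term, end3 = assign_termination(genome, strand, d5, downstream, policy)
            stop_free_u = ori.offset(end3)  # any candidate must not cross a stop
            # enumerate in-frame allowed starts around the draft start
            candidates: list[tuple[int, str]] = []
            W = policy.start_window_codons
            for k in range(-W, W + 1):
                u = 3 * k
                p_major = ori.major(u)
                codon = "".join(
                    _oriented_base(genome, strand, ori.major(u + j)) for j in range(3)
                )
                if codon not in policy.allowed_starts:
                    continue
                if k < 0:
                    # must reach the shared stop: no full stop between here and d5
                    blocked = any(
                        "".join(
                            _oriented_base(genome, strand, ori.major(3 * m + j))
                            for j in range(3)
                        )
                        in FULL_STOPS
                        for m in range(k, 0)
                    )
                    if blocked:
                        continue
                else:
                    if u >= stop_free_u:  # start at/after the terminus
                        continue
                candidates.append((p_major, codon))
            p5, init = assign_initiation(candidates, upstream, strand, L, policy)
            term, end3 = assign_termination(genome, strand, p5, downstream, policy)
        except BoundaryError as exc:
            raise type(exc)(f"{g.name}: {exc}") from exc
        if strand == "J":
            g.start, g.end = p5, end3
        else:
            g.start, g.end = end3, p5
        g.init_codon, g.term_codon = init, term
    return AnnotationTable(genes=genes, genome_length=L)
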