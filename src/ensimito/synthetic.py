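"""Synthetic mitogenomes, tRNAs and alignments with known truth.

Every pipeline stage is exercisable without downloads: this module
plants a complete annotated circular mitogenome (37 genes + control
region in the ancestral arthropod gene order by default, with the
published layout's lengths, strands, spacers and codon assignments),
builds tRNA genes from cloverleaf templates with optional planted
pairing defects, and simulates sequence alignments along a known tree
under GTR+I+Γ.

The genome generator guarantees, by construction and a deterministic
constraint-repair pass, that the boundary-refinement rules of
:mod:`ensimito.annotation` recover the planted truth exactly: PCG
bodies contain no in-frame stops, and no decoy start codon lies closer
to the upstream neighbor than the planted start.

One global seed drives per-stage/per-gene sub-seeds (via numpy
``SeedSequence.spawn``) so regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .annotation import FULL_STOPS, START_PREFERENCE
from .genome import (
    AnnotationTable,
    CircularGenome,
    GeneClass,
    GeneRecord,
    circular_spacer,
    reverse_complement,
)
from .io import load_reference_annotation
from .supermatrix import GeneAlignment
from .phylo.model import BASES, GTRModel, GTRParams
from .phylo.tree import Node, Tree
from .trna import CloverleafStructure, _build_structure, classify_pair, PairClass

__all__ = [
    "TrnaTemplate",
    "generate_trna",
    "GenomeRecipe",
    "RecipeError",
    "default_recipe",
    "GenomeBundle",
    "generate_mitogenome",
    "perturb_to_draft",
    "simulate_alignment",
    "simulate_gene_alignments",
    "random_topology",
    "ensifera_demo_tree",
]

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_ALLOWED_STARTS = set(START_PREFERENCE)


class RecipeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tRNA generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrnaTemplate:
    """Arm-length specification of a cloverleaf template.

    Defaults are the canonical mito layout: 7 bp acceptor, 4 bp DHU,
    5 bp anticodon stem with a 7-nt loop, 5 bp TψC stem.
    """

    acceptor: int = 7
    connector1: int = 2
    dhu: int = 4
    dhu_loop: int = 4
    connector2: int = 1
    anticodon_stem: int = 5
    bulge: bool = False
    anticodon_loop: int = 7
    variable: int = 4
    t_stem: int = 5
    t_loop: int = 4
    anticodon: Optional[str] = None

    @property
    def length(self) -> int:
        dhu = 2 * self.dhu + self.dhu_loop if self.dhu > 0 else 0
        return (
            2 * self.acceptor + self.connector1 + dhu + self.connector2
            + 2 * self.anticodon_stem + (1 if self.bulge else 0)
            + self.anticodon_loop + self.variable + 2 * self.t_stem + self.t_loop
        )

    @property
    def layout(self) -> tuple:
        return (
            self.acceptor, self.connector1, self.dhu, self.dhu_loop if self.dhu else 0,
            self.connector2, self.anticodon_stem, self.bulge, self.anticodon_loop,
            self.variable, self.t_stem, self.t_loop,
        )


def template_for_length(length: int, anticodon: Optional[str] = None) -> TrnaTemplate:
    """A canonical template whose loops are sized to hit ``length``."""
    base = TrnaTemplate(anticodon=anticodon)
    rem = length - (base.length - base.dhu_loop - base.t_loop)
    if rem < 6:
        raise RecipeError(f"tRNA length {length} too short for the canonical template")
    dl = min(3 + (rem - 6) // 2, 9)
    tl = rem - dl
    if not 3 <= tl <= 9:
        raise RecipeError(f"tRNA length {length} outside the canonical template range")
    return replace(base, dhu_loop=dl, t_loop=tl)


_MISMATCH_PAIRS = [("T", "T"), ("T", "C"), ("C", "T"), ("A", "C"), ("C", "A"),
                   ("A", "A"), ("G", "A"), ("A", "G"), ("C", "C")]
_LOOP_ALPHABET = "AC"  # loop bases never form WC/wobble pairs with each other


def random_defects(
    template: "TrnaTemplate", n: int, seed: int | np.random.Generator
) -> list[tuple[str, int, str]]:
    """Sample ``n`` pairing defects scattered over distinct arms.

    At most one defect is planted per stem, mirroring observed mito
    tRNA structures where non-canonical pairs scatter across arms;
    clustering several defects in one short stem can make the
    template assignment genuinely sub-optimal (another fold then
    scores higher), which is a property of the structure, not a
    recovery failure.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stems = {
        "acceptor": template.acceptor,
        "DHU": template.dhu,
        "anticodon": template.anticodon_stem,
        "TpsiC": template.t_stem,
    }
    arms = [a for a, ln in stems.items() if ln > 0]
    if n > len(arms):
        raise RecipeError(f"cannot place {n} defects in {len(arms)} distinct arms")
    chosen = rng.choice(len(arms), size=n, replace=False)
    out = []
    for ai in chosen:
        arm = arms[ai]
        ln = stems[arm]
        kind = ("wobble", "mismatch")[int(rng.integers(2))]
        if kind == "mismatch":
            # a mismatched terminal rung is indistinguishable from a
            # shorter stem, so mismatches go to interior rungs only
            # (the acceptor stem is anchored at the sequence ends, so
            # only its inner terminus is ambiguous)
            if arm == "acceptor":
                valid = list(range(0, ln - 1))
            else:
                valid = list(range(1, ln - 1))
            if not valid:
                kind = "wobble"
                idx = int(rng.integers(ln))
            else:
                idx = int(valid[rng.integers(len(valid))])
        else:
            idx = int(rng.integers(ln))
        out.append((arm, idx, kind))
    return out


def generate_trna(
    template: TrnaTemplate,
    defects: list[tuple[str, int, str]] = (),
    seed: int | np.random.Generator = 0,
    fixed_positions: Optional[dict[int, str]] = None,
    verify: bool = True,
) -> tuple[str, CloverleafStructure]:
    """Build a tRNA sequence folding onto ``template`` by construction.

    ``defects`` plant non-WC pairs: (arm name, pair index within the
    stem, "wobble"|"mismatch"); every other stem pair is Watson-Crick.
    ``fixed_positions`` pins bases (0-based index in the tRNA's own
    5'->3' orientation), used when genes overlap in a genome.  With
    ``verify`` the generated sequence is re-folded and must reproduce
    the template layout and the planted pairing census exactly
    (regenerating with a derived sub-seed when an accidental
    alternative fold scores equally well).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fixed_positions = dict(fixed_positions or {})
    truth = _build_structure(template.length, template.layout, template.anticodon)
    for arm, idx, kind in defects:
        if arm not in truth.arms or idx >= len(truth.arms[arm]):
            raise RecipeError(f"defect outside stem: {(arm, idx, kind)}")
        if kind not in ("wobble", "mismatch"):
            raise RecipeError(f"unknown defect kind {kind!r}")
    last_err = "unknown"
    for _attempt in range(40):
        seq = [None] * template.length
        ok = True
        for i, b in fixed_positions.items():
            seq[i] = b
        paired = {i for ij in truth.all_pairs() for i in ij}
        # anticodon triplet
        anticodon = template.anticodon
        if anticodon is None:
            anticodon = "".join(rng.choice(list("ACGT"), 3))
        truth.anticodon_triplet = anticodon
        for i, b in zip(truth.anticodon_indices, anticodon):
            if seq[i] is not None and seq[i] != b:
                raise RecipeError("fixed position conflicts with the anticodon")
            seq[i] = b
        # loops, connectors, bulges
        for i in range(template.length):
            if i in paired or seq[i] is not None:
                continue
            seq[i] = _LOOP_ALPHABET[rng.integers(len(_LOOP_ALPHABET))]
        # stems
        defect_map = {(arm, idx): kind for arm, idx, kind in defects}
        for arm, ladder in truth.arms.items():
            for idx, (i, j) in enumerate(ladder):
                kind = defect_map.get((arm, idx))
                if kind is None:  # Watson-Crick
                    if seq[i] is not None and seq[j] is not None:
                        if classify_pair(seq[i], seq[j]) is not PairClass.WC:
                            ok = False
                            last_err = f"fixed bases break WC pair at {arm}[{idx}]"
                            break
                    elif seq[i] is not None:
                        seq[j] = _COMP[seq[i]]
                    elif seq[j] is not None:
                        seq[i] = _COMP[seq[j]]
                    else:
                        b = "ACGT"[rng.integers(4)]
                        seq[i], seq[j] = b, _COMP[b]
                elif kind == "wobble":
                    choice = [("G", "T"), ("T", "G")][rng.integers(2)]
                    if seq[i] is None and seq[j] is None:
                        seq[i], seq[j] = choice
                    elif seq[i] in ("G", "T") and seq[j] is None:
                        seq[j] = "T" if seq[i] == "G" else "G"
                    elif seq[j] in ("G", "T") and seq[i] is None:
                        seq[i] = "T" if seq[j] == "G" else "G"
                    else:
                        ok = False
                        last_err = f"cannot plant wobble at {arm}[{idx}]"
                        break
                else:  # mismatch
                    options = [
                        (x, y) for x, y in _MISMATCH_PAIRS
                        if (seq[i] in (None, x)) and (seq[j] in (None, y))
                    ]
                    if not options:
                        ok = False
                        last_err = f"cannot plant mismatch at {arm}[{idx}]"
                        break
                    x, y = options[rng.integers(len(options))]
                    seq[i], seq[j] = x, y
            if not ok:
                break
        if not ok:
            continue
        # mini DHU arms (1-2 bp) are fragile: an accidental WC/wobble
        # contact between nearby loop/connector bases forms an
        # equally-scoring alternative arm.  Scrub the DHU window so the
        # planted rung(s) are the only pairable contacts in it.
        if 1 <= template.dhu <= 2:
            ac_start = min(i for i, _ in truth.arms["anticodon"]) if truth.arms["anticodon"] else template.length
            ac_start = min(ac_start, *(truth.bulges or [ac_start]))
            window = range(template.acceptor, ac_start)
            truth_dhu = set(truth.arms["DHU"])
            stem_positions = {i for ij in truth.all_pairs() for i in ij}
            for _scrub_round in range(10):
                dirty = False
                for x in window:
                    for y in window:
                        if y - x - 1 < 3 or (x, y) in truth_dhu:
                            continue
                        if classify_pair(seq[x], seq[y]) is PairClass.MISMATCH:
                            continue
                        repaired = False
                        for pos, other in ((y, x), (x, y)):
                            if pos in fixed_positions or pos in stem_positions:
                                continue
                            for base in "AC":
                                seq[pos] = base
                                if classify_pair(seq[x], seq[y]) is PairClass.MISMATCH:
                                    repaired = True
                                    break
                            if repaired:
                                break
                        if repaired:
                            dirty = True
                        else:
                            ok = False
                if not dirty:
                    break
            if not ok:
                last_err = "cannot scrub decoy pairs around the mini DHU arm"
                continue
        seq_str = "".join(seq)
        if not verify:
            return seq_str, truth
        from .trna import fold_cloverleaf, pairing_census

        folded = fold_cloverleaf(seq_str, anticodon=anticodon)
        if folded is None:
            last_err = "no admissible fold"
            continue
        if (
            folded.stem_lengths == truth.stem_lengths
            and folded.all_pairs() == truth.all_pairs()
        ):
            return seq_str, truth
        last_err = "alternative fold outscored the template"
    raise RecipeError(f"could not generate tRNA after 40 attempts: {last_err}")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayoutRow:
    name: str
    klass: GeneClass
    strand: str
    length: int
    spacer_after: int  # signed gap to the next feature in table order


@dataclass
class GenomeRecipe:
    """Everything needed to plant a mitogenome with known truth."""

    layout: list[LayoutRow]
    pcg_codons: dict[str, tuple[str, str]]
    trna_anticodons: dict[str, str]
    trna_templates: dict[str, TrnaTemplate] = field(default_factory=dict)
    control_repeat_unit: int = 55
    control_repeat_copies: int = 8
    at_fraction: float = 0.70
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return sum(r.length + r.spacer_after for r in self.layout)


def default_recipe(seed: int = 0) -> GenomeRecipe:
    """The published 37-gene + control-region layout as a recipe.

    Gene order, strands, lengths, signed spacers, start/stop codon
    choices and anticodons all mirror the deposited annotation, so
    generated genomes have the ancestral arthropod gene order with the
    same adjacency ledger (including the atp8/atp6 and nad4L/nad4
    7-nt overlaps and the six single-T incomplete stops).
    """
    ref = load_reference_annotation()
    L = ref.genome_length
    rows = []
    genes = ref.genes
    for i, g in enumerate(genes):
        nxt = genes[(i + 1) % len(genes)]
        rows.append(
            LayoutRow(
                name=g.name,
                klass=g.klass,
                strand=g.strand,
                length=g.length(L),
                spacer_after=circular_spacer(g.end, nxt.start, L),
            )
        )
    pcg_codons = {
        g.name: (g.init_codon, g.term_codon) for g in ref.of_class(GeneClass.PCG)
    }
    anticodons = {g.name: g.anticodon for g in ref.of_class(GeneClass.TRNA)}
    return GenomeRecipe(
        layout=rows, pcg_codons=pcg_codons, trna_anticodons=anticodons, seed=seed
    )


@dataclass
class GenomeBundle:
    genome: CircularGenome
    table: AnnotationTable
    trna_structures: dict[str, CloverleafStructure]
    recipe: GenomeRecipe

    def __iter__(self):  # allow  genome, table = generate_mitogenome(...)
        return iter((self.genome, self.table))


class _Builder:
    def __init__(self, L: int, at: float):
        self.L = L
        self.seq: list[Optional[str]] = [None] * L
        self.fixed = [False] * L
        self.at_p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])

    def random_base(self, rng) -> str:
        return BASES[rng.choice(4, p=self.at_p)]

    def write(self, pos1: int, base: str, fix: bool) -> None:
        i = (pos1 - 1) % self.L
        if self.seq[i] is not None and self.seq[i] != base:
            raise RecipeError(f"conflicting fixed bases at position {pos1}")
        self.seq[i] = base
        self.fixed[i] = self.fixed[i] or fix


def _oriented_major(rec: GeneRecord, u: int, L: int) -> int:
    if rec.strand == "J":
        return (rec.start - 1 + u) % L + 1
    return (rec.end - 1 - u) % L + 1


def _scrub_offsets(spacer: int) -> list[int]:
    """Codon offsets (in codons) whose start would tie or beat the truth."""
    ks = []
    k = 1
    while abs(spacer + 3 * k) <= abs(spacer):
        ks.append(k)
        k += 1
    k = -1
    while abs(spacer + 3 * k) <= abs(spacer):
        ks.append(k)
        k -= 1
    return ks


def generate_mitogenome(recipe: GenomeRecipe) -> GenomeBundle:
    """Plant an annotated circular genome; deterministic per seed."""
    L = recipe.genome_length
    if L <= 0:
        raise RecipeError("layout lengths/spacers do not define a positive genome length")
    names = [r.name for r in recipe.layout]
    if len(names) != len(set(names)):
        raise RecipeError("duplicate gene names in layout")
    ss = np.random.SeedSequence(recipe.seed)
    rng_gap, rng_body, rng_repair, rng_region = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    trna_seeds = {r.name: s for r, s in
                  zip([r for r in recipe.layout if r.klass is GeneClass.TRNA],
                      ss.spawn(sum(1 for r in recipe.layout if r.klass is GeneClass.TRNA)))}

    # coordinates
    records: list[GeneRecord] = []
    pos = 1
    for row in recipe.layout:
        start = (pos - 1) % L + 1
        end = (pos + row.length - 2) % L + 1
        kw = {}
        if row.klass is GeneClass.TRNA:
            kw["anticodon"] = recipe.trna_anticodons.get(row.name, "NNN")
        if row.klass is GeneClass.PCG:
            try:
                kw["init_codon"], kw["term_codon"] = recipe.pcg_codons[row.name]
            except KeyError:
                raise RecipeError(f"{row.name}: missing start/stop codon choice")
        records.append(GeneRecord(row.name, row.klass, row.strand, start, end, **kw))
        pos = pos + row.length + row.spacer_after
    if (pos - 1) % L != 0:
        raise RecipeError("spacers do not close the circle")
    table = AnnotationTable(genes=records, genome_length=L)
    by_name = {g.name: g for g in records}

    b = _Builder(L, recipe.at_fraction)

    def write_oriented(rec: GeneRecord, u: int, base: str, fix: bool) -> None:
        m = _oriented_major(rec, u, L)
        b.write(m, base if rec.strand == "J" else _COMP[base], fix)

    def read_oriented(rec: GeneRecord, u: int) -> Optional[str]:
        m = _oriented_major(rec, u, L)
        raw = b.seq[(m - 1) % L]
        if raw is None:
            return None
        return raw if rec.strand == "J" else _COMP[raw]

    # 1. pin PCG start and stop codons
    for g in records:
        if g.klass is not GeneClass.PCG:
            continue
        glen = g.length(L)
        init, term = g.init_codon, g.term_codon
        if (glen - len(term)) % 3 != 0:
            raise RecipeError(
                f"{g.name}: length {glen} inconsistent with termination codon {term}"
            )
        for u, base in enumerate(init):
            write_oriented(g, u, base, fix=True)
        for off, base in enumerate(term):
            write_oriented(g, glen - len(term) + off, base, fix=True)

    # PCG-frame codon constraints that later fixed regions must respect:
    # no in-frame stop inside a PCG body, and no decoy start codon that
    # would tie or beat the planted start's spacer.
    def upstream_spacer(i: int) -> int:
        g = records[i]
        n = len(records)
        if g.strand == "J":
            up = records[(i - 1) % n]
            return circular_spacer(up.end, g.start, L)
        up = records[(i + 1) % n]
        return circular_spacer(g.end, up.start, L)

    stops = set(FULL_STOPS)
    constraints: list[tuple[tuple[int, int, int], str, frozenset]] = []
    for i, g in enumerate(records):
        if g.klass is not GeneClass.PCG:
            continue
        glen = g.length(L)
        tail = len(g.term_codon)
        for m in range(1, (glen - tail) // 3):
            triple = tuple((_oriented_major(g, 3 * m + j, L) - 1) % L for j in range(3))
            constraints.append((triple, g.strand, frozenset(stops)))
        for k in _scrub_offsets(upstream_spacer(i)):
            triple = tuple((_oriented_major(g, 3 * k + j, L) - 1) % L for j in range(3))
            constraints.append((triple, g.strand, frozenset(_ALLOWED_STARTS)))
    touching: dict[int, list[int]] = {}
    for ci, (triple, _, _) in enumerate(constraints):
        for p in triple:
            touching.setdefault(p, []).append(ci)

    # 2. tRNAs from templates (respecting already-pinned bases and the
    #    PCG-frame constraints on any overlap)
    trna_structures: dict[str, CloverleafStructure] = {}
    for g in records:
        if g.klass is not GeneClass.TRNA:
            continue
        glen = g.length(L)
        template = recipe.trna_templates.get(g.name)
        if template is None:
            template = template_for_length(glen, anticodon=g.anticodon)
        elif template.length != glen:
            raise RecipeError(f"{g.name}: template length {template.length} != {glen}")
        fixed = {}
        span: dict[int, int] = {}  # majority index0 -> oriented offset
        for u in range(glen):
            span[(_oriented_major(g, u, L) - 1) % L] = u
            base = read_oriented(g, u)
            if base is not None:
                fixed[u] = base
        check = sorted({ci for p in span for ci in touching.get(p, [])})
        trna_rng = np.random.default_rng(trna_seeds[g.name])
        for _attempt in range(60):
            seq, struct = generate_trna(
                template, seed=trna_rng, fixed_positions=fixed, verify=False,
            )

            def base_after(p: int) -> Optional[str]:
                if p in span:
                    ob = seq[span[p]]
                    return ob if g.strand == "J" else _COMP[ob]
                return b.seq[p] if b.fixed[p] else None

            bad = False
            for ci in check:
                triple, strand, forbidden = constraints[ci]
                raw = [base_after(p) for p in triple]
                # reject when every completion of the fixed bases is forbidden
                # (a remaining modifiable base can otherwise be repaired later)
                completions = [""]
                for x in raw:
                    opts = [x] if x is not None else list("ACGT")
                    completions = [c + o for c in completions for o in opts]
                if strand == "N":
                    completions = ["".join(_COMP[ch] for ch in c) for c in completions]
                if all(c in forbidden for c in completions):
                    bad = True
                    break
            if not bad:
                break
        else:
            raise RecipeError(f"{g.name}: no tRNA sequence satisfies the overlap constraints")
        for u, base in enumerate(seq):
            write_oriented(g, u, base, fix=True)
        trna_structures[g.name] = struct

    # 3. rRNAs and control region
    for g in records:
        glen = g.length(L)
        if g.klass is GeneClass.RRNA:
            for u in range(glen):
                if read_oriented(g, u) is None:
                    write_oriented(g, u, b.random_base(rng_region), fix=True)
        elif g.klass is GeneClass.CONTROL:
            unit = "".join(b.random_base(rng_region) for _ in range(recipe.control_repeat_unit))
            rep = (unit * recipe.control_repeat_copies)[: glen]
            body = rep + "".join(
                b.random_base(rng_region) for _ in range(glen - len(rep))
            )
            for u in range(glen):
                if read_oriented(g, u) is None:
                    write_oriented(g, u, body[u], fix=True)

    # 4. intergenic gaps
    covered = [False] * L
    for g in records:
        glen = g.length(L)
        for u in range(glen):
            covered[(_oriented_major(g, u, L) - 1) % L] = True
    for i in range(L):
        if not covered[i] and b.seq[i] is None:
            b.seq[i] = b.random_base(rng_gap)

    # 5. PCG bodies: in-frame codons avoiding stops where freely choosable
    stops = set(FULL_STOPS)
    for g in records:
        if g.klass is not GeneClass.PCG:
            continue
        glen = g.length(L)
        tail = len(g.term_codon)
        for m in range(1, (glen - tail) // 3):
            us = (3 * m, 3 * m + 1, 3 * m + 2)
            current = [read_oriented(g, u) for u in us]
            if all(c is None for c in current):
                while True:
                    codon = "".join(
                        BASES[rng_body.choice(4, p=b.at_p)] for _ in range(3)
                    )
                    if codon not in stops:
                        break
                for u, base in zip(us, codon):
                    write_oriented(g, u, base, fix=False)
            else:
                for u, c in zip(us, current):
                    if c is None:
                        write_oriented(g, u, b.random_base(rng_body), fix=False)

    # 6. constraint repair: no in-frame stops in bodies, no decoy starts
    def codon_at(g: GeneRecord, u: int) -> str:
        out = []
        for j in range(3):
            base = b.seq[(_oriented_major(g, u + j, L) - 1) % L]
            out.append("N" if base is None else (base if g.strand == "J" else _COMP[base]))
        return "".join(out)

    def violations() -> list[tuple[GeneRecord, int, str]]:
        out = []
        for i, g in enumerate(records):
            if g.klass is not GeneClass.PCG:
                continue
            glen = g.length(L)
            tail = len(g.term_codon)
            for m in range(1, (glen - tail) // 3):
                if codon_at(g, 3 * m) in stops:
                    out.append((g, 3 * m, "stop"))
            for k in _scrub_offsets(upstream_spacer(i)):
                if codon_at(g, 3 * k) in _ALLOWED_STARTS:
                    out.append((g, 3 * k, "decoy_start"))
        return out

    current = violations()
    guard = len(current) + 60
    while current and guard > 0:
        guard -= 1
        g, u, _kind = current[0]
        fixed_it = False
        for off in (1, 0, 2):  # middle base first: clears both stop and ATN/NTG
            m = (_oriented_major(g, u + off, L) - 1) % L
            if b.fixed[m]:
                continue
            old = b.seq[m]
            for base in "CGAT":
                if base == old:
                    continue
                b.seq[m] = base
                new = violations()
                if len(new) < len(current):
                    current = new
                    fixed_it = True
                    break
                b.seq[m] = old
            if fixed_it:
                break
        if not fixed_it:
            raise RecipeError(
                f"{g.name}: cannot repair constraint at oriented offset {u}"
            )
    if current:
        raise RecipeError("constraint repair did not converge")

    if any(s is None for s in b.seq):
        raise RecipeError("internal error: unfilled genome positions")
    genome = CircularGenome(seq="".join(b.seq), id=f"synthetic_mitogenome_seed{recipe.seed}")
    return GenomeBundle(genome=genome, table=table, trna_structures=trna_structures,
                        recipe=recipe)


def perturb_to_draft(
    bundle: GenomeBundle, seed: int = 0, max_shift_codons: int = 4
) -> AnnotationTable:
    """A draft table with PCG 5' starts displaced into the gene body.

    Emulates an ORF-finder draft: reading frames are preserved, tRNA
    and rRNA boundaries are untouched, and each PCG's start is shifted
    0-``max_shift_codons`` codons downstream (never past the body).
    """
    rng = np.random.default_rng(seed)
    L = bundle.table.genome_length
    genes = []
    for g in bundle.table.genes:
        g = replace(g)
        if g.klass is GeneClass.PCG:
            glen = g.length(L)
            max_shift = min(max_shift_codons, max((glen - 9) // 3 - 1, 0))
            shift = 3 * int(rng.integers(0, max_shift + 1))
            if g.strand == "J":
                g.start = (g.start - 1 + shift) % L + 1
            else:
                g.end = (g.end - 1 - shift) % L + 1
        genes.append(g)
    return AnnotationTable(genes=genes, genome_length=L)


# ---------------------------------------------------------------------------
# sequence simulation under GTR+I+Gamma
# ---------------------------------------------------------------------------

def simulate_alignment(
    tree: Tree,
    params: GTRParams,
    n_sites: int,
    seed: int,
) -> tuple[dict[str, str], np.ndarray]:
    """Evolve sequences along a tree; returns (taxon->row, site categories).

    Root states are drawn from the stationary frequencies; each site is
    assigned a rate category of the +I+Γ mixture (category 0 is the
    invariant class when p_inv > 0) and evolved with the per-category
    transition matrices down every branch.  Deterministic per seed.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    model = GTRModel(params)
    ncat = len(model.category_rates)
    cats = rng.choice(ncat, p=model.category_weights, size=n_sites)
    states = {id(tree.root): rng.choice(4, p=model.pi, size=n_sites)}
    rows: dict[str, str] = {}
    for node in reversed(tree.postorder()):  # preorder
        if node is tree.root:
            if node.is_leaf:
                raise ValueError("tree must have internal structure")
            continue
        parent_state = states[id(node.parent)]
        P = model.transition_matrices(node.length)  # (ncat, 4, 4)
        cum = P.cumsum(axis=2)
        probs = cum[cats, parent_state, :]
        u = rng.random(n_sites)
        child_state = (u[:, None] > probs).sum(axis=1)
        states[id(node)] = child_state
        if node.is_leaf:
            rows[node.name] = "".join(BASES[s] for s in child_state)
    return rows, cats


def simulate_gene_alignments(
    tree: Tree,
    params: GTRParams,
    seed: int,
    gene_widths: Optional[dict[str, int]] = None,
) -> list[GeneAlignment]:
    """Per-gene alignments shaped like the 13 PCG + 2 rRNA dataset."""
    if gene_widths is None:
        ref = load_reference_annotation()
        L = ref.genome_length
        gene_widths = {}
        for g in ref.of_class(GeneClass.PCG):
            gene_widths[g.name] = (g.length(L) // 3) * 3
        for g in ref.of_class(GeneClass.RRNA):
            gene_widths[g.name] = g.length(L)
    ss = np.random.SeedSequence(seed)
    out = []
    for child, (gene, width) in zip(ss.spawn(len(gene_widths)), gene_widths.items()):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rows, _ = simulate_alignment(tree, params, width, sub_seed)
        kind = "rRNA" if gene.startswith("rrn") else "codon"
        taxa = sorted(rows)
        out.append(GeneAlignment(gene=gene, taxa=taxa, rows=[rows[t] for t in taxa],
                                 kind=kind))
    return out


def random_topology(
    taxa: list[str],
    seed: int,
    internal_range: tuple[float, float] = (0.03, 0.12),
    terminal_range: tuple[float, float] = (0.05, 0.30),
) -> Tree:
    """Random unrooted binary tree by sequential random joins."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    nodes = [Node(name=t, length=float(rng.uniform(*terminal_range))) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = Node(length=float(rng.uniform(*internal_range)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


def ensifera_demo_tree(
    internal: float = 0.06, terminal: float = 0.15, outgroup: bool = True
) -> Tree:
    """The four-superfamily topology with moderate branch lengths.

    (Grylloidea,(Tettigonioidea,(Hagloidea,Rhaphidophoroidea))), with a
    caeliferan outgroup by default.
    """
    ing = (
        f"(Grylloidea:{terminal},(Tettigonioidea:{terminal},"
        f"(Hagloidea:{terminal},Rhaphidophoroidea:{terminal}):{internal}):{internal})"
    )
    if outgroup:
        newick = f"({ing}:{internal},Caelifera_1:{terminal},Caelifera_2:{terminal});"
    else:
        newick = ing + ";"
    return Tree.from_newick(newick)
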