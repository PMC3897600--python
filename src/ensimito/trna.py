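"""tRNA cloverleaf secondary structure by template-constrained search.

A mitochondrial tRNA gene (63-70 bp here) folds into the canonical
cloverleaf: an acceptor stem (7 bp), DHU arm, anticodon arm (5 bp stem
plus 7-nt loop with the anticodon centered), and a TψC arm, joined by
short connectors and a variable loop.  Mito tRNAs deviate freely from
the canon — serine AGN tRNAs classically show a one-base-pair "mini"
DHU arm, lengthened anticodon stems with bulges, and extended T stems.

Folding here is *not* thermodynamic: the sequence is assigned to the
arm template by exhaustively enumerating admissible arm placements
within configurable bounds and maximizing the number of paired
positions that are Watson-Crick or G-U wobble.  This makes the fold
deterministic, auditable, and directly comparable with hand-curated
structures.  T and U are synonyms throughout (DNA-encoded genes, RNA
structure semantics).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PairClass",
    "ArmBounds",
    "FoldConfig",
    "CloverleafStructure",
    "classify_pair",
    "fold_cloverleaf",
    "pairing_census",
    "flag_atypical",
    "dot_bracket",
    "ARM_NAMES",
]

ARM_NAMES = ("acceptor", "DHU", "anticodon", "TpsiC")

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


class PairClass(str, enum.Enum):
    WC = "WC"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


def _norm(base: str) -> str:
    b = base.upper().replace("U", "T")
    if b not in "ACGT" or len(base) != 1:
        raise ValueError(f"not a nucleotide base: {base!r}")
    return b


def classify_pair(b1: str, b2: str) -> PairClass:
    """Watson-Crick / G-U wobble / mismatch classification (symmetric)."""
    pair = (_norm(b1), _norm(b2))
    if pair in _WC:
        return PairClass.WC
    if pair in _WOBBLE:
        return PairClass.WOBBLE
    return PairClass.MISMATCH


@dataclass(frozen=True)
class ArmBounds:
    """Inclusive stem-length bounds per arm, in base pairs."""

    acceptor: tuple[int, int] = (6, 7)
    dhu: tuple[int, int] = (0, 4)
    anticodon: tuple[int, int] = (4, 9)
    tpsic: tuple[int, int] = (3, 6)


@dataclass(frozen=True)
class FoldConfig:
    arms: ArmBounds = ArmBounds()
    dhu_loop: tuple[int, int] = (3, 9)
    t_loop: tuple[int, int] = (3, 9)
    anticodon_loop: tuple[int, int] = (3, 9)  # odd sizes only (centered triplet)
    connector1: tuple[int, int] = (0, 3)
    connector2: tuple[int, int] = (0, 2)
    variable_loop: tuple[int, int] = (0, 9)
    #: allow one bulged nucleotide mid-5'-strand in anticodon stems >= this
    bulge_min_stem: int = 8


@dataclass
class CloverleafStructure:
    """A cloverleaf fold: arm layout plus explicit paired index pairs.

    ``arms`` maps arm name to a ladder of (i, j) 0-based sequence
    indices; ``loops`` maps loop name to the unpaired index run;
    ``bulges`` are stem positions excluded from pairing.
    """

    length: int
    stem_lengths: dict[str, int]
    arms: dict[str, list[tuple[int, int]]]
    loops: dict[str, list[int]]
    bulges: list[int]
    connector_lengths: tuple[int, int]
    variable_loop_length: int
    anticodon_triplet: Optional[str] = None
    anticodon_indices: Optional[tuple[int, int, int]] = None

    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for arm in ARM_NAMES for p in self.arms[arm]]


def _build_structure(seq_len: int, layout: tuple, anticodon: Optional[str]) -> CloverleafStructure:
    a, c1, d, dl, c2, c, bulge, acl, v, t, tl = layout
    arms: dict[str, list[tuple[int, int]]] = {n: [] for n in ARM_NAMES}
    loops: dict[str, list[int]] = {}
    bulges: list[int] = []
    arms["acceptor"] = [(i, seq_len - 1 - i) for i in range(a)]
    pos = a + c1
    if d > 0:
        arms["DHU"] = [(pos + i, pos + 2 * d + dl - 1 - i) for i in range(d)]
        loops["DHU"] = list(range(pos + d, pos + d + dl))
        pos += 2 * d + dl
    else:
        loops["DHU"] = []
    pos += c2
    five = list(range(pos, pos + c + (1 if bulge else 0)))
    if bulge:
        mid = c // 2
        bulges.append(five.pop(mid))
    loop_start = pos + c + (1 if bulge else 0)
    arms["anticodon"] = [(five[i], loop_start + acl + c - 1 - i) for i in range(c)]
    loops["anticodon"] = list(range(loop_start, loop_start + acl))
    ac_idx = None
    if acl >= 3:
        off = (acl - 3) // 2
        ac_idx = (loop_start + off, loop_start + off + 1, loop_start + off + 2)
    pos = loop_start + acl + c
    loops["variable"] = list(range(pos, pos + v))
    pos += v
    arms["TpsiC"] = [(pos + i, pos + 2 * t + tl - 1 - i) for i in range(t)]
    loops["TpsiC"] = list(range(pos + t, pos + t + tl))
    return CloverleafStructure(
        length=seq_len,
        stem_lengths={"acceptor": a, "DHU": d, "anticodon": c, "TpsiC": t},
        arms=arms,
        loops=loops,
        bulges=bulges,
        connector_lengths=(c1, c2),
        variable_loop_length=v,
        anticodon_triplet=anticodon,
        anticodon_indices=ac_idx,
    )


def _stem_score(seq: str, pairs: list[tuple[int, int]]) -> tuple[int, int]:
    """(paired = WC+wobble, WC) over a ladder of index pairs."""
    good = wc = 0
    for i, j in pairs:
        k = classify_pair(seq[i], seq[j])
        if k is PairClass.WC:
            wc += 1
            good += 1
        elif k is PairClass.WOBBLE:
            good += 1
    return good, wc


_CANON = {"acceptor": 7, "DHU": 4, "anticodon": 5, "TpsiC": 5}


def fold_cloverleaf(
    seq: str,
    anticodon: Optional[str] = None,
    config: FoldConfig = FoldConfig(),
) -> Optional[CloverleafStructure]:
    """Best-scoring cloverleaf assignment, or None when no placement fits.

    The search decomposes over the interface coordinates (acceptor
    length, anticodon-arm start/end) so each arm's placements are
    scored once; the combination maximizing WC+wobble pairs is exact.
    Ties prefer more WC pairs, then fewer mismatched rungs, then no
    bulge, then canonical arm/connector/loop sizes, then the smallest
    layout tuple.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    if not 45 <= L <= 120:
        raise ValueError(f"sequence length {L} outside plausible tRNA range")
    if anticodon is not None:
        anticodon = anticodon.upper().replace("U", "T")
    cfg = config
    b = cfg.arms

    def canon_pen(arm: str, n: int) -> int:
        return abs(n - _CANON[arm])

    # T arm + variable loop: for each acceptor length, best T placement
    # reachable from a given anticodon-arm end index.
    t_by_send: dict[int, dict[int, tuple]] = {}
    for a in range(b.acceptor[0], b.acceptor[1] + 1):
        table: dict[int, tuple] = {}
        for t in range(b.tpsic[0], b.tpsic[1] + 1):
            for tl in range(cfg.t_loop[0], cfg.t_loop[1] + 1):
                s = L - a - 2 * t - tl
                if s < 0:
                    continue
                pairs = [(s + i, s + 2 * t + tl - 1 - i) for i in range(t)]
                good, wc = _stem_score(seq, pairs)
                cand = (good, wc, -(t - good), -canon_pen("TpsiC", t),
                        (-t, -tl), (t, tl, s))
                if s not in table or cand > table[s]:
                    table[s] = cand
        t_by_send[a] = table

    # left block: acceptor + connector1 + DHU + connector2 -> anticodon start
    left_by_ap: dict[tuple[int, int], tuple] = {}
    for a in range(b.acceptor[0], b.acceptor[1] + 1):
        acc_pairs = [(i, L - 1 - i) for i in range(a)]
        acc_good, acc_wc = _stem_score(seq, acc_pairs)
        for c1 in range(cfg.connector1[0], cfg.connector1[1] + 1):
            base = a + c1
            dhu_opts = [(0, 0)] if b.dhu[0] == 0 else []
            for d in range(max(1, b.dhu[0]), b.dhu[1] + 1):
                for dl in range(cfg.dhu_loop[0], cfg.dhu_loop[1] + 1):
                    dhu_opts.append((d, dl))
            for d, dl in dhu_opts:
                span = 2 * d + dl if d > 0 else 0
                if d > 0:
                    pairs = [(base + i, base + span - 1 - i) for i in range(d)]
                    good, wc = _stem_score(seq, pairs)
                else:
                    good = wc = 0
                for c2 in range(cfg.connector2[0], cfg.connector2[1] + 1):
                    p = base + span + c2
                    pen = (canon_pen("acceptor", a) + canon_pen("DHU", d)
                           + abs(c1 - 2) + abs(c2 - 1))
                    cand = (
                        acc_good + good,
                        acc_wc + wc,
                        -(a + d - acc_good - good),
                        -pen,
                        (-a, -c1, -d, -dl, -c2),
                        (a, c1, d, dl, c2),
                    )
                    key = (a, p)
                    if key not in left_by_ap or cand > left_by_ap[key]:
                        left_by_ap[key] = cand

    best: Optional[tuple] = None
    acl_values = [n for n in range(cfg.anticodon_loop[0], cfg.anticodon_loop[1] + 1) if n % 2 == 1]
    for (a, p), left in left_by_ap.items():
        for c in range(b.anticodon[0], b.anticodon[1] + 1):
            for bulge in ((False, True) if c >= cfg.bulge_min_stem else (False,)):
                extra = 1 if bulge else 0
                for acl in acl_values:
                    loop_start = p + c + extra
                    triplet_off = (acl - 3) // 2
                    if anticodon is not None:
                        i0 = loop_start + triplet_off
                        if seq[i0 : i0 + 3] != anticodon:
                            continue
                    ac_end = loop_start + acl + c  # exclusive
                    if ac_end > L - 1:
                        continue
                    five = list(range(p, p + c + extra))
                    if bulge:
                        five.pop(c // 2)
                    pairs = [(five[i], loop_start + acl + c - 1 - i) for i in range(c)]
                    good, wc = _stem_score(seq, pairs)
                    tmap = t_by_send[a]
                    for v in range(cfg.variable_loop[0], cfg.variable_loop[1] + 1):
                        s = ac_end + v
                        tcand = tmap.get(s)
                        if tcand is None:
                            continue
                        t, tl, _s = tcand[5]
                        layout = (a, left[5][1], left[5][2], left[5][3], left[5][4],
                                  c, bulge, acl, v, t, tl)
                        leftmost_key = tuple(-int(x) for x in layout)
                        total_good = left[0] + good + tcand[0]
                        n_pairs = a + left[5][2] + c + tcand[5][0]
                        cand = (
                            total_good,
                            left[1] + wc + tcand[1],
                            -(n_pairs - total_good),  # fewest mismatched rungs
                            -(1 if bulge else 0),
                            left[3] + tcand[3] - canon_pen("anticodon", c)
                            - abs(v - 4),
                            leftmost_key,
                            layout,
                        )
                        if best is None or cand[:6] > best[:6]:
                            best = cand
    if best is None:
        return None
    return _build_structure(L, best[6], anticodon)


def pairing_census(structure: CloverleafStructure, seq: str) -> dict[str, dict[str, int]]:
    """Counts of WC / wobble / mismatch pairs per arm, plus totals."""
    seq = seq.upper().replace("U", "T")
    out: dict[str, dict[str, int]] = {}
    totals = {k.value: 0 for k in PairClass}
    for arm in ARM_NAMES:
        counts = {k.value: 0 for k in PairClass}
        for i, j in structure.arms[arm]:
            counts[classify_pair(seq[i], seq[j]).value] += 1
        out[arm] = counts
        for k, nv in counts.items():
            totals[k] += nv
    out["total"] = totals
    return out


@dataclass(frozen=True)
class AtypicalLimits:
    """Canonical bounds; a structure outside them is flagged."""

    max_anticodon_stem: int = 5
    max_t_stem: int = 5
    mini_dhu_max: int = 1
    min_acceptor: int = 6


def flag_atypical(
    structure: CloverleafStructure, limits: AtypicalLimits = AtypicalLimits()
) -> set[str]:
    flags: set[str] = set()
    sl = structure.stem_lengths
    if sl["anticodon"] > limits.max_anticodon_stem:
        flags.add("lengthened_anticodon_stem")
    if sl["TpsiC"] > limits.max_t_stem:
        flags.add("extended_T_stem")
    if sl["DHU"] <= limits.mini_dhu_max:
        flags.add("mini_DHU_arm")
    if structure.connector_lengths == (0, 0):
        flags.add("no_connector")
    if structure.bulges:
        flags.add("bulged_stem")
    return flags


def dot_bracket(structure: CloverleafStructure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.all_pairs():
        chars[i], chars[j] = "(", ")"
    return "".join(chars)
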