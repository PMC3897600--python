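"""Cloverleaf folding: pair classes, template search, atypical flags."""

import itertools

import pytest

from ensimito.synthetic import TrnaTemplate, generate_trna, random_defects, template_for_length
from ensimito.trna import (
    ArmBounds,
    FoldConfig,
    PairClass,
    classify_pair,
    dot_bracket,
    flag_atypical,
    fold_cloverleaf,
    pairing_census,
)


class TestClassifyPair:
    @pytest.mark.parametrize(
        "b1,b2,expect",
        [
            ("G", "C", PairClass.WC),
            ("A", "T", PairClass.WC),
            ("A", "U", PairClass.WC),   # U/T synonyms
            ("G", "U", PairClass.WOBBLE),
            ("T", "G", PairClass.WOBBLE),
            ("U", "U", PairClass.MISMATCH),
            ("A", "C", PairClass.MISMATCH),
            ("G", "A", PairClass.MISMATCH),
        ],
    )
    def test_table(self, b1, b2, expect):
        assert classify_pair(b1, b2) is expect
        assert classify_pair(b2, b1) is expect  # symmetric

    def test_non_base_raises(self):
        with pytest.raises(ValueError):
            classify_pair("Z", "A")


class TestFoldRecovery:
    def test_perfect_template_recovered(self):
        seq, truth = generate_trna(template_for_length(66), seed=11)
        fold = fold_cloverleaf(seq, anticodon=truth.anticodon_triplet)
        assert fold is not None
        assert fold.all_pairs() == truth.all_pairs()
        census = pairing_census(fold, seq)["total"]
        assert census["wobble"] == 0 and census["mismatch"] == 0

    @pytest.mark.parametrize("defect", [
        ("acceptor", 2, "mismatch"),
        ("anticodon", 2, "wobble"),
        ("TpsiC", 2, "mismatch"),
        ("DHU", 1, "wobble"),
    ])
    def test_single_planted_defect_located(self, defect):
        arm, idx, kind = defect
        seq, truth = generate_trna(template_for_length(68), defects=[defect], seed=5)
        fold = fold_cloverleaf(seq, anticodon=truth.anticodon_triplet)
        census = pairing_census(fold, seq)
        key = "wobble" if kind == "wobble" else "mismatch"
        assert census[arm][key] == 1
        assert census["total"][key] == 1

    def test_determinism(self):
        seq, truth = generate_trna(template_for_length(65), seed=3)
        f1 = fold_cloverleaf(seq, anticodon=truth.anticodon_triplet)
        f2 = fold_cloverleaf(seq, anticodon=truth.anticodon_triplet)
        assert f1.all_pairs() == f2.all_pairs()
        assert f1.stem_lengths == f2.stem_lengths

    def test_census_additivity(self):
        totals = {"WC": 0, "wobble": 0, "mismatch": 0}
        grand_seqs = []
        for seed in range(6):
            seq, truth = generate_trna(template_for_length(64 + seed), seed=seed)
            c = pairing_census(truth, seq)["total"]
            for k in totals:
                totals[k] += c[k]
            grand_seqs.append((seq, truth))
        again = {"WC": 0, "wobble": 0, "mismatch": 0}
        for seq, truth in grand_seqs:
            for k in again:
                again[k] += pairing_census(truth, seq)["total"][k]
        assert totals == again


def _exhaustive_best_good(seq, anticodon, cfg=FoldConfig()):
    """Brute-force max WC+wobble over all admissible layouts (slow)."""
    from ensimito.trna import _build_structure, _stem_score

    L = len(seq)
    best = -1
    b = cfg.arms
    acl_values = [n for n in range(cfg.anticodon_loop[0], cfg.anticodon_loop[1] + 1)
                  if n % 2 == 1]
    dhu_opts = [(0, 0)] + [(d, dl) for d in range(max(1, b.dhu[0]), b.dhu[1] + 1)
                           for dl in range(cfg.dhu_loop[0], cfg.dhu_loop[1] + 1)]
    for a in range(b.acceptor[0], b.acceptor[1] + 1):
        for c1 in range(cfg.connector1[0], cfg.connector1[1] + 1):
            for d, dl in dhu_opts:
                for c2 in range(cfg.connector2[0], cfg.connector2[1] + 1):
                    for c in range(b.anticodon[0], b.anticodon[1] + 1):
                        for bulge in ((False, True) if c >= cfg.bulge_min_stem else (False,)):
                            for acl in acl_values:
                                for v in range(cfg.variable_loop[0], cfg.variable_loop[1] + 1):
                                    for t in range(b.tpsic[0], b.tpsic[1] + 1):
                                        used = (2 * a + c1 + (2 * d + dl if d else 0)
                                                + c2 + 2 * c + (1 if bulge else 0)
                                                + acl + v + 2 * t)
                                        tl = L - used
                                        if not cfg.t_loop[0] <= tl <= cfg.t_loop[1]:
                                            continue
                                        layout = (a, c1, d, dl, c2, c, bulge, acl, v, t, tl)
                                        s = _build_structure(L, layout, None)
                                        if anticodon is not None:
                                            i0 = s.anticodon_indices[0]
                                            if seq[i0:i0 + 3] != anticodon:
                                                continue
                                        good, _ = _stem_score(seq, s.all_pairs())
                                        best = max(best, good)
    return best


class TestScoreOptimality:
    def test_matches_exhaustive_enumeration(self):
        """The decomposed search attains the brute-force maximum score."""
        for seed in (0, 1):
            seq, truth = generate_trna(template_for_length(63), seed=seed, verify=False)
            fold = fold_cloverleaf(seq, anticodon=truth.anticodon_triplet)
            got = pairing_census(fold, seq)["total"]
            best = _exhaustive_best_good(seq, truth.anticodon_triplet)
            assert got["WC"] + got["wobble"] == best


class TestAtypicalFlags:
    def test_canonical_is_clean(self):
        seq, truth = generate_trna(template_for_length(66), seed=1)
        assert flag_atypical(truth) == set()

    def test_serine_agn_style_structure(self):
        template = TrnaTemplate(acceptor=7, connector1=0, dhu=1, dhu_loop=5,
                                connector2=0, anticodon_stem=9, bulge=True,
                                anticodon_loop=7, variable=0, t_stem=6, t_loop=4,
                                anticodon="GCT")
        seq, truth = generate_trna(template, seed=2)
        flags = flag_atypical(truth)
        assert {"mini_DHU_arm", "lengthened_anticodon_stem", "extended_T_stem",
                "no_connector", "bulged_stem"} <= flags
        fold = fold_cloverleaf(seq, anticodon="GCT")
        assert {"mini_DHU_arm", "lengthened_anticodon_stem",
                "extended_T_stem"} <= flag_atypical(fold)

    def test_extended_t_stem_alone(self):
        template = TrnaTemplate(t_stem=6, t_loop=3, dhu_loop=4)
        seq, truth = generate_trna(template, seed=4)
        assert flag_atypical(truth) == {"extended_T_stem"}


class TestDotBracket:
    def test_balanced_and_sized(self):
        seq, truth = generate_trna(template_for_length(70), seed=9)
        db = dot_bracket(truth)
        assert len(db) == len(seq)
        assert db.count("(") == db.count(")") == len(truth.all_pairs())


class TestFoldInputChecks:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold_cloverleaf("ACGT" * 5)
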