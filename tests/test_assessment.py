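"""Confusion matrices, ROC/PR curves and error decomposition."""

import random

import numpy as np
import pytest

from grnassess import (
    Digraph,
    RankedEdgeList,
    build_confusion,
    common_false_negatives,
    curves_and_auc,
    ensemble_bounds,
    fraction_noninferable_errors,
    transitive_closure,
)
from grnassess.errors import (
    DegenerateGoldError,
    DuplicateEdgeError,
    MissingBoundsError,
    SelfLoopError,
    ShortRankingError,
    UniverseMismatchError,
)

from conftest import ranking_from_edges, random_digraph


class TestRankedEdgeList:
    def test_rejects_duplicates(self):
        with pytest.raises(DuplicateEdgeError):
            RankedEdgeList((("A", "B", 0.9), ("A", "B", 0.8)))

    def test_rejects_self_loops(self):
        with pytest.raises(SelfLoopError):
            RankedEdgeList((("A", "A", 0.9),))

    def test_rejects_increasing_confidence(self):
        with pytest.raises(ValueError):
            RankedEdgeList((("A", "B", 0.1), ("B", "C", 0.9),))

    def test_top_prefix_and_short_error(self):
        r = ranking_from_edges([("A", "B"), ("B", "C")])
        assert r.top(1) == {("A", "B")}
        with pytest.raises(ShortRankingError):
            r.top(3)


class TestBuildConfusion:
    def test_cascade_example_both_modes(self, cascade):
        b = ensemble_bounds(cascade)
        pred = {("A", "B"), ("A", "C")}
        classic = build_confusion(pred, cascade, mode="classic")
        assert (classic.tp, classic.fp, classic.fn, classic.tn) == (1, 1, 1, 3)
        inf = build_confusion(pred, cascade, b, mode="inferable")
        assert (inf.tp, inf.fp, inf.fn, inf.tn) == (1, 0, 1, 3)

    def test_empty_prediction_inferable(self, cascade):
        b = ensemble_bounds(cascade)
        c = build_confusion(set(), cascade, b, mode="inferable")
        universe = set(cascade.universe())
        assert (c.tp, c.fp) == (0, 0)
        assert c.tn == len(universe - b.upper)
        assert c.fn == len(b.lower)

    def test_full_universe_prediction_inferable(self, cascade):
        b = ensemble_bounds(cascade)
        universe = set(cascade.universe())
        c = build_confusion(universe, cascade, b, mode="inferable")
        assert (c.tp, c.fp, c.tn, c.fn) == (
            len(b.lower), len(universe - b.upper), 0, 0
        )

    def test_conservation_both_modes(self, cascade):
        b = ensemble_bounds(cascade)
        rng = random.Random(1)
        universe = sorted(cascade.universe())
        for _ in range(20):
            pred = {e for e in universe if rng.random() < 0.5}
            classic = build_confusion(pred, cascade, mode="classic")
            assert classic.total == cascade.universe_size()
            inf = build_confusion(pred, cascade, b, mode="inferable")
            assert inf.total == cascade.universe_size() - len(b.non_inferable)

    def test_missing_bounds(self, cascade):
        with pytest.raises(MissingBoundsError):
            build_confusion(set(), cascade, mode="inferable")

    def test_universe_mismatch(self, cascade):
        with pytest.raises(UniverseMismatchError):
            build_confusion({("A", "Z")}, cascade, mode="classic")


class TestCurves:
    def test_perfect_ranking_scores_one_in_both_modes(self, cascade):
        b = ensemble_bounds(cascade)
        r = ranking_from_edges(sorted(cascade.edges))
        for mode in ("classic", "inferable"):
            res = curves_and_auc(r, cascade, b, mode=mode)
            assert res.auroc == 1.0
            assert res.aupr == 1.0

    def test_closure_ranking_forgiven_only_in_inferable_mode(self, cascade):
        b = ensemble_bounds(cascade)
        closure = transitive_closure(cascade)
        rng = random.Random(0)
        edges = sorted(closure.edges)
        for _ in range(5):
            rng.shuffle(edges)
            r = ranking_from_edges(list(edges))
            res = curves_and_auc(r, cascade, b, mode="inferable")
            assert res.auroc == 1.0 and res.aupr == 1.0
        # Classic mode charges the shortcut as an FP: with A->C ranked first
        # precision suffers before recall completes, so AUPR drops below 1.
        r = ranking_from_edges([("A", "C"), ("A", "B"), ("B", "C")])
        res_c = curves_and_auc(r, cascade, b, mode="classic")
        assert res_c.aupr < 1.0

    def test_hand_stepped_full_ranking(self, cascade):
        # Inferable mode, gold A->B,B->C: P'={A->B,B->C}, N'={B->A,C->A,C->B},
        # A->C non-inferable.  Stepping the confusion table by hand over all
        # six prefixes of [B->A, A->B, A->C, B->C, C->A, C->B] gives
        # AUROC = 2/3 and AUPR = 5/12 (trapezoidal).
        b = ensemble_bounds(cascade)
        order = [("B", "A"), ("A", "B"), ("A", "C"), ("B", "C"), ("C", "A"), ("C", "B")]
        res = curves_and_auc(ranking_from_edges(order), cascade, b, mode="inferable")
        assert res.auroc == pytest.approx(2 / 3, abs=1e-12)
        assert res.aupr == pytest.approx(5 / 12, abs=1e-12)

        # All-shortcut-first ordering: the non-inferable edge costs nothing.
        order2 = [("A", "C"), ("A", "B"), ("B", "C"), ("B", "A"), ("C", "A"), ("C", "B")]
        res2 = curves_and_auc(ranking_from_edges(order2), cascade, b, mode="inferable")
        assert res2.auroc == 1.0 and res2.aupr == 1.0

    def test_matches_independent_prefix_enumeration(self):
        # Cross-check full-list curves against a from-scratch set-arithmetic
        # sweep, on random graphs and rankings, in both modes.
        rng = random.Random(9)
        checked = 0
        while checked < 15:
            g = random_digraph(5, rng, p=0.35)
            b = ensemble_bounds(g)
            universe = sorted(g.universe())
            rng.shuffle(universe)
            ranking = ranking_from_edges(list(universe))
            for mode in ("classic", "inferable"):
                pos = set(b.lower) if mode == "inferable" else set(g.edges)
                neg = (
                    set(g.universe()) - b.upper
                    if mode == "inferable"
                    else set(g.universe()) - g.edges
                )
                if not pos or not neg:
                    continue
                roc = [(0.0, 0.0)]
                pr = []
                for k in range(1, len(universe) + 1):
                    pred = set(universe[:k])
                    tp, fp = len(pred & pos), len(pred & neg)
                    roc.append((fp / len(neg), tp / len(pos)))
                    if tp + fp:
                        pr.append((tp / len(pos), tp / (tp + fp)))
                pr.insert(0, (0.0, pr[0][1]))
                exp_auroc = np.trapezoid([p[1] for p in roc], [p[0] for p in roc])
                exp_aupr = np.trapezoid([p[1] for p in pr], [p[0] for p in pr])
                res = curves_and_auc(ranking, g, b, mode=mode)
                assert res.auroc == pytest.approx(exp_auroc, abs=1e-12)
                assert res.aupr == pytest.approx(exp_aupr, abs=1e-12)
                checked += 1

    def test_expected_tail_completes_truncated_gold_only_list(self, cascade):
        b = ensemble_bounds(cascade)
        r = ranking_from_edges(sorted(cascade.edges))  # only 2 of 6 edges
        for mode in ("classic", "inferable"):
            res = curves_and_auc(r, cascade, b, mode=mode)
            assert res.auroc == 1.0 and res.aupr == 1.0
            assert res.roc.points[-1] == (1.0, 1.0)

    def test_strict_policy_rejects_truncation(self, cascade):
        r = ranking_from_edges(sorted(cascade.edges))
        with pytest.raises(ShortRankingError):
            curves_and_auc(r, cascade, None, mode="classic", tail="strict")

    def test_noninferable_positions_are_irrelevant(self):
        # Permuting which Ē edges occupy the Ē-occupied slots changes nothing.
        g = Digraph.from_edges(
            [("A", "B"), ("B", "C"), ("C", "D")], nodes="ABCD"
        )
        b = ensemble_bounds(g)
        assert len(b.non_inferable) == 3
        base = [("A", "B"), None, ("B", "C"), None, ("C", "D"), None]
        rest = sorted(set(g.universe()) - b.upper)
        rng = random.Random(2)
        results = set()
        for _ in range(6):
            noninf = sorted(b.non_inferable)
            rng.shuffle(noninf)
            order = [noninf.pop() if e is None else e for e in base] + rest
            res = curves_and_auc(ranking_from_edges(order), g, b, mode="inferable")
            results.add((res.auroc, res.aupr))
        assert len(results) == 1

    def test_classic_equals_inferable_when_nothing_noninferable(self):
        # Two 2-cycles: Ē is empty, so the redefinition changes nothing.
        g = Digraph.from_edges(
            [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C")], nodes="ABCD"
        )
        b = ensemble_bounds(g)
        assert not b.non_inferable
        rng = random.Random(4)
        universe = sorted(g.universe())
        for _ in range(10):
            rng.shuffle(universe)
            r = ranking_from_edges(list(universe))
            res_c = curves_and_auc(r, g, b, mode="classic")
            res_i = curves_and_auc(r, g, b, mode="inferable")
            assert res_c.auroc == res_i.auroc
            assert res_c.aupr == res_i.aupr

    def test_reversed_perfect_ranking_has_zero_auroc(self, cascade):
        b = ensemble_bounds(cascade)
        universe = sorted(cascade.universe())
        order = [e for e in universe if e not in cascade.edges] + sorted(cascade.edges)
        r = ranking_from_edges(order)
        assert curves_and_auc(r, cascade, b, mode="classic").auroc == 0.0
        assert curves_and_auc(r, cascade, b, mode="inferable").auroc == 0.0

    def test_cell_monotonicity_along_prefixes(self, cascade):
        b = ensemble_bounds(cascade)
        universe = sorted(cascade.universe())
        random.Random(8).shuffle(universe)
        prev = None
        for k in range(1, len(universe) + 1):
            c = build_confusion(set(universe[:k]), cascade, b, mode="inferable")
            if prev is not None:
                assert c.tp >= prev.tp and c.fp >= prev.fp
                assert c.fn <= prev.fn and c.tn <= prev.tn
            prev = c

    def test_degenerate_gold_raises(self, three_cycle):
        b = ensemble_bounds(three_cycle)  # P' = 0
        r = ranking_from_edges(sorted(three_cycle.universe()))
        with pytest.raises(DegenerateGoldError):
            curves_and_auc(r, three_cycle, b, mode="inferable")


class TestErrorDecomposition:
    def test_fp_fraction_splits_noninferable(self, cascade):
        b = ensemble_bounds(cascade)
        r = ranking_from_edges(
            [("A", "C"), ("B", "A"), ("A", "B"), ("B", "C"), ("C", "A"), ("C", "B")]
        )
        frac_fp, frac_fn = fraction_noninferable_errors(r, cascade, b)
        assert frac_fp == pytest.approx(0.5)  # A->C in Ē, B->A outside G_U
        assert frac_fn == pytest.approx(0.0)  # both missed edges inferable

    def test_perfect_prediction_fractions_undefined(self, cascade):
        b = ensemble_bounds(cascade)
        r = ranking_from_edges(sorted(cascade.edges) + [("B", "A")])
        assert fraction_noninferable_errors(r, cascade, b) == (None, None)

    def test_ffl_missed_shortcut_is_noninferable(self, ffl):
        b = ensemble_bounds(ffl)
        r = ranking_from_edges(
            [("A", "B"), ("B", "C"), ("C", "A"), ("A", "C"), ("B", "A"), ("C", "B")]
        )
        frac_fp, frac_fn = fraction_noninferable_errors(r, ffl, b)
        assert frac_fp == pytest.approx(0.0)  # C->A is a genuine FP outside G_U
        assert frac_fn == pytest.approx(1.0)  # missed A->C lies in Ē

    def test_short_ranking_rejected(self, cascade):
        b = ensemble_bounds(cascade)
        with pytest.raises(ShortRankingError):
            fraction_noninferable_errors(
                ranking_from_edges([("A", "B")]), cascade, b
            )

    def test_common_false_negatives(self, cascade):
        b = ensemble_bounds(cascade)
        # Both submissions miss only B->C (an inferable edge).
        r1 = ranking_from_edges([("A", "B"), ("A", "C"), ("B", "C"), ("B", "A")])
        r2 = ranking_from_edges([("A", "B"), ("C", "B"), ("B", "C"), ("B", "A")])
        common, frac = common_false_negatives([r1, r2], cascade, b)
        assert common == frozenset({("B", "C")})
        assert frac == pytest.approx(0.0)

    def test_single_ranking_common_fn_is_own_fn_set(self, ffl):
        b = ensemble_bounds(ffl)
        r = ranking_from_edges(
            [("A", "B"), ("B", "C"), ("C", "A"), ("A", "C"), ("B", "A"), ("C", "B")]
        )
        common, frac = common_false_negatives([r], ffl, b)
        assert common == frozenset({("A", "C")})
        assert frac == pytest.approx(1.0)

    def test_no_common_fn_is_undefined(self, cascade):
        b = ensemble_bounds(cascade)
        r = ranking_from_edges(sorted(cascade.edges) + [("B", "A")])
        common, frac = common_false_negatives([r], cascade, b)
        assert common == frozenset() and frac is None


def test_classic_auroc_matches_sklearn():
    """Full-universe classic-mode AUROC agrees with scikit-learn's
    roc_auc_score on the same labels/confidences (distinct confidences, so
    tie conventions cannot differ)."""
    from sklearn.metrics import roc_auc_score

    rng = random.Random(13)
    checked = 0
    while checked < 10:
        g = random_digraph(6, rng, p=0.3)
        if not g.edges or len(g.edges) == g.universe_size():
            continue
        universe = sorted(g.universe())
        rng.shuffle(universe)
        ranking = ranking_from_edges(list(universe))
        res = curves_and_auc(ranking, g, None, mode="classic")
        labels = [1 if e in g.edges else 0 for e in universe]
        confs = [c for _, _, c in ranking.entries]
        assert res.auroc == pytest.approx(roc_auc_score(labels, confs), abs=1e-12)
        checked += 1
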