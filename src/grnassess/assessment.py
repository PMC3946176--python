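"""Confusion matrices and ROC/PR assessment of ranked edge predictions.

Two scoring modes are supported:

``classic``
    The standard benchmark confusion matrix: positives are the gold-standard
    edges, negatives everything else in the ``n(n-1)`` edge universe.

``inferable``
    The inferability-aware redefinition: positives are the ensemble lower
    bound ``G_L``, negatives are edges outside the upper bound ``G_U``, and
    the non-inferable edges ``Ē = G_U \\ G_L`` are excluded from every cell —
    a method is neither rewarded nor penalised for guessing edges that
    KO/KD data cannot decide.

Curves are built DREAM-style by sweeping prefixes of the ranked list, one
edge at a time, and integrating trapezoidally.  Lists shorter than the edge
universe are either completed with an expected-value tail (unlisted edges
treated as uniformly randomly ordered) or rejected, depending on the
truncation policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateGoldError,
    DuplicateEdgeError,
    MissingBoundsError,
    SelfLoopError,
    ShortRankingError,
    UniverseMismatchError,
)
from .graphs import Digraph, Edge, EnsembleBounds

Mode = Literal["classic", "inferable"]

__all__ = [
    "RankedEdgeList",
    "ConfusionCounts",
    "Curve",
    "CurveResult",
    "build_confusion",
    "curves_and_auc",
    "fraction_noninferable_errors",
    "common_false_negatives",
]


@dataclass(frozen=True)
class RankedEdgeList:
    """One submission for one network: candidate edges ordered by confidence.

    ``entries`` are ``(tail, head, confidence)`` triples with non-increasing
    confidence; ties keep their given order.  Duplicate edges and self-loops
    are rejected.
    """

    entries: tuple[tuple[str, str, float], ...]
    network_id: str = ""

    def __post_init__(self) -> None:
        seen: set[Edge] = set()
        prev = np.inf
        for tail, head, conf in self.entries:
            if tail == head:
                raise SelfLoopError(f"self-loop prediction {tail!r}")
            if (tail, head) in seen:
                raise DuplicateEdgeError(f"duplicate edge ({tail!r}, {head!r})")
            seen.add((tail, head))
            if conf > prev:
                raise ValueError("confidences must be non-increasing")
            prev = conf

    def __len__(self) -> int:
        return len(self.entries)

    def edges(self) -> list[Edge]:
        return [(t, h) for t, h, _ in self.entries]

    def top(self, k: int) -> set[Edge]:
        """Network structure from the first ``k`` entries."""
        if k > len(self.entries):
            raise ShortRankingError(
                f"ranking has {len(self.entries)} entries, {k} requested"
            )
        return {(t, h) for t, h, _ in self.entries[:k]}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: Mode = "classic"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Curve:
    """An ROC (x = FPR, y = TPR) or PR (x = recall, y = precision) curve."""

    points: tuple[tuple[float, float], ...]
    kind: Literal["roc", "pr"]

    @property
    def auc(self) -> float:
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return float(np.trapezoid(ys, xs))


class CurveResult(NamedTuple):
    roc: Curve
    pr: Curve
    auroc: float
    aupr: float


def _classes(
    gold: Digraph, bounds: EnsembleBounds | None, mode: Mode
) -> tuple[set[Edge], set[Edge]]:
    """Positive and negative edge classes for the requested mode."""
    universe = set(gold.universe())
    if mode == "classic":
        return set(gold.edges), universe - set(gold.edges)
    if bounds is None:
        raise MissingBoundsError("inferable mode requires ensemble bounds")
    return set(bounds.lower), universe - set(bounds.upper)


def build_confusion(
    pred_edges: Iterable[Edge],
    gold: Digraph,
    bounds: EnsembleBounds | None = None,
    mode: Mode = "classic",
) -> ConfusionCounts:
    """Confusion matrix of a predicted network structure against the gold
    standard.

    In ``inferable`` mode edges of ``Ē`` contribute to no cell, so the four
    cells sum to ``n(n-1) - |Ē|`` rather than ``n(n-1)``.
    """
    universe = set(gold.universe())
    pred = set(pred_edges)
    stray = pred - universe
    if stray:
        raise UniverseMismatchError(
            f"predicted edges outside the gold universe: {sorted(stray, key=repr)[:5]}"
        )
    pos, neg = _classes(gold, bounds, mode)
    return ConfusionCounts(
        tp=len(pred & pos),
        fp=len(pred & neg),
        tn=len(neg - pred),
        fn=len(pos - pred),
        mode=mode,
    )


def curves_and_auc(
    ranking: RankedEdgeList,
    gold: Digraph,
    bounds: EnsembleBounds | None = None,
    mode: Mode = "inferable",
    tail: Literal["expected", "strict"] = "expected",
) -> CurveResult:
    """ROC and PR curves (with AUCs) from a ranked edge list.

    The confusion matrix is evaluated at every prefix length ``k = 1..L``.
    Prefixes where precision is undefined (``TP + FP = 0``, possible in
    inferable mode when only non-inferable edges have been listed) contribute
    no PR point; the PR curve is anchored at recall 0 with the precision of
    the first defined prefix.

    If the list stops short of the edge universe, the ``expected`` tail
    policy appends the curve a method would trace on average if the unlisted
    edges were in uniformly random order; ``strict`` raises instead.

    Raises
    ------
    DegenerateGoldError
        If the positive or negative class is empty.
    ShortRankingError
        Under the ``strict`` policy, if any positive or negative edge is
        unlisted.
    """
    if not ranking.entries:
        raise ValueError("ranking is empty")
    universe = set(gold.universe())
    pos, neg = _classes(gold, bounds, mode)
    p_tot, n_tot = len(pos), len(neg)
    if p_tot == 0 or n_tot == 0:
        raise DegenerateGoldError(
            f"P'={p_tot}, N'={n_tot}: curves are undefined"
        )

    tp = fp = 0
    tps = [0]
    fps = [0]
    for tail_node, head, _ in ranking.entries:
        edge = (tail_node, head)
        if edge not in universe:
            raise UniverseMismatchError(
                f"predicted edge {edge!r} outside the gold universe"
            )
        if edge in pos:
            tp += 1
        elif edge in neg:
            fp += 1
        # non-inferable edges fall through: no cell changes
        tps.append(tp)
        fps.append(fp)

    p_rem, n_rem = p_tot - tp, n_tot - fp
    if p_rem or n_rem:
        if tail == "strict":
            raise ShortRankingError(
                "ranking does not cover the edge universe and policy is strict"
            )
        # Expected-value completion: each remaining step uncovers positives
        # at rate p_rem / (p_rem + n_rem).
        steps = p_rem + n_rem
        for mstep in range(1, steps + 1):
            tps.append(tp + mstep * p_rem / steps)
            fps.append(fp + mstep * n_rem / steps)

    roc_pts = [(f / n_tot, t / p_tot) for t, f in zip(tps, fps)]
    pr_pts: list[tuple[float, float]] = []
    for t, f in zip(tps[1:], fps[1:]):
        if t + f > 0:
            pr_pts.append((t / p_tot, t / (t + f)))
    if not pr_pts:  # every listed edge non-inferable and no tail
        raise DegenerateGoldError("precision undefined at every prefix")
    pr_pts.insert(0, (0.0, pr_pts[0][1]))

    roc = Curve(tuple(roc_pts), "roc")
    pr = Curve(tuple(pr_pts), "pr")
    return CurveResult(roc, pr, roc.auc, pr.auc)


def fraction_noninferable_errors(
    ranking: RankedEdgeList,
    gold: Digraph,
    bounds: EnsembleBounds,
) -> tuple[float | None, float | None]:
    """Fractions of classic-mode FP and FN edges that are non-inferable.

    The prediction is the top-``P`` prefix of the ranking, where ``P`` is the
    gold-standard edge count.  FPs and FNs are taken against the gold
    standard itself (classic definitions); each returned fraction is the
    share of those errors lying in ``Ē``, or ``None`` when there are no
    errors of that type (undefined, not zero).
    """
    pred = ranking.top(gold.m)
    gold_edges = set(gold.edges)
    fps = pred - gold_edges
    fns = gold_edges - pred
    frac_fp = len(fps & bounds.non_inferable) / len(fps) if fps else None
    frac_fn = len(fns & bounds.non_inferable) / len(fns) if fns else None
    return frac_fp, frac_fn


def common_false_negatives(
    rankings: Sequence[RankedEdgeList],
    gold: Digraph,
    bounds: EnsembleBounds,
) -> tuple[frozenset[Edge], float | None]:
    """Gold edges missed by *every* top-``P`` prediction, and the fraction of
    those common misses that are non-inferable (``None`` if there are none).

    Common false negatives persist in any consensus built from the
    submissions, so a high non-inferable fraction means no community strategy
    could recover them from the same data.
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    common = set(gold.edges)
    for ranking in rankings:
        common &= set(gold.edges) - ranking.top(gold.m)
    if not common:
        return frozenset(), None
    frac = len(common & bounds.non_inferable) / len(common)
    return frozenset(common), frac
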