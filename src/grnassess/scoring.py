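"""Empirical-null scoring and ranking of network submissions.

A submission's AUROC/AUPR alone says little: curve areas depend strongly on
network size and sparsity.  Following the DREAM convention, each gold
standard gets an empirical null built from many uniformly random edge
rankings; the score of a submission is

    score = AUC / AUC_alpha,

where ``AUC_alpha`` is the ``100*(1-alpha)``-th percentile of the null AUCs
(the AUC matching the prescribed acceptable p-value).  A score below 1 means
the submission is not distinguishable from random guessing at level alpha.
Per-metric scores are averaged over the ``M`` networks of a subchallenge and
the overall score is the mean of the AUROC and AUPR means.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .assessment import RankedEdgeList, curves_and_auc
from .errors import MismatchedTeamsError, ZeroNullError
from .graphs import Digraph, Edge, EnsembleBounds

Metric = Literal["auroc", "aupr"]

__all__ = [
    "NullDistribution",
    "SubmissionScore",
    "random_ranking",
    "null_distribution",
    "score_submission",
    "rank_teams",
    "spearman_rank",
    "derive_seed",
]


@dataclass(frozen=True)
class NullDistribution:
    """Empirical AUC distribution of random predictions for one gold
    standard and one metric."""

    metric: Metric
    aucs: tuple[float, ...]
    alpha: float
    auc_alpha: float
    seed: int
    n_reps: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))


@dataclass(frozen=True)
class SubmissionScore:
    """Per-network and aggregate scores of one team's submission set."""

    per_network: dict[str, tuple[float, float]]  # id -> (auroc_score, aupr_score)
    mean_auroc_score: float
    mean_aupr_score: float
    overall: float

    @property
    def M(self) -> int:
        return len(self.per_network)


def derive_seed(master: int, *labels: str) -> int:
    """Stable per-(network, metric, ...) child seed below 2**31.

    Keeps one RNG stream per labelled purpose, so adding networks or teams
    never perturbs existing null distributions.
    """
    tag = "\x1f".join(str(x) for x in labels).encode()
    return (master * 2654435761 + zlib.crc32(tag)) % (2**31 - 1)


def random_ranking(
    universe: Sequence[Edge], seed: int, network_id: str = "random"
) -> RankedEdgeList:
    """A uniformly random permutation of the whole edge universe, with
    strictly decreasing confidences.  Deterministic per seed."""
    if not universe:
        raise ValueError("edge universe is empty")
    edges = list(universe)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    L = len(edges)
    entries = tuple(
        (edges[j][0], edges[j][1], (L - i) / L) for i, j in enumerate(perm)
    )
    return RankedEdgeList(entries, network_id=network_id)


def null_distribution(
    gold: Digraph,
    bounds: EnsembleBounds | None,
    mode: Literal["classic", "inferable"],
    metric: Metric,
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullDistribution:
    """Empirical null of ``metric`` from ``n_reps`` random full-universe
    rankings; ``auc_alpha`` is the linearly interpolated
    ``100*(1-alpha)``-th percentile."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    universe = list(gold.universe())
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    aucs = []
    for rep_seed in child:
        ranking = random_ranking(universe, int(rep_seed))
        result = curves_and_auc(ranking, gold, bounds, mode=mode)
        aucs.append(result.auroc if metric == "auroc" else result.aupr)
    auc_alpha = float(np.percentile(aucs, 100 * (1 - alpha)))
    return NullDistribution(
        metric=metric,
        aucs=tuple(aucs),
        alpha=alpha,
        auc_alpha=auc_alpha,
        seed=seed,
        n_reps=n_reps,
    )


def score_submission(
    aucs: Mapping[str, tuple[float, float]],
    nulls: Mapping[str, tuple[NullDistribution, NullDistribution]],
) -> SubmissionScore:
    """Ratio scores from per-network (AUROC, AUPR) pairs and matching nulls.

    ``nulls[net]`` holds the (AUROC, AUPR) null distributions.  Per-network
    score is ``AUC / AUC_alpha``; aggregate scores are plain means over the
    ``M`` networks and the overall score is the mean of the two metric means.
    """
    missing = set(aucs) ^ set(nulls)
    if missing:
        raise KeyError(f"networks without both AUCs and nulls: {sorted(missing)}")
    per_network: dict[str, tuple[float, float]] = {}
    for net, (auroc, aupr) in aucs.items():
        null_roc, null_pr = nulls[net]
        if null_roc.auc_alpha == 0 or null_pr.auc_alpha == 0:
            raise ZeroNullError(f"null percentile AUC is zero for network {net!r}")
        per_network[net] = (auroc / null_roc.auc_alpha, aupr / null_pr.auc_alpha)
    mean_roc = float(np.mean([s[0] for s in per_network.values()]))
    mean_pr = float(np.mean([s[1] for s in per_network.values()]))
    return SubmissionScore(
        per_network=per_network,
        mean_auroc_score=mean_roc,
        mean_aupr_score=mean_pr,
        overall=(mean_roc + mean_pr) / 2,
    )


def rank_teams(scores: Mapping[str, SubmissionScore]) -> list[str]:
    """Teams ordered by decreasing overall score; ties broken by team label
    so the ranking never depends on input order."""
    return sorted(scores, key=lambda team: (-scores[team].overall, team))


def spearman_rank(
    ranking_a: Sequence[str], ranking_b: Sequence[str]
) -> tuple[float, float]:
    """Spearman's rho (and two-sided p-value) between two orderings of the
    same team set."""
    if set(ranking_a) != set(ranking_b) or len(ranking_a) != len(ranking_b):
        raise MismatchedTeamsError("rankings must order the same team set")
    pos_b = {team: i for i, team in enumerate(ranking_b)}
    ranks_a = list(range(len(ranking_a)))
    ranks_b = [pos_b[team] for team in ranking_a]
    result = stats.spearmanr(ranks_a, ranks_b)
    return float(result.statistic), float(result.pvalue)
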