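"""End-to-end evaluation: gold standards + submissions -> scores + ranking.

This is the library face of the ``grnassess evaluate`` command: load the
gold standards, derive ensemble bounds, compute each team's AUROC/AUPR in
the configured mode, build per-(network, metric) empirical nulls, score and
rank.  Everything is deterministic given the configuration and master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

from .assessment import curves_and_auc
from .graphs import ensemble_bounds
from .io import read_gold_standard, read_prediction, write_scores, write_scores_json
from .scoring import (
    NullDistribution,
    SubmissionScore,
    derive_seed,
    null_distribution,
    rank_teams,
    score_submission,
)

__all__ = ["RunConfig", "run_evaluate"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one evaluation run.

    ``gold_paths`` maps network id to gold-standard file;
    ``prediction_paths`` maps team to {network id: prediction file}.  Every
    team must cover every network.
    """

    gold_paths: Mapping[str, str | Path]
    prediction_paths: Mapping[str, Mapping[str, str | Path]]
    mode: Literal["classic", "inferable"] = "inferable"
    alpha: float = 0.05
    n_reps: int = 100_000
    seed: int = 0
    tail: Literal["expected", "strict"] = "expected"
    out_dir: str | Path | None = None


def run_evaluate(config: RunConfig) -> dict[str, SubmissionScore]:
    """Run the full assessment and (optionally) write reports.

    Writes ``scores.tsv``, ``scores.json`` and ``run_log.json`` (the
    configuration and derived null seeds) under ``config.out_dir`` when one
    is given.  Returns the per-team scores.
    """
    golds = {
        net: read_gold_standard(path) for net, path in config.gold_paths.items()
    }
    bounds = {net: ensemble_bounds(g) for net, g in golds.items()}

    nulls: dict[str, tuple[NullDistribution, NullDistribution]] = {}
    null_seeds: dict[str, dict[str, int]] = {}
    for net, gold in golds.items():
        per_metric = []
        null_seeds[net] = {}
        for metric in ("auroc", "aupr"):
            child = derive_seed(config.seed, net, metric)
            null_seeds[net][metric] = child
            per_metric.append(
                null_distribution(
                    gold,
                    bounds[net],
                    mode=config.mode,
                    metric=metric,  # type: ignore[arg-type]
                    n_reps=config.n_reps,
                    alpha=config.alpha,
                    seed=child,
                )
            )
        nulls[net] = (per_metric[0], per_metric[1])

    scores: dict[str, SubmissionScore] = {}
    for team, per_net in config.prediction_paths.items():
        missing = set(golds) - set(per_net)
        if missing:
            raise KeyError(f"team {team!r} lacks predictions for {sorted(missing)}")
        aucs = {}
        for net in golds:
            ranking = read_prediction(per_net[net], network_id=net)
            result = curves_and_auc(
                ranking, golds[net], bounds[net], mode=config.mode, tail=config.tail
            )
            aucs[net] = (result.auroc, result.aupr)
        scores[team] = score_submission(aucs, nulls)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_scores(scores, out / "scores.tsv")
        write_scores_json(scores, out / "scores.json")
        log = {
            "mode": config.mode,
            "alpha": config.alpha,
            "n_reps": config.n_reps,
            "seed": config.seed,
            "tail": config.tail,
            "null_seeds": null_seeds,
            "ranking": rank_teams(scores),
            "auc_alpha": {
                net: {"auroc": nulls[net][0].auc_alpha, "aupr": nulls[net][1].auc_alpha}
                for net in golds
            },
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return scores
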