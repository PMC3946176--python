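"""Readers and writers for DREAM-style edge-list files and score reports.

Gold standards are three-column files ``regulator<TAB>target<TAB>{0,1}``: a
third column of 1 marks a gold edge, 0 marks a known absent edge (it still
contributes its genes to the universe).  Predictions are
``regulator<TAB>target<TAB>confidence`` ranked lists.  Both tab- and
comma-separated dialects are accepted on read (tab is written); Unix and
Windows line endings are both fine.  Gene labels are opaque, case-sensitive
strings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from .assessment import RankedEdgeList
from .errors import DuplicateEdgeError, ParseError, SelfLoopError
from .graphs import Digraph
from .scoring import SubmissionScore

__all__ = [
    "read_gold_standard",
    "write_gold_standard",
    "read_prediction",
    "write_prediction",
    "write_scores",
    "read_scores",
    "write_scores_json",
]


def _rows(path: str | Path, n_cols: int):
    """Yield (line_number, fields) from a delimiter-sniffed table file."""
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\r\n ")
        if not line:
            continue
        sep = "\t" if "\t" in line else ","
        fields = [f.strip() for f in line.split(sep)]
        if len(fields) != n_cols:
            raise ParseError(
                f"expected {n_cols} fields, found {len(fields)}", line=lineno
            )
        yield lineno, fields


def read_gold_standard(
    path: str | Path, universe: Iterable[str] | None = None
) -> Digraph:
    """Parse a gold-standard edge list into a :class:`Digraph`.

    The gene universe is every label seen in the file; pass ``universe`` to
    declare it explicitly (required for an empty file, and it must contain
    every label the file mentions).
    """
    edges = []
    seen: dict[str, None] = {}
    for lineno, (tail, head, flag) in _rows(path, 3):
        if flag not in {"0", "1"}:
            raise ParseError(f"third column must be 0 or 1, got {flag!r}", lineno)
        seen.setdefault(tail, None)
        seen.setdefault(head, None)
        if flag == "1":
            if tail == head:
                raise SelfLoopError(
                    f"line {lineno}: self-loop {tail!r} in gold standard"
                )
            edges.append((tail, head))
    if universe is not None:
        declared = list(dict.fromkeys(universe))
        missing = set(seen) - set(declared)
        if missing:
            raise ParseError(
                f"labels {sorted(missing)} not in the declared universe"
            )
        nodes = tuple(declared)
    else:
        if not seen:
            raise ParseError(
                "empty gold standard requires an explicit gene universe"
            )
        nodes = tuple(seen)
    return Digraph.from_edges(edges, nodes=nodes)


def write_gold_standard(gold: Digraph, path: str | Path) -> None:
    """Write every universe pair with a 0/1 membership flag, gold edges
    first (canonical node order within each block)."""
    members = set(gold.edges)
    lines = [f"{u}\t{v}\t1" for u, v in gold.universe() if (u, v) in members]
    lines += [f"{u}\t{v}\t0" for u, v in gold.universe() if (u, v) not in members]
    Path(path).write_text("\n".join(lines) + "\n")


def read_prediction(path: str | Path, network_id: str = "") -> RankedEdgeList:
    """Parse a ranked prediction list.

    Entries are re-sorted by decreasing confidence with a stable sort, so
    ties keep their file order; duplicate edges are an error.
    """
    entries = []
    seen = set()
    for lineno, (tail, head, conf) in _rows(path, 3):
        try:
            value = float(conf)
        except ValueError:
            raise ParseError(f"confidence {conf!r} is not a number", lineno)
        if (tail, head) in seen:
            raise DuplicateEdgeError(
                f"line {lineno}: duplicate edge ({tail!r}, {head!r})"
            )
        seen.add((tail, head))
        entries.append((tail, head, value))
    entries.sort(key=lambda e: -e[2])  # stable: ties keep file order
    if network_id == "":
        network_id = Path(path).stem
    return RankedEdgeList(tuple(entries), network_id=network_id)


def write_prediction(ranking: RankedEdgeList, path: str | Path) -> None:
    lines = [f"{t}\t{h}\t{c!r}" for t, h, c in ranking.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def _score_columns(networks: list[str]) -> list[str]:
    cols = [f"auroc_score_{net}" for net in networks]
    cols += [f"aupr_score_{net}" for net in networks]
    return cols + ["mean_auroc_score", "mean_aupr_score", "overall", "rank"]


def write_scores(scores: Mapping[str, SubmissionScore], path: str | Path) -> None:
    """Tab-separated score report: one row per team, ordered by rank.

    Columns: team, per-network AUROC and AUPR scores, the two metric means,
    the overall score and the 1-based rank.  Floats are written at full
    precision so the report round-trips through :func:`read_scores`.
    """
    if not scores:
        raise ValueError("no scores to write")
    from .scoring import rank_teams

    order = rank_teams(scores)
    networks = sorted(next(iter(scores.values())).per_network)
    header = ["team"] + _score_columns(networks)
    lines = ["\t".join(header)]
    for rank, team in enumerate(order, start=1):
        s = scores[team]
        if sorted(s.per_network) != networks:
            raise ValueError(f"team {team!r} scored a different network set")
        row = [team]
        row += [repr(s.per_network[net][0]) for net in networks]
        row += [repr(s.per_network[net][1]) for net in networks]
        row += [
            repr(s.mean_auroc_score),
            repr(s.mean_aupr_score),
            repr(s.overall),
            str(rank),
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_scores(path: str | Path) -> dict[str, SubmissionScore]:
    """Inverse of :func:`write_scores` (rank column is recomputed, not
    stored)."""
    text = Path(path).read_text().splitlines()
    if not text:
        raise ParseError("empty score report")
    header = text[0].rstrip("\r").split("\t")
    networks = [
        c[len("auroc_score_"):] for c in header if c.startswith("auroc_score_")
    ]
    out: dict[str, SubmissionScore] = {}
    for raw in text[1:]:
        fields = raw.rstrip("\r").split("\t")
        rec = dict(zip(header, fields))
        per_network = {
            net: (
                float(rec[f"auroc_score_{net}"]),
                float(rec[f"aupr_score_{net}"]),
            )
            for net in networks
        }
        out[rec["team"]] = SubmissionScore(
            per_network=per_network,
            mean_auroc_score=float(rec["mean_auroc_score"]),
            mean_aupr_score=float(rec["mean_aupr_score"]),
            overall=float(rec["overall"]),
        )
    return out


def write_scores_json(scores: Mapping[str, SubmissionScore], path: str | Path) -> None:
    """Structured key-value companion to the tab-separated report."""
    from .scoring import rank_teams

    order = rank_teams(scores)
    payload = {
        team: {
            "rank": rank,
            "per_network": {
                net: {"auroc_score": s[0], "aupr_score": s[1]}
                for net, s in sorted(scores[team].per_network.items())
            },
            "mean_auroc_score": scores[team].mean_auroc_score,
            "mean_aupr_score": scores[team].mean_aupr_score,
            "overall": scores[team].overall,
        }
        for rank, team in enumerate(order, start=1)
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
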