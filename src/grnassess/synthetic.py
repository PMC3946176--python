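"""Synthetic gold standards and predictions with controlled error structure.

The generator builds gold standards from the motifs whose inferability
behaviour is known in closed form under a complete single-gene KO/KD design:

* cascade ``A -> B -> C``      — both edges inferable, shortcut ``A -> C`` not;
* feed-forward loop (FFL)      — ``A -> B, B -> C`` inferable, ``A -> C`` not;
* 2-cycle ``A <-> B``          — fully inferable;
* k-cycle, ``k >= 3``          — fully non-inferable.

Motifs are placed on disjoint node groups so the ensemble bounds of the
whole network are the unions of the per-motif bounds, which keeps the ground
truth analytic in tests.  Optional Bernoulli "extra" edges break that
guarantee and are off by default.

Predictions come with two independently controlled error channels:

``cascade_error_rate``
    A gold edge is displaced by a non-inferable shortcut (an edge of ``Ē``):
    the classic systematic error of confusing direct and indirect
    regulation.  The displaced gold edge still precedes every genuine
    negative, so inferability-aware scores are untouched while classic
    scores degrade.

``flip_rate``
    A gold edge swaps rank with an edge outside the transitive closure — a
    genuine error no perturbation design forgives; both assessments degrade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assessment import RankedEdgeList
from .errors import InfeasibleSpecError
from .graphs import Digraph, Edge, ensemble_bounds

__all__ = ["MotifSpec", "generate_gold", "generate_prediction"]


@dataclass(frozen=True)
class MotifSpec:
    """Composition of a synthetic gold standard.

    ``k_cycles`` lists the length of each directed cycle to embed (k >= 3);
    2-cycles have their own counter.  ``extra_edge_prob`` adds independent
    Bernoulli edges between so-far-unconnected ordered pairs.
    """

    n_nodes: int
    n_cascades: int = 0
    n_ffls: int = 0
    n_two_cycles: int = 0
    k_cycles: tuple[int, ...] = field(default_factory=tuple)
    extra_edge_prob: float = 0.0
    seed: int = 0

    def nodes_needed(self) -> int:
        return (
            3 * self.n_cascades
            + 3 * self.n_ffls
            + 2 * self.n_two_cycles
            + sum(self.k_cycles)
        )

    def __post_init__(self) -> None:
        if not 0.0 <= self.extra_edge_prob <= 1.0:
            raise ValueError("extra_edge_prob must lie in [0, 1]")
        if any(k < 3 for k in self.k_cycles):
            raise InfeasibleSpecError("k-cycles must have k >= 3")
        if min(self.n_cascades, self.n_ffls, self.n_two_cycles) < 0:
            raise InfeasibleSpecError("motif counts must be non-negative")
        if self.nodes_needed() > self.n_nodes:
            raise InfeasibleSpecError(
                f"motifs need {self.nodes_needed()} nodes, only "
                f"{self.n_nodes} available"
            )


def generate_gold(spec: MotifSpec) -> Digraph:
    """Deterministic (per seed) gold standard realising ``spec``.

    Nodes are labelled ``G1..Gn``; the seed shuffles which genes land in
    which motif, so different seeds give differently-labelled but
    isomorphic cores.
    """
    rng = np.random.default_rng(spec.seed)
    labels = [f"G{i + 1}" for i in range(spec.n_nodes)]
    pool = [labels[i] for i in rng.permutation(spec.n_nodes)]

    def take(k: int) -> list[str]:
        group, pool[:k] = pool[:k], []
        return group

    edges: set[Edge] = set()
    for _ in range(spec.n_cascades):
        a, b, c = take(3)
        edges |= {(a, b), (b, c)}
    for _ in range(spec.n_ffls):
        a, b, c = take(3)
        edges |= {(a, b), (b, c), (a, c)}
    for _ in range(spec.n_two_cycles):
        a, b = take(2)
        edges |= {(a, b), (b, a)}
    for k in spec.k_cycles:
        cyc = take(k)
        edges |= {(cyc[i], cyc[(i + 1) % k]) for i in range(k)}

    if spec.extra_edge_prob > 0:
        for u in labels:
            for v in labels:
                if u != v and (u, v) not in edges:
                    if rng.random() < spec.extra_edge_prob:
                        edges.add((u, v))
    return Digraph(tuple(labels), frozenset(edges))


def generate_prediction(
    gold: Digraph,
    cascade_error_rate: float = 0.0,
    flip_rate: float = 0.0,
    seed: int = 0,
) -> RankedEdgeList:
    """Ranked prediction for ``gold`` with controlled error channels.

    The list has three blocks.  Block 1 holds the gold edges (shuffled),
    except that each gold edge is independently displaced: with probability
    ``cascade_error_rate`` a fresh non-inferable edge takes its place and the
    gold edge drops to block 2; otherwise, with probability ``flip_rate``, a
    fresh edge from outside the transitive closure takes its place and the
    gold edge drops into the random tail.  Block 2 holds the
    cascade-displaced gold edges, block 3 the remaining universe edges, both
    shuffled.  Confidences decrease linearly over the full universe.

    When the supply of substitute edges runs out the displacement is
    skipped, so error rates saturate on small or cycle-free-closure
    networks.
    """
    if not 0.0 <= cascade_error_rate <= 1.0 or not 0.0 <= flip_rate <= 1.0:
        raise ValueError("error rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bounds = ensemble_bounds(gold)
    universe = list(gold.universe())

    def shuffled(items: list[Edge]) -> list[Edge]:
        return [items[i] for i in rng.permutation(len(items))]

    noninf_pool = shuffled(sorted(bounds.non_inferable - gold.edges, key=repr))
    outside_pool = shuffled(
        sorted(set(universe) - bounds.upper, key=repr)
    )

    block1: list[Edge] = []
    block2: list[Edge] = []
    tail_gold: list[Edge] = []
    for edge in shuffled(sorted(gold.edges, key=repr)):
        r = rng.random()
        if r < cascade_error_rate:
            if noninf_pool:
                block1.append(noninf_pool.pop())
                block2.append(edge)
            else:  # substitute supply exhausted: keep the gold edge
                block1.append(edge)
        elif r < cascade_error_rate + flip_rate:
            if outside_pool:
                block1.append(outside_pool.pop())
                tail_gold.append(edge)
            else:
                block1.append(edge)
        else:
            block1.append(edge)

    placed = set(block1) | set(block2)
    rest = shuffled([e for e in universe if e not in placed])
    ordered = block1 + shuffled(block2) + rest
    L = len(ordered)
    entries = tuple(
        (t, h, (L - i) / L) for i, (t, h) in enumerate(ordered)
    )
    return RankedEdgeList(entries, network_id="synthetic")
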