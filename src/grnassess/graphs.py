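"""Directed-graph machinery for ensemble bounds of a gold-standard network.

Steady-state expression profiles from single-gene knock-out/knock-down (KO/KD)
experiments reveal which genes respond to a perturbation, i.e. *reachability*,
but cannot separate direct from indirect regulation.  Every digraph with the
same transitive closure as the true network is therefore indistinguishable
from such data.  This module computes, for a gold-standard digraph ``G``:

* the **upper bound** ``G_U`` — the transitive closure, i.e. the largest
  network consistent with ideal KO/KD reachability data;
* the **lower bound** ``G_L`` — an approximation of the edges present in
  *every* network sharing that closure, obtained by transitively reducing the
  condensation (the DAG of strongly connected components) and discarding
  edges whose causal attachment point inside a cycle is unidentifiable;
* the **non-inferable set** ``Ē = G_U \\ G_L`` — edges the data can neither
  confirm nor refute.

Self-loops (auto-regulation) are excluded throughout: the edge universe of an
``n``-gene network has ``n(n-1)`` candidate edges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Sequence

import networkx as nx

from .errors import CyclicGraphError, SelfLoopError, TooLargeError

Node = Hashable
Edge = tuple[Node, Node]

__all__ = [
    "Digraph",
    "SccPartition",
    "EnsembleBounds",
    "scc_condense",
    "transitive_closure",
    "transitive_reduction_dag",
    "ensemble_bounds",
    "enumerate_closure_class",
]


@dataclass(frozen=True)
class Digraph:
    """A labelled digraph without self-loops.

    Parameters
    ----------
    nodes
        Ordered tuple of node labels; order fixes the canonical edge-universe
        enumeration used elsewhere (ranking universes, synthetic generators).
    edges
        Frozen set of ordered ``(tail, head)`` pairs.
    """

    nodes: tuple[Node, ...]
    edges: frozenset[Edge] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for tail, head in self.edges:
            if tail == head:
                raise SelfLoopError(f"self-loop on node {tail!r}")
            if tail not in node_set or head not in node_set:
                raise ValueError(f"edge ({tail!r}, {head!r}) uses an unknown node")

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], nodes: Iterable[Node] | None = None
    ) -> "Digraph":
        """Build a digraph from an edge list; nodes default to the labels seen,
        in first-appearance order."""
        edges = list(edges)
        if nodes is None:
            seen: dict[Node, None] = {}
            for tail, head in edges:
                seen.setdefault(tail, None)
                seen.setdefault(head, None)
            nodes = seen
        return cls(tuple(nodes), frozenset(edges))

    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.nodes)

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    def universe(self) -> Iterator[Edge]:
        """All ``n(n-1)`` ordered node pairs, in canonical node order."""
        return (
            (u, v) for u in self.nodes for v in self.nodes if u != v
        )

    def universe_size(self) -> int:
        return self.n * (self.n - 1)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def replace_edges(self, edges: Iterable[Edge]) -> "Digraph":
        """Same node set, different edge set."""
        return Digraph(self.nodes, frozenset(edges))


@dataclass(frozen=True)
class SccPartition:
    """Strongly connected components of a digraph and their condensation.

    ``components[i]`` is the i-th block of the node partition;
    ``component_dag`` is the acyclic digraph on block indices with an edge
    ``i -> j`` iff some source edge runs from block i to block j.
    """

    components: tuple[frozenset[Node], ...]
    component_dag: Digraph

    def block_of(self, node: Node) -> int:
        for i, block in enumerate(self.components):
            if node in block:
                return i
        raise KeyError(node)


@dataclass(frozen=True)
class EnsembleBounds:
    """Lower/upper ensemble bounds and non-inferable edge set for a gold
    standard under an all-single-gene KO/KD design."""

    lower: frozenset[Edge]
    upper: frozenset[Edge]
    non_inferable: frozenset[Edge]
    gold_size: int

    @property
    def n_non_inferable(self) -> int:
        return len(self.non_inferable)


def scc_condense(g: Digraph) -> SccPartition:
    """Partition ``g`` into strongly connected components and condense.

    Two nodes share a block iff each is accessible from the other; the
    condensation lumps each block into a single node and is always acyclic.
    """
    nxg = g.to_networkx()
    cond = nx.condensation(nxg)  # nodes 0..k-1, attribute "members"
    components = tuple(
        frozenset(cond.nodes[i]["members"]) for i in cond.nodes
    )
    dag = Digraph(tuple(range(len(components))), frozenset(cond.edges))
    return SccPartition(components, dag)


def transitive_closure(g: Digraph) -> Digraph:
    """Digraph with an edge ``(i, j)``, ``i != j``, iff ``j`` is reachable
    from ``i`` by a directed path of length >= 1.  Idempotent."""
    closed = nx.transitive_closure(g.to_networkx(), reflexive=False)
    # Nodes on cycles reach themselves; the edge universe excludes self-loops.
    edges = frozenset((u, v) for u, v in closed.edges if u != v)
    return Digraph(g.nodes, edges)


def transitive_reduction_dag(
    g: Digraph, order: Sequence[Edge] | None = None
) -> Digraph:
    """Unique minimal digraph with the same transitive closure as the DAG ``g``.

    Follows the pruning formulation: repeatedly delete any edge ``(u, v)``
    for which a directed path from ``u`` to ``v`` survives without it.  For a
    DAG the result does not depend on the pruning order; ``order`` (default
    lexicographic by ``(tail, head)`` repr) exists so tests can assert that.

    Raises
    ------
    CyclicGraphError
        If ``g`` contains a directed cycle.
    """
    nxg = g.to_networkx()
    if not nx.is_directed_acyclic_graph(nxg):
        raise CyclicGraphError("transitive reduction is only unique for DAGs")
    if order is None:
        order = sorted(g.edges, key=repr)
    else:
        if set(order) != set(g.edges):
            raise ValueError("order must be a permutation of the edge set")
    kept = nxg.copy()
    for u, v in order:
        kept.remove_edge(u, v)
        if not nx.has_path(kept, u, v):
            kept.add_edge(u, v)
    return Digraph(g.nodes, frozenset(kept.edges))


def ensemble_bounds(gold: Digraph) -> EnsembleBounds:
    """Ensemble bounds of a gold standard under complete single-gene KO/KD.

    The upper bound is the transitive closure.  The lower bound condenses the
    gold standard, transitively reduces the resulting DAG, drops every
    condensed edge incident to a non-trivial strong component (the attachment
    point of an edge entering or leaving a cycle cannot be identified from
    reachability), expands blocks back to gene level, and keeps internal
    edges only for 2-cycles — the unique minimal strongly connected digraph
    on two nodes — while all internal edges of larger cycles are dropped.
    """
    upper = transitive_closure(gold).edges
    part = scc_condense(gold)
    reduced = transitive_reduction_dag(part.component_dag)
    sizes = [len(block) for block in part.components]

    lower: set[Edge] = set()
    # Representative node of each singleton block, for expansion.
    singleton = {
        i: next(iter(block))
        for i, block in enumerate(part.components)
        if sizes[i] == 1
    }
    for bi, bj in reduced.edges:
        if sizes[bi] >= 2 or sizes[bj] >= 2:
            continue  # incident to a cycle component: attachment unidentifiable
        lower.add((singleton[bi], singleton[bj]))
    # Internal edges: 2-cycles are fully determined, k>=3 cycles are not.
    for i, block in enumerate(part.components):
        if sizes[i] == 2:
            u, v = tuple(block)
            lower.update({(u, v), (v, u)})

    lower_f = frozenset(lower)
    return EnsembleBounds(
        lower=lower_f,
        upper=upper,
        non_inferable=upper - lower_f,
        gold_size=gold.m,
    )


def _closure_bits(rows: list[int], n: int) -> tuple[int, ...]:
    """Warshall transitive closure on bitmask adjacency rows; keeps the
    diagonal behaviour of length->=1 paths (a node on a cycle reaches itself,
    stripped by the caller)."""
    reach = list(rows)
    for k in range(n):
        bit = 1 << k
        rk = reach[k]
        for i in range(n):
            if reach[i] & bit:
                reach[i] |= rk
    return tuple(reach)


def enumerate_closure_class(gold: Digraph, max_nodes: int = 5) -> set[Digraph]:
    """Every digraph on ``gold``'s node set whose transitive closure equals
    ``gold``'s (the ensemble indistinguishable from ideal KO/KD data).

    Exhaustive over subsets of the closure's edge set (any member must be a
    subgraph of the closure), so feasible only for small ``n``.

    Raises
    ------
    TooLargeError
        If the node count exceeds ``max_nodes``.
    """
    if gold.n > max_nodes:
        raise TooLargeError(
            f"{gold.n} nodes exceeds the enumeration cap of {max_nodes}"
        )
    n = gold.n
    index = {node: i for i, node in enumerate(gold.nodes)}

    def rows_of(edges: Iterable[Edge]) -> list[int]:
        rows = [0] * n
        for u, v in edges:
            rows[index[u]] |= 1 << index[v]
        return rows

    def closure_key(edges: Iterable[Edge]) -> tuple[int, ...]:
        closed = _closure_bits(rows_of(edges), n)
        # strip diagonal: self-reachability is not an edge
        return tuple(row & ~(1 << i) for i, row in enumerate(closed))

    target = closure_key(gold.edges)
    closure_edges = [
        (gold.nodes[i], gold.nodes[j])
        for i in range(n)
        for j in range(n)
        if i != j and target[i] >> j & 1
    ]
    members: set[Digraph] = set()
    for r in range(len(closure_edges) + 1):
        for subset in itertools.combinations(closure_edges, r):
            if closure_key(subset) == target:
                members.add(gold.replace_edges(subset))
    return members
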