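import itertools

import numpy as np
import pytest

from grnassess import Digraph, RankedEdgeList


@pytest.fixture
def cascade():
    return Digraph.from_edges([("A", "B"), ("B", "C")], nodes=["A", "B", "C"])


@pytest.fixture
def ffl():
    return Digraph.from_edges(
        [("A", "B"), ("A", "C"), ("B", "C")], nodes=["A", "B", "C"]
    )


@pytest.fixture
def two_cycle():
    return Digraph.from_edges([("A", "B"), ("B", "A")], nodes=["A", "B"])


@pytest.fixture
def three_cycle():
    return Digraph.from_edges(
        [("A", "B"), ("B", "C"), ("C", "A")], nodes=["A", "B", "C"]
    )


def ranking_from_edges(edges, network_id=""):
    """Ranked list with strictly decreasing confidences in the given order."""
    L = len(edges)
    return RankedEdgeList(
        tuple((t, h, (L - i) / L) for i, (t, h) in enumerate(edges)),
        network_id=network_id,
    )


def all_digraphs(n):
    """Every digraph on n labelled nodes (no self-loops): 2^(n(n-1)) graphs."""
    nodes = tuple(chr(ord("A") + i) for i in range(n))
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    for r in range(len(pairs) + 1):
        for subset in itertools.combinations(pairs, r):
            yield Digraph(nodes, frozenset(subset))


def random_digraph(n, rng, p=0.3):
    nodes = tuple(chr(ord("A") + i) for i in range(n))
    edges = [
        (u, v) for u in nodes for v in nodes if u != v and rng.random() < p
    ]
    return Digraph(nodes, frozenset(edges))
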