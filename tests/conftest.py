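"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netknock.expression import node_weights, weight_edges
from netknock.fixtures import (
    FixtureSpec,
    make_expression_fixture,
    make_network_fixture,
    make_taxonomy_fixture,
)
from netknock.network import add_anchors, build_curated, rescue_experimental


def enumerate_paths_oracle(graph: nx.DiGraph, start: str, end: str, k: int):
    """Exhaustive loopless-path enumeration by depth-first search.

    Independent of the Yen's-algorithm route under test. Returns the k
    cheapest (cost, node-tuple) pairs, sorted by cost then sequence.
    """
    results = []

    def dfs(node, visited, cost, path):
        if node == end:
            results.append((cost, tuple(path)))
            return
        for nb in graph.successors(node):
            if nb not in visited:
                dfs(nb, visited | {nb}, cost + graph.edges[node, nb]["cost"], path + [nb])

    if start in graph and end in graph:
        dfs(start, {start}, 0.0, [start])
    results.sort(key=lambda cp: (cp[0], cp[1]))
    return results[:k]


def random_cost_digraph(rng: np.random.Generator, n_max: int = 8, p: float = 0.4):
    """A random directed graph with positive edge costs."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.DiGraph()
    g.add_nodes_from(f"N{i}" for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(f"N{i}", f"N{j}", cost=float(rng.uniform(0.1, 2.0)))
    return g


def build_weighted_pipeline(spec: FixtureSpec):
    """Run build → rescue → anchors → weighting on a generated fixture."""
    fx = make_network_fixture(spec)
    net, _, unconnected = build_curated(fx.candidate_nodes, fx.curated_edges)
    net, report = rescue_experimental(net, unconnected, fx.experimental_edges)
    net = add_anchors(net, fx.anchors)
    expr = make_expression_fixture(
        spec, fx.candidate_nodes, dysregulated=fx.truth.get("background_nodes")
    )
    net = weight_edges(net, node_weights(expr, net.nodes))
    return fx, expr, net, report


@pytest.fixture
def taxonomies():
    return make_taxonomy_fixture()


@pytest.fixture
def diamond_net():
    """A -> B -> D (1 + 1) and A -> C -> D (1 + 3)."""
    g = nx.DiGraph()
    g.add_edge("A", "B", cost=1.0)
    g.add_edge("B", "D", cost=1.0)
    g.add_edge("A", "C", cost=1.0)
    g.add_edge("C", "D", cost=3.0)
    return g
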