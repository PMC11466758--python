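"""K-shortest-path references and in silico single-node knockouts.

For every (start, end) anchor pair the K lowest-cost loopless directed
paths are enumerated with Yen's algorithm and their total cost stored as
the pair's reference. Each network node is then removed in turn and the
paths recomputed; the increase in total path cost (or outright
disconnection of the pair) measures how essential that node is to the
disease pathways, and nodes are ranked accordingly.

When a knockout leaves fewer surviving paths than the reference, the
surviving-path cost sum is compared against the reference sum truncated
to the same number of paths, so path scarcity is not conflated with cost
increase. Pairs left with no path at all are counted as disconnections —
the primary ranking key — rather than being mapped to an arbitrary
numeric penalty (an optional finite-penalty mode is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx

from netknock.network import DiseaseNetwork

logger = logging.getLogger(__name__)

DEFAULT_K = 100
_TIE_SLACK = 1e-12

AGGREGATION_METHODS = ("default", "sum_delta", "max_delta")


@dataclass(frozen=True)
class PathResult:
    """One loopless directed path and its total edge cost."""

    nodes: tuple[str, ...]
    cost: float


@dataclass
class PairPathReference:
    """The K lowest-cost paths for one (start, end) pair on the intact network."""

    start: str
    end: str
    k: int
    paths: list[PathResult] = field(default_factory=list)

    @property
    def ref_cost(self) -> float:
        return sum(p.cost for p in self.paths)

    @property
    def unreachable(self) -> bool:
        return not self.paths

    def node_union(self) -> set[str]:
        out: set[str] = set()
        for p in self.paths:
            out.update(p.nodes)
        return out


@dataclass(frozen=True)
class KnockoutDelta:
    """Cost change for one (removed node, pair) combination.

    ``delta`` is ``new_cost`` minus the reference cost truncated to the
    surviving path count; it is ``None`` when the pair is disconnected.
    """

    removed_node: str
    start: str
    end: str
    new_cost: Optional[float]
    delta: Optional[float]
    disconnected: bool
    ref_cost: float


@dataclass(frozen=True)
class TargetRanking:
    node: str
    n_pairs_affected: int
    n_pairs_disconnected: int
    sum_delta: float
    max_delta: float
    rank: int
    blocked: bool = False


def _as_graph(net: Union[DiseaseNetwork, nx.DiGraph]) -> nx.DiGraph:
    return net.graph if isinstance(net, DiseaseNetwork) else net


def _path_cost(graph: nx.DiGraph, path: Sequence[str]) -> float:
    return sum(graph.edges[u, v]["cost"] for u, v in zip(path, path[1:]))


def k_shortest_paths(
    net: Union[DiseaseNetwork, nx.DiGraph],
    start: str,
    end: str,
    k: int = DEFAULT_K,
) -> PairPathReference:
    """The K lowest-cost loopless directed paths from start to end.

    Paths are sorted by non-decreasing cost with ties broken by
    lexicographic node sequence, so the result is deterministic and
    matches exhaustive enumeration on graphs where that is feasible.
    An unreachable pair yields an empty reference (not an error).
    """
    graph = _as_graph(net)
    if start == end:
        raise ValueError("start and end nodes must differ")
    for node in (start, end):
        if node not in graph:
            raise KeyError(f"node {node!r} not in network")
    if k < 1:
        raise ValueError("k must be >= 1")

    ref = PairPathReference(start=start, end=end, k=k)
    try:
        generator = nx.shortest_simple_paths(graph, start, end, weight="cost")
        collected: list[tuple[float, tuple[str, ...]]] = []
        kth_cost = float("inf")
        for path in generator:
            cost = _path_cost(graph, path)
            if len(collected) >= k and cost > kth_cost + _TIE_SLACK:
                break
            collected.append((cost, tuple(path)))
            if len(collected) >= k:
                kth_cost = sorted(c for c, _ in collected)[k - 1]
    except nx.NetworkXNoPath:
        return ref
    collected.sort(key=lambda cp: (cp[0], cp[1]))
    ref.paths = [PathResult(nodes=p, cost=c) for c, p in collected[:k]]
    return ref


def reference_scan(
    net: Union[DiseaseNetwork, nx.DiGraph],
    pairs: Optional[Iterable[tuple[str, str]]] = None,
    k: int = DEFAULT_K,
) -> dict[tuple[str, str], PairPathReference]:
    """Path references for every (start, end) anchor combination.

    ``pairs`` defaults to the Cartesian product of the network's anchor
    start nodes (ligands + receptors) and end nodes (ECM). Unreachable
    pairs are flagged (empty path list) and skipped by the knockout
    scan; anchor nodes missing from the graph count as unreachable.
    """
    graph = _as_graph(net)
    if pairs is None:
        anchors = net.anchors if isinstance(net, DiseaseNetwork) else None
        if anchors is None:
            raise ValueError("no pairs given and the network has no anchor config")
        pairs = anchors.pairs()
    references: dict[tuple[str, str], PairPathReference] = {}
    n_unreachable = 0
    for start, end in pairs:
        if start not in graph or end not in graph:
            references[(start, end)] = PairPathReference(start=start, end=end, k=k)
            n_unreachable += 1
            continue
        ref = k_shortest_paths(graph, start, end, k)
        references[(start, end)] = ref
        n_unreachable += ref.unreachable
    if n_unreachable:
        logger.info("%d of %d anchor pairs unreachable", n_unreachable, len(references))
    return references


def knockout_delta(
    graph: nx.DiGraph,
    ref: PairPathReference,
    node: str,
    k: int,
) -> KnockoutDelta:
    """Delta for one (node, pair) by recomputing paths on graph − node."""
    pruned = nx.restricted_view(graph, [node], [])
    new_ref = k_shortest_paths(pruned, ref.start, ref.end, k)
    if new_ref.unreachable:
        return KnockoutDelta(
            removed_node=node,
            start=ref.start,
            end=ref.end,
            new_cost=None,
            delta=None,
            disconnected=True,
            ref_cost=ref.ref_cost,
        )
    m = len(new_ref.paths)
    new_cost = sum(p.cost for p in new_ref.paths)
    ref_trunc = sum(p.cost for p in ref.paths[:m])
    return KnockoutDelta(
        removed_node=node,
        start=ref.start,
        end=ref.end,
        new_cost=new_cost,
        delta=new_cost - ref_trunc,
        disconnected=False,
        ref_cost=ref.ref_cost,
    )


def knockout_scan(
    net: Union[DiseaseNetwork, nx.DiGraph],
    references: Mapping[tuple[str, str], PairPathReference],
    k: int = DEFAULT_K,
    nodes: Optional[Iterable[str]] = None,
    short_circuit: bool = True,
) -> list[KnockoutDelta]:
    """Remove each node in turn and score the cost change for every pair.

    A node is never knocked out for a pair it anchors. Nodes absent from
    every reference path of a pair cannot change that pair's K cheapest
    paths, so their delta is emitted as exactly 0 without recomputation
    (disable with ``short_circuit=False`` to verify the equivalence).
    """
    graph = _as_graph(net)
    candidates = sorted(nodes) if nodes is not None else sorted(graph.nodes)
    reachable = {pair: ref for pair, ref in references.items() if not ref.unreachable}
    path_nodes = {pair: ref.node_union() for pair, ref in reachable.items()}
    deltas: list[KnockoutDelta] = []
    for node in candidates:
        for pair, ref in reachable.items():
            if node in pair:
                continue
            if short_circuit and node not in path_nodes[pair]:
                deltas.append(
                    KnockoutDelta(
                        removed_node=node,
                        start=ref.start,
                        end=ref.end,
                        new_cost=ref.ref_cost,
                        delta=0.0,
                        disconnected=False,
                        ref_cost=ref.ref_cost,
                    )
                )
                continue
            deltas.append(knockout_delta(graph, ref, node, k))
    return deltas


def aggregate_and_rank(
    deltas: Iterable[KnockoutDelta],
    method: str = "default",
    blocklist: Iterable[str] = (),
    disconnection_penalty: Optional[float] = None,
) -> list[TargetRanking]:
    """Aggregate per-pair deltas into one ranked record per node.

    Default order: descending (pairs disconnected, sum of finite deltas,
    pairs affected), ties by identifier. ``sum_delta`` and ``max_delta``
    rank purely numerically. With ``disconnection_penalty`` = λ, a
    disconnected pair contributes λ·ref_cost to the numeric aggregates,
    reproducing a pure "maximal cost increase" reading.

    Blocklisted nodes (generic hubs such as EGFR, TGFBR1/2, SMAD3 or
    TP53 that would dominate any ranking) are flagged after ranking and
    keep their rank number; downstream reports drop them.
    """
    if method not in AGGREGATION_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {AGGREGATION_METHODS}")
    blocked = set(blocklist)
    per_node: dict[str, dict] = {}
    for d in deltas:
        agg = per_node.setdefault(
            d.removed_node,
            {"affected": 0, "disconnected": 0, "sum": 0.0, "max": 0.0},
        )
        if d.disconnected:
            agg["disconnected"] += 1
            agg["affected"] += 1
            if disconnection_penalty is not None:
                penalized = disconnection_penalty * d.ref_cost
                agg["sum"] += penalized
                agg["max"] = max(agg["max"], penalized)
        else:
            if d.delta > 0.0:
                agg["affected"] += 1
            agg["sum"] += d.delta
            agg["max"] = max(agg["max"], d.delta)

    def sort_key(item: tuple[str, dict]):
        node, a = item
        if method == "sum_delta":
            return (-a["sum"], node)
        if method == "max_delta":
            return (-a["max"], node)
        return (-a["disconnected"], -a["sum"], -a["affected"], node)

    ranked = sorted(per_node.items(), key=sort_key)
    out = []
    for rank, (node, a) in enumerate(ranked, start=1):
        out.append(
            TargetRanking(
                node=node,
                n_pairs_affected=a["affected"],
                n_pairs_disconnected=a["disconnected"],
                sum_delta=a["sum"],
                max_delta=a["max"],
                rank=rank,
                blocked=node in blocked,
            )
        )
    return out


def shortlist(rankings: Iterable[TargetRanking]) -> list[TargetRanking]:
    """Rankings with blocklisted nodes removed (original ranks retained)."""
    return [r for r in rankings if not r.blocked]


def all_simple_paths_reference(
    net: Union[DiseaseNetwork, nx.DiGraph],
    start: str,
    end: str,
    k: int = DEFAULT_K,
) -> PairPathReference:
    """Brute-force reference by exhaustive simple-path enumeration.

    Exponential; intended for validation on small graphs only.
    """
    graph = _as_graph(net)
    ref = PairPathReference(start=start, end=end, k=k)
    if start not in graph or end not in graph:
        return ref
    scored = []
    for path in nx.all_simple_paths(graph, start, end):
        scored.append((_path_cost(graph, path), tuple(path)))
    scored.sort(key=lambda cp: (cp[0], cp[1]))
    ref.paths = [PathResult(nodes=p, cost=c) for c, p in scored[:k]]
    return ref
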