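"""Construction of the directional disease network from two edge sources.

The curated source (IPA-like) supplies directed, high-trust edges; the
experimental source (STRING-like) supplies undirected edges with a
confidence e-score in [0, 1]. Candidate nodes left isolated by the
curated source are rescued through experimental edges where possible,
and nodes that remain isolated are pruned. Anchor nodes (ligands,
receptors, ECM proteins) are then added, with directed ligand→receptor
edges from a ligand–receptor pair table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from netknock.anchors import StartEndConfig

logger = logging.getLogger(__name__)

CURATED = "curated"
EXPERIMENTAL = "experimental"


class DiseaseNetwork:
    """Directed simple graph with per-edge provenance, e-score, weight and cost.

    Thin wrapper around :class:`networkx.DiGraph`. At most one edge per
    ordered pair; when the same ordered pair arrives from both sources
    the provenances are unioned and the experimental e-score retained.
    Self-loops are dropped at insertion (paths are loopless downstream).
    """

    def __init__(self, anchors: Optional[StartEndConfig] = None) -> None:
        self.graph = nx.DiGraph()
        self.anchors = anchors

    # -- node / edge management -------------------------------------------

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(
        self,
        src: str,
        dst: str,
        provenance: str,
        e_score: Optional[float] = None,
    ) -> None:
        if src == dst:
            return
        if provenance == EXPERIMENTAL and e_score is None:
            raise ValueError(f"experimental edge {src}->{dst} lacks an e-score")
        if e_score is not None and not (0.0 <= e_score <= 1.0):
            raise ValueError(f"e-score {e_score} outside [0, 1] for {src}->{dst}")
        if self.graph.has_edge(src, dst):
            data = self.graph.edges[src, dst]
            data["provenance"] = data["provenance"] | {provenance}
            # experimental confidence wins over the curated default-to-be
            if e_score is not None:
                data["e_score"] = e_score
        else:
            self.graph.add_edge(
                src, dst, provenance=frozenset({provenance}), e_score=e_score
            )

    def remove_nodes(self, nodes: Iterable[str]) -> None:
        self.graph.remove_nodes_from(list(nodes))

    # -- views --------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def connected_nodes(self) -> set[str]:
        """Nodes with at least one edge in either direction."""
        g = self.graph
        return {n for n in g.nodes if g.in_degree(n) + g.out_degree(n) > 0}

    def copy(self) -> "DiseaseNetwork":
        out = DiseaseNetwork(anchors=self.anchors)
        out.graph = self.graph.copy()
        return out

    # -- (de)serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for src, dst, data in sorted(self.graph.edges(data=True)):
            rows.append(
                {
                    "src": src,
                    "dst": dst,
                    "provenance": "+".join(sorted(data["provenance"])),
                    "e_score": data.get("e_score"),
                    "expr_w": data.get("expr_w"),
                    "weight": data.get("weight"),
                    "cost": data.get("cost"),
                }
            )
        return pd.DataFrame(
            rows, columns=["src", "dst", "provenance", "e_score", "expr_w", "weight", "cost"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, anchors: Optional[StartEndConfig] = None
    ) -> "DiseaseNetwork":
        net = cls(anchors=anchors)
        for row in frame.itertuples(index=False):
            prov = frozenset(row.provenance.split("+"))
            net.graph.add_edge(row.src, row.dst, provenance=prov)
            data = net.graph.edges[row.src, row.dst]
            for col in ("e_score", "expr_w", "weight", "cost"):
                val = getattr(row, col, None)
                if val is not None and pd.notna(val):
                    data[col] = float(val)
                elif col == "e_score":
                    data[col] = None
        return net


@dataclass(frozen=True)
class MergeReport:
    """Bookkeeping of the two-source merge.

    Conservation identities:
    ``n_curated_connected + n_unconnected == n_initial``,
    ``n_rescued + n_removed == n_unconnected``,
    ``n_final == n_initial - n_removed``.
    """

    n_initial: int
    n_curated_connected: int
    n_unconnected: int
    n_rescued: int
    n_removed: int
    n_final: int

    def validate(self) -> None:
        if self.n_curated_connected + self.n_unconnected != self.n_initial:
            raise ValueError("merge report: connected + unconnected != initial")
        if self.n_rescued + self.n_removed != self.n_unconnected:
            raise ValueError("merge report: rescued + removed != unconnected")
        if self.n_final != self.n_initial - self.n_removed:
            raise ValueError("merge report: final != initial - removed")

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_curated_connected": self.n_curated_connected,
            "n_unconnected": self.n_unconnected,
            "n_rescued": self.n_rescued,
            "n_removed": self.n_removed,
            "n_final": self.n_final,
        }


def build_curated(
    candidate_nodes: Iterable[str],
    curated_edges: Iterable[tuple[str, str]],
) -> tuple[DiseaseNetwork, set[str], set[str]]:
    """Build the initial directed network from the curated edge source.

    Edges referencing nodes outside ``candidate_nodes`` are dropped, as
    are self-loops; duplicate rows collapse silently (count logged).
    Returns the network (all candidates present, isolated ones included),
    the set of connected nodes (degree >= 1 either direction) and the set
    of unconnected nodes.
    """
    candidates = set(candidate_nodes)
    net = DiseaseNetwork()
    for n in candidates:
        net.add_node(n)
    n_rows = 0
    for src, dst in curated_edges:
        n_rows += 1
        if src not in candidates or dst not in candidates:
            continue
        net.add_edge(src, dst, provenance=CURATED)
    dup = n_rows - net.n_edges()
    if dup > 0:
        logger.info("curated source: %d duplicate/dropped rows collapsed", dup)
    connected = net.connected_nodes()
    unconnected = candidates - connected
    return net, connected, unconnected


def rescue_experimental(
    net: DiseaseNetwork,
    unconnected: set[str],
    experimental_edges: Iterable[tuple[str, str, float]],
    min_escore: float = 0.0,
) -> tuple[DiseaseNetwork, MergeReport]:
    """Rescue isolated candidates with experimental edges; prune the rest.

    Experimental pairs are undirected in the source; each kept pair is
    expanded to both directed edges because path walks are directional.
    An unconnected node is rescued when it reaches the connected network
    through kept experimental edges (applied iteratively, so chains of
    unconnected nodes hanging off the network are rescued together).
    Nodes still isolated afterwards are removed; experimental edges
    joining two removed nodes are discarded.
    """
    candidates = net.nodes
    n_initial = len(candidates)
    connected = net.connected_nodes()
    unconnected = set(unconnected)

    kept_pairs = []
    adjacency: dict[str, set[str]] = {}
    for a, b, e in experimental_edges:
        if e < min_escore or a == b:
            continue
        if a not in candidates or b not in candidates:
            continue
        kept_pairs.append((a, b, e))
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    # iterative rescue to a fixpoint
    in_network = set(connected)
    rescued: set[str] = set()
    frontier = True
    while frontier:
        frontier = False
        for node in sorted(unconnected - rescued):
            if adjacency.get(node, set()) & in_network:
                rescued.add(node)
                in_network.add(node)
                frontier = True

    removed = unconnected - rescued
    net.remove_nodes(removed)
    for a, b, e in kept_pairs:
        if a in removed or b in removed:
            continue
        net.add_edge(a, b, provenance=EXPERIMENTAL, e_score=e)
        net.add_edge(b, a, provenance=EXPERIMENTAL, e_score=e)

    report = MergeReport(
        n_initial=n_initial,
        n_curated_connected=len(connected),
        n_unconnected=len(unconnected),
        n_rescued=len(rescued),
        n_removed=len(removed),
        n_final=n_initial - len(removed),
    )
    report.validate()
    if removed:
        logger.info("pruned %d nodes that no source could connect", len(removed))
    return net, report


def add_anchors(
    net: DiseaseNetwork,
    config: StartEndConfig,
    ligand_receptor_pairs: Optional[Iterable[tuple[str, str]]] = None,
) -> DiseaseNetwork:
    """Add start/end anchor nodes and directed ligand->receptor edges.

    Idempotent: nodes already present are not duplicated, and repeated
    pair edges collapse onto one edge. A receptor with no downstream
    path is still added — reachability is resolved by the path stage.
    """
    pairs = list(
        ligand_receptor_pairs
        if ligand_receptor_pairs is not None
        else config.ligand_receptor_pairs
    )
    for node in config.start_nodes + config.end_nodes:
        net.add_node(node)
    for lig, rec in pairs:
        net.add_edge(lig, rec, provenance=CURATED)
    net.anchors = config
    return net
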