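"""Expression-derived node weights and final edge weights.

Each node's weight is the absolute log2 fold change (|2logR|) of its
gene between fibrotic (F3/F4) and non-fibrotic (F0) patients; genes
without a measurement weigh 0, which keeps them traversable without
inventing expression signal. An edge's expression component is the mean
of its endpoint node weights, and its final weight is

    weight = e_score + (w(src) + w(dst)) / 2

where curated-only edges receive the default e-score 0.5001. The path
cost per edge is a configurable transform of the weight; the default is
the identity (cost = weight).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from netknock.network import DiseaseNetwork

DEFAULT_ESCORE = 0.5001
EPSILON = 1e-9

#: Available weight→cost transforms. ``identity`` follows the literal
#: "cost = total edge weight" reading; ``complement`` and ``inverse``
#: invert the scale so that high-confidence, high-dysregulation edges
#: become cheap to traverse.
TRANSFORMS = ("identity", "complement", "inverse")

EXPRESSION_COLUMNS = ("gene", "log2fc", "pvalue", "mean_counts")


def validate_expression(stats: pd.DataFrame) -> pd.DataFrame:
    """Check an expression-statistics table (gene, log2fc, pvalue, mean_counts)."""
    missing = [c for c in EXPRESSION_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    dup = stats["gene"][stats["gene"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene rows in expression table: {sorted(set(dup))}")
    if not stats["log2fc"].map(pd.notna).all() or (~stats["log2fc"].abs().lt(float("inf"))).any():
        raise ValueError("log2fc contains missing or non-finite values")
    return stats


def filter_degs(
    stats: pd.DataFrame,
    p_max: float = 0.01,
    up_min: float = 0.5,
    down_max: float = -1.0,
    counts_min: float = 20.0,
) -> set[str]:
    """Differentially expressed genes under the asymmetric threshold rule.

    A gene is kept iff p < 0.01 AND (log2fc > 0.5 OR log2fc < -1) AND
    mean counts > 20 (all inequalities strict). Down-regulation must be
    stronger than up-regulation to count — a fold change of -0.8 fails.
    """
    validate_expression(stats)
    mask = (
        (stats["pvalue"] < p_max)
        & ((stats["log2fc"] > up_min) | (stats["log2fc"] < down_max))
        & (stats["mean_counts"] > counts_min)
    )
    return set(stats.loc[mask, "gene"])


def node_weights(stats: pd.DataFrame, nodes: Iterable[str]) -> dict[str, float]:
    """Node weight = |log2fc| for measured genes, 0 for unmeasured nodes."""
    validate_expression(stats)
    measured = dict(zip(stats["gene"], stats["log2fc"].abs()))
    return {n: float(measured.get(n, 0.0)) for n in nodes}


def _cost(weight: float, transform: str, w_max: float) -> float:
    if transform == "identity":
        return weight
    if transform == "complement":
        return (w_max + EPSILON) - weight
    if transform == "inverse":
        return 1.0 / (weight + EPSILON)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def weight_edges(
    net: DiseaseNetwork,
    node_w: Mapping[str, float],
    default_escore: float = DEFAULT_ESCORE,
    transform: str = "identity",
) -> DiseaseNetwork:
    """Assign e_score, expression component, weight and cost to every edge.

    Curated-only edges get the default e-score; mixed-provenance edges
    keep their experimental e-score. Raises if any resulting cost is
    negative (cannot occur with the shipped transforms on valid inputs,
    but guards user-supplied weight maps).
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    weights = {}
    for src, dst, data in net.graph.edges(data=True):
        e_score = data.get("e_score")
        if e_score is None:
            if "curated" not in data["provenance"]:
                raise ValueError(f"edge {src}->{dst} has no e-score and no curated provenance")
            e_score = default_escore
        expr_w = (node_w.get(src, 0.0) + node_w.get(dst, 0.0)) / 2.0
        weights[(src, dst)] = (e_score, expr_w, e_score + expr_w)
    w_max = max((w for _, _, w in weights.values()), default=0.0)
    for (src, dst), (e_score, expr_w, weight) in weights.items():
        cost = _cost(weight, transform, w_max)
        if cost < 0.0:
            raise ValueError(f"negative cost {cost} on edge {src}->{dst}")
        net.graph.edges[src, dst].update(
            e_score=e_score, expr_w=expr_w, weight=weight, cost=cost
        )
    return net
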