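"""Seed-deterministic synthetic inputs for every pipeline stage.

Real inputs — a curated interaction export, a STRING-like confidence
table, clinical differential-expression statistics and an annotated
abstract corpus — are licensed or large. These generators emulate their
structure at desk scale so every stage is testable offline, and each
fixture ships a ground-truth manifest sufficient to verify downstream
outputs without rerunning the generator.

Two network modes:

* exact-count mode reproduces a requested (connected, rescued, removed)
  merge partition, e.g. (1670 candidates, 999 curated-connected, 665
  rescued) leaving 6 pruned and 1664 final nodes;
* bottleneck mode plants a cheap "highway" of experimental edges from
  every start anchor through one bottleneck node to every end anchor,
  on top of an expensive curated background graph, so the bottleneck
  carries essentially all low-cost start→end routes and is the known
  best knockout target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from netknock.anchors import StartEndConfig
from netknock.textmine import CorpusDocument, TaxonomyTerm


@dataclass
class FixtureSpec:
    """Parameters for all generators; identical specs give identical fixtures."""

    seed: int = 0
    # network (bottleneck mode)
    n_background: int = 50
    n_start: int = 2
    n_end: int = 2
    n_feeders: int = 4
    edge_density: float = 0.06
    bottleneck_nodes: tuple[str, ...] = ("BTLNK",)
    bottleneck_route_fraction: float = 0.9
    highway_escore: float = 0.01
    escore_point_mass: float = 0.3  # P(e-score ≈ 0.5), remainder Beta tail
    escore_beta: tuple[float, float] = (4.0, 1.5)
    # network (exact-count mode): (n_initial, n_connected, n_rescued)
    exact_counts: Optional[tuple[int, int, int]] = None
    # expression
    fraction_dysregulated: float = 0.3
    effect_size_range: tuple[float, float] = (1.0, 3.0)
    # corpus
    n_docs: int = 30
    n_filler_sentences: int = 2


@dataclass
class NetworkFixture:
    candidate_nodes: list[str]
    curated_edges: list[tuple[str, str]]
    experimental_edges: list[tuple[str, str, float]]
    anchors: StartEndConfig
    truth: dict = field(default_factory=dict)


def _draw_escore(rng: np.random.Generator, spec: FixtureSpec) -> float:
    """STRING-like e-score: point mass near 0.5 plus a Beta tail."""
    if rng.random() < spec.escore_point_mass:
        return float(np.clip(rng.normal(0.5, 0.02), 0.0, 1.0))
    a, b = spec.escore_beta
    return float(rng.beta(a, b))


# ---------------------------------------------------------------------------
# network fixtures
# ---------------------------------------------------------------------------


def _exact_count_fixture(spec: FixtureSpec, rng: np.random.Generator) -> NetworkFixture:
    n_initial, n_connected, n_rescued = spec.exact_counts
    n_removed = n_initial - n_connected - n_rescued
    if n_connected < 2 or n_rescued < 0 or n_removed < 0:
        raise ValueError(f"infeasible exact-count request {spec.exact_counts}")
    nodes = [f"G{i:05d}" for i in range(n_initial)]
    connected = nodes[:n_connected]
    rescued = nodes[n_connected : n_connected + n_rescued]
    removed = nodes[n_connected + n_rescued :]

    # preferential-attachment-ish curated core: every connected node gets
    # one outgoing edge to a random earlier node, guaranteeing degree >= 1
    curated = []
    for i in range(1, n_connected):
        j = int(rng.integers(0, i))
        curated.append((connected[i], connected[j]))
    # a few shortcuts for realism
    for _ in range(n_connected // 5):
        i, j = rng.integers(0, n_connected, size=2)
        if i != j:
            curated.append((connected[int(i)], connected[int(j)]))

    # each rescued node attaches to the connected core (or an earlier
    # rescued node, exercising iterative rescue) via an experimental edge
    experimental = []
    for idx, node in enumerate(rescued):
        if idx > 0 and rng.random() < 0.1:
            partner = rescued[int(rng.integers(0, idx))]
        else:
            partner = connected[int(rng.integers(0, n_connected))]
        experimental.append((node, partner, _draw_escore(rng, spec)))

    anchors = _fixture_anchors(spec)
    truth = {
        "mode": "exact_count",
        "n_initial": n_initial,
        "n_curated_connected": n_connected,
        "n_unconnected": n_initial - n_connected,
        "n_rescued": n_rescued,
        "n_removed": n_removed,
        "n_final": n_initial - n_removed,
        "removed_nodes": removed,
    }
    return NetworkFixture(nodes, curated, experimental, anchors, truth)


def _fixture_anchors(spec: FixtureSpec) -> StartEndConfig:
    ligands = tuple(f"LIG{i:02d}" for i in range(spec.n_start))
    receptors = tuple(f"REC{i:02d}" for i in range(spec.n_start))
    ecm = tuple(f"ECM{i:02d}" for i in range(spec.n_end))
    pairs = tuple(zip(ligands, receptors))
    return StartEndConfig(ligands=ligands, receptors=receptors, ecm=ecm,
                          ligand_receptor_pairs=pairs)


def _bottleneck_fixture(spec: FixtureSpec, rng: np.random.Generator) -> NetworkFixture:
    anchors = _fixture_anchors(spec)
    starts = list(anchors.start_nodes)
    ends = list(anchors.end_nodes)
    bottlenecks = list(spec.bottleneck_nodes)
    background = [f"BG{i:03d}" for i in range(spec.n_background)]
    feeders_in = [f"FIN{i:02d}" for i in range(spec.n_feeders)]
    feeders_out = [f"FOUT{i:02d}" for i in range(spec.n_feeders)]

    # curated background: preferential attachment plus random shortcuts;
    # these edges get the default e-score downstream and their endpoints
    # are dysregulated in the paired expression fixture, so background
    # routes are expensive.
    curated = []
    for i in range(1, spec.n_background):
        j = int(rng.integers(0, i))
        curated.append((background[i], background[j]))
        curated.append((background[j], background[i]))
    n_extra = int(spec.edge_density * spec.n_background * (spec.n_background - 1))
    for _ in range(n_extra):
        i, j = rng.integers(0, spec.n_background, size=2)
        if i != j:
            curated.append((background[int(i)], background[int(j)]))
    # end anchors always hang off the background so the curated component
    # is one piece; start anchors get background detours only when some
    # route mass is allowed to bypass the bottleneck.
    for e in ends:
        for bg in rng.choice(spec.n_background, size=3, replace=False):
            curated.append((background[int(bg)], e))
    if spec.bottleneck_route_fraction < 1.0:
        for s in starts:
            for bg in rng.choice(spec.n_background, size=3, replace=False):
                curated.append((s, background[int(bg)]))

    # cheap experimental highway through the bottleneck(s)
    experimental = []

    def highway(a: str, b: str) -> None:
        experimental.append((a, b, spec.highway_escore))

    for btl in bottlenecks:
        for s in starts:
            highway(s, btl)
            for f in feeders_in:
                highway(s, f)
        for f in feeders_in:
            highway(f, btl)
        for f in feeders_out:
            highway(btl, f)
        for e in ends:
            highway(btl, e)
            for f in feeders_out:
                highway(f, e)

    nodes = starts + ends + bottlenecks + feeders_in + feeders_out + background
    truth = {
        "mode": "bottleneck",
        "bottleneck_nodes": bottlenecks,
        "background_nodes": background,
        "route_fraction": spec.bottleneck_route_fraction,
    }
    return NetworkFixture(nodes, curated, experimental, anchors, truth)


def make_network_fixture(spec: FixtureSpec) -> NetworkFixture:
    """Candidate nodes, curated edges, experimental edges and anchors."""
    rng = np.random.default_rng(spec.seed)
    if spec.exact_counts is not None:
        return _exact_count_fixture(spec, rng)
    if spec.n_background < spec.n_start + spec.n_end + len(spec.bottleneck_nodes):
        raise ValueError("n_background too small for the requested anchors")
    return _bottleneck_fixture(spec, rng)


# ---------------------------------------------------------------------------
# expression fixtures
# ---------------------------------------------------------------------------


def make_expression_fixture(
    spec: FixtureSpec,
    nodes: Sequence[str],
    dysregulated: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Differential-expression statistics with planted dysregulated genes.

    Planted genes draw |log2fc| from ``effect_size_range`` (random
    sign), p-values from 10^-U(3, 8) and mean counts well above the DEG
    threshold; background genes sit near log2fc 0 with uniform
    p-values. ``dysregulated`` defaults to a random fraction of nodes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nodes = list(nodes)
    if dysregulated is None:
        n_dys = int(round(spec.fraction_dysregulated * len(nodes)))
        dysregulated = list(rng.choice(nodes, size=n_dys, replace=False))
    dys = set(dysregulated)
    lo, hi = spec.effect_size_range
    rows = []
    for gene in nodes:
        if gene in dys:
            fc = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            p = float(10.0 ** -rng.uniform(3.0, 8.0))
            counts = float(rng.uniform(30.0, 500.0))
        else:
            fc = float(rng.uniform(-0.09, 0.09))
            p = float(rng.uniform(0.0, 1.0))
            counts = float(rng.lognormal(3.5, 1.0))
        rows.append({"gene": gene, "log2fc": fc, "pvalue": p, "mean_counts": counts})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# taxonomy, corpus and PPI fixtures
# ---------------------------------------------------------------------------


def make_taxonomy_fixture(
    proteins: Sequence[str] = ("TGFB1", "PDGFB", "EP300", "COL1A2", "ACTA2", "LOXL2"),
) -> tuple[list[TaxonomyTerm], list[TaxonomyTerm]]:
    """A minimal protein taxonomy and a clustered disease taxonomy."""
    protein_tax = [
        TaxonomyTerm(
            term_id=p,
            canonical_name=p,
            synonyms=(f"{p} protein",),
            kind="protein",
        )
        for p in proteins
    ]
    disease_tax = [
        TaxonomyTerm(
            term_id="D:HSC_ACT",
            canonical_name="hepatic stellate cell activation",
            synonyms=("hepatic stellate cell", "stellate cell activation"),
            kind="disease",
            cluster="HSC",
        ),
        TaxonomyTerm(
            term_id="D:ECM_DEP",
            canonical_name="extracellular matrix deposition",
            synonyms=("extracellular matrix", "collagen deposition"),
            kind="disease",
            cluster="ECM",
        ),
        TaxonomyTerm(
            term_id="D:FIB",
            canonical_name="liver fibrosis",
            synonyms=("hepatic fibrosis",),
            kind="disease",
            cluster="CLINICAL",
        ),
    ]
    return protein_tax, disease_tax


_TEMPLATES = (
    "{protein} promotes {disease} in chronic injury.",
    "Expression of {protein} correlates with {disease} severity.",
    "Inhibition of {protein} attenuates {disease} in vivo.",
)
_FILLERS = (
    "Patients were followed for two years.",
    "Samples were processed with standard protocols.",
    "The cohort included biopsy-confirmed cases.",
)


def make_corpus_fixture(
    spec: FixtureSpec,
    protein_tax: Sequence[TaxonomyTerm],
    disease_tax: Sequence[TaxonomyTerm],
    planted: Optional[dict[tuple[str, str], int]] = None,
) -> tuple[list[CorpusDocument], dict]:
    """Abstracts with planted protein–disease co-occurrences.

    ``planted`` maps (protein_id, cluster) to the number of documents in
    which a co-occurring sentence is planted; by default a random table
    is drawn. Some documents introduce a term through a parenthesized
    acronym definition and use the bare acronym in a later sentence.
    Returns the documents and a ground-truth manifest with the planted
    publication-level counts.
    """
    rng = np.random.default_rng(spec.seed + 2)
    by_cluster: dict[str, list[TaxonomyTerm]] = {}
    for term in disease_tax:
        by_cluster.setdefault(term.cluster, []).append(term)
    if planted is None:
        planted = {}
        for p in protein_tax:
            for cluster in by_cluster:
                n = int(rng.integers(0, 4))
                if n:
                    planted[(p.term_id, cluster)] = n
    protein_by_id = {t.term_id: t for t in protein_tax}

    docs: list[CorpusDocument] = []
    doc_no = 0
    for (protein_id, cluster), n_docs in sorted(planted.items()):
        term = by_cluster[cluster][0]
        for _ in range(n_docs):
            doc_no += 1
            sentences = []
            use_acronym = rng.random() < 0.3 and cluster == "HSC"
            if use_acronym:
                # define via acronym, then use the bare short form
                sentences.append(
                    f"Activation of the hepatic stellate cell (HSC) drives scarring."
                )
                sentences.append(
                    f"{protein_by_id[protein_id].canonical_name} levels rise during HSC expansion."
                )
            else:
                template = _TEMPLATES[int(rng.integers(0, len(_TEMPLATES)))]
                sentences.append(
                    template.format(
                        protein=protein_by_id[protein_id].canonical_name,
                        disease=term.canonical_name,
                    )
                )
            for _ in range(spec.n_filler_sentences):
                sentences.append(_FILLERS[int(rng.integers(0, len(_FILLERS)))])
            rng.shuffle(sentences)
            docs.append(
                CorpusDocument(
                    doc_id=f"PM{doc_no:06d}",
                    year=int(rng.integers(2000, 2024)),
                    title=f"Study {doc_no}",
                    abstract=" ".join(sentences),
                )
            )
    # filler-only documents
    for _ in range(max(0, spec.n_docs - len(docs))):
        doc_no += 1
        sents = [
            _FILLERS[int(rng.integers(0, len(_FILLERS)))]
            for _ in range(1 + spec.n_filler_sentences)
        ]
        docs.append(
            CorpusDocument(
                doc_id=f"PM{doc_no:06d}",
                year=int(rng.integers(2000, 2024)),
                title=f"Study {doc_no}",
                abstract=" ".join(sents),
            )
        )
    truth = {"planted_counts": {f"{p}|{c}": n for (p, c), n in planted.items()}}
    return docs, truth


def make_ppi_fixture(
    spec: FixtureSpec,
    proteins: Sequence[str],
    n_partners: int = 8,
) -> pd.DataFrame:
    """Symmetric PPI neighbor table with interaction scores in [0, 1]."""
    rng = np.random.default_rng(spec.seed + 3)
    rows = []
    proteins = list(proteins)
    for p in proteins:
        partners = [q for q in proteins if q != p]
        chosen = rng.choice(len(partners), size=min(n_partners, len(partners)), replace=False)
        for idx in chosen:
            q = partners[int(idx)]
            if p < q:  # one row per unordered pair
                rows.append({"protein_a": p, "protein_b": q, "score": float(rng.uniform(0.2, 1.0))})
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"]).drop_duplicates(
        subset=["protein_a", "protein_b"]
    )
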