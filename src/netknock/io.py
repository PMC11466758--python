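"""Flat-file readers and writers for every pipeline interface.

All interchange formats are plain text: TSV edge and statistics tables,
JSONL corpora, YAML anchor configs and JSON reports. The weighted
network edge-list TSV round-trips through
:meth:`netknock.network.DiseaseNetwork.to_frame` / ``from_frame``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from netknock.anchors import StartEndConfig
from netknock.fixtures import NetworkFixture
from netknock.knockout import TargetRanking
from netknock.network import DiseaseNetwork
from netknock.textmine import CorpusDocument, TaxonomyTerm


# -- nodes and edges ---------------------------------------------------------


def read_nodes(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_nodes(nodes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(nodes) + "\n")


def read_curated_edges(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["src"], df["dst"]))


def write_curated_edges(edges: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(edges, columns=["src", "dst"]).to_csv(path, sep="\t", index=False)


def read_experimental_edges(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(a, b, float(e)) for a, b, e in zip(df["protein_a"], df["protein_b"], df["e_score"])]


def write_experimental_edges(edges: Iterable[tuple[str, str, float]], path) -> None:
    pd.DataFrame(edges, columns=["protein_a", "protein_b", "e_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_network(path, anchors: Optional[StartEndConfig] = None) -> DiseaseNetwork:
    return DiseaseNetwork.from_frame(pd.read_csv(path, sep="\t"), anchors=anchors)


def write_network(net: DiseaseNetwork, path) -> None:
    net.to_frame().to_csv(path, sep="\t", index=False)


# -- expression and PPI tables ----------------------------------------------


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_ppi(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ppi(ppi: pd.DataFrame, path) -> None:
    ppi.to_csv(path, sep="\t", index=False)


# -- corpus and taxonomies ---------------------------------------------------


def read_corpus(path, min_year: Optional[int] = None) -> list[CorpusDocument]:
    docs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            doc = CorpusDocument(
                doc_id=str(rec["id"]),
                year=int(rec["year"]),
                title=rec.get("title", ""),
                abstract=rec.get("abstract", rec.get("text", "")),
            )
            if min_year is None or doc.year >= min_year:
                docs.append(doc)
    return docs


def write_corpus(docs: Iterable[CorpusDocument], path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "id": doc.doc_id,
                        "year": doc.year,
                        "title": doc.title,
                        "abstract": doc.abstract,
                    }
                )
                + "\n"
            )


def read_taxonomy(path) -> list[TaxonomyTerm]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    terms = []
    for row in df.itertuples(index=False):
        synonyms = tuple(s for s in str(row.synonyms).split("|") if s)
        cluster = getattr(row, "cluster", "") or None
        terms.append(
            TaxonomyTerm(
                term_id=row.term_id,
                canonical_name=row.canonical_name,
                synonyms=synonyms,
                kind=row.kind,
                cluster=cluster,
            )
        )
    return terms


def write_taxonomy(terms: Iterable[TaxonomyTerm], path) -> None:
    pd.DataFrame(
        [
            {
                "term_id": t.term_id,
                "canonical_name": t.canonical_name,
                "synonyms": "|".join(t.synonyms),
                "cluster": t.cluster or "",
                "kind": t.kind,
            }
            for t in terms
        ]
    ).to_csv(path, sep="\t", index=False)


# -- rankings and reports ----------------------------------------------------


def write_ranking(rankings: Sequence[TargetRanking], path) -> None:
    pd.DataFrame(
        [
            {
                "node": r.node,
                "n_pairs_disconnected": r.n_pairs_disconnected,
                "sum_delta": r.sum_delta,
                "max_delta": r.max_delta,
                "n_pairs_affected": r.n_pairs_affected,
                "rank": r.rank,
                "blocked": r.blocked,
            }
            for r in rankings
        ]
    ).to_csv(path, sep="\t", index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def write_fixture_dir(fixture: NetworkFixture, expr: pd.DataFrame, out_dir) -> None:
    """Write nodes.txt, ipa.tsv, string.tsv, expr.tsv, anchors.yaml, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nodes(fixture.candidate_nodes, out / "nodes.txt")
    write_curated_edges(fixture.curated_edges, out / "ipa.tsv")
    write_experimental_edges(fixture.experimental_edges, out / "string.tsv")
    write_expression(expr, out / "expr.tsv")
    fixture.anchors.to_yaml(out / "anchors.yaml")
    write_report(fixture.truth, out / "truth.json")
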