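"""Text-mining node selection: co-occurrence and hub scoring over abstracts.

Candidate disease-network nodes are chosen from a literature corpus by
four measures per protein:

1. m1 — distinct publications where the protein co-occurs in a sentence
   with a disease term of the hepatic-stellate-cell (HSC) cluster;
2. m2 — number of high-confidence interaction partners (score > 0.9)
   that are themselves disease-associated ("fibrotic neighbors");
3. m3 — (disease publications / total publications mentioning the
   protein) + (fibrotic neighbors / total neighbors), each ratio 0 when
   its denominator is 0;
4. m4 — distinct publications with a co-occurrence in any disease
   cluster.

The union of the top-N proteins (default 600) under each measure is the
node set. Co-occurrence is scored at the publication level: a (protein,
cluster) pair counts at most once per document however many sentences
qualify.

Tokenization is a small self-contained regex tokenizer with rule-based
plural lemmatization; term matching runs over lemmatized, case-folded
n-grams, longest-match-first then leftmost, non-overlapping. Acronyms
defined in a document ("hepatic stellate cell (HSC)") extend the
synonym index for that document only.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

MIN_PPI_SCORE = 0.9
DEFAULT_TOP_N = 600
MIN_YEAR = 2000

_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")
_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-/']*|[()]|[.,;:!?]")
_PUNCT = {".", ",", ";", ":", "!", "?", "(", ")"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonomyTerm:
    """One taxonomy entry: a protein or a clustered disease concept."""

    term_id: str
    canonical_name: str
    synonyms: tuple[str, ...]
    kind: str  # "protein" | "disease"
    cluster: Optional[str] = None  # disease terms only

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError(f"term {self.term_id}: empty canonical name")
        if self.kind not in ("protein", "disease"):
            raise ValueError(f"term {self.term_id}: kind must be protein or disease")
        if self.kind == "disease" and not self.cluster:
            raise ValueError(f"disease term {self.term_id} has no cluster")
        folded = [s.lower() for s in self.synonyms]
        if len(set(folded)) != len(folded):
            raise ValueError(f"term {self.term_id}: duplicate synonyms after case-folding")

    def surface_forms(self) -> tuple[str, ...]:
        return (self.canonical_name,) + self.synonyms


@dataclass(frozen=True)
class CorpusDocument:
    doc_id: str
    year: int
    title: str
    abstract: str


@dataclass(frozen=True)
class Token:
    text: str
    lemma: str


@dataclass(frozen=True)
class SentenceAnnotation:
    doc_id: str
    sentence_index: int
    protein_hits: frozenset[str]
    disease_hits: frozenset[tuple[str, str]]  # (term_id, cluster)


@dataclass
class ProteinRankRecord:
    protein_id: str
    m1_hsc_pubs: int
    m2_fibrotic_neighbors: int
    m3_ratio_sum: float
    m4_total_fibrosis_pubs: int
    rank_m1: int = 0
    rank_m2: int = 0
    rank_m3: int = 0
    rank_m4: int = 0


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------


def lemmatize(word: str) -> str:
    """Case-fold and strip regular plural suffixes (cells→cell, HSCs→hsc)."""
    w = word.lower()
    if len(w) > 3 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and w.endswith(("ches", "shes", "sses", "xes", "zes")):
        return w[:-2]
    if len(w) > 2 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def split_sentences(text: str) -> list[list[Token]]:
    """Split text into sentences, each an ordered list of tokens.

    Tokens keep their original surface form alongside the lemmatized,
    case-folded form; parentheses and sentence punctuation survive as
    their own tokens so acronym detection can see them. An empty input
    yields an empty list.
    """
    text = text.strip()
    if not text:
        return []
    sentences = []
    for raw in _SENTENCE_RE.split(text):
        tokens = [Token(text=t, lemma=lemmatize(t)) for t in _TOKEN_RE.findall(raw)]
        if tokens:
            sentences.append(tokens)
    return sentences


# ---------------------------------------------------------------------------
# acronym detection (Schwartz–Hearst style)
# ---------------------------------------------------------------------------


def _is_acronym_candidate(word: str) -> bool:
    if not (2 <= len(word) <= 10):
        return False
    if not any(ch.isalpha() for ch in word):
        return False
    return word[0].isalnum()


def _chars_in_order(definition: str, acronym: str) -> bool:
    it = iter(definition.lower())
    return all(ch in it for ch in acronym.lower() if ch.isalnum())


def detect_acronyms(sentence_tokens: Sequence[Token]) -> list[tuple[str, str]]:
    """Find (acronym, definition) pairs of the form "long form (SF)".

    The acronym sits alone inside parentheses, is 2–10 characters with
    at least one letter (all-numeric parentheticals such as years are
    rejected), and the definition is the shortest immediately preceding
    token span containing all acronym characters in order,
    case-insensitively, with at most min(len+5, 2·len) words.
    """
    pairs = []
    texts = [t.text for t in sentence_tokens]
    for i in range(len(texts) - 2):
        if texts[i] != "(" or texts[i + 2] != ")":
            continue
        acronym = texts[i + 1]
        if not _is_acronym_candidate(acronym) or acronym.isdigit():
            continue
        max_words = min(len(acronym) + 5, len(acronym) * 2)
        # candidate definition words: contiguous non-punctuation run before "("
        j = i
        preceding = []
        while j > 0 and texts[j - 1] not in _PUNCT and len(preceding) < max_words:
            j -= 1
            preceding.insert(0, texts[j])
        for span_len in range(1, len(preceding) + 1):
            span = preceding[len(preceding) - span_len :]
            definition = " ".join(span)
            if _chars_in_order(definition, acronym):
                pairs.append((acronym, definition))
                break
    return pairs


# ---------------------------------------------------------------------------
# taxonomy index and annotation
# ---------------------------------------------------------------------------


class TermIndex:
    """Synonym index over lemmatized n-grams, supporting doc-local extension."""

    def __init__(self, terms: Iterable[TaxonomyTerm]) -> None:
        self.terms = list(terms)
        self._index: dict[tuple[str, ...], list[TaxonomyTerm]] = defaultdict(list)
        self.max_len = 1
        for term in self.terms:
            for surface in term.surface_forms():
                self._add_surface(surface, term)

    def _add_surface(self, surface: str, term: TaxonomyTerm) -> None:
        key = tuple(
            lemmatize(t) for t in _TOKEN_RE.findall(surface) if t not in _PUNCT
        )
        if not key:
            return
        if term not in self._index[key]:
            self._index[key].append(term)
        self.max_len = max(self.max_len, len(key))

    def lookup(self, ngram: tuple[str, ...]) -> list[TaxonomyTerm]:
        return self._index.get(ngram, [])

    def with_acronyms(self, acronyms: Iterable[tuple[str, str]]) -> "TermIndex":
        """A copy extended with acronyms whose definitions resolve to known terms."""
        clone = TermIndex([])
        clone.terms = self.terms
        clone._index = defaultdict(list, {k: list(v) for k, v in self._index.items()})
        clone.max_len = self.max_len
        for acronym, definition in acronyms:
            def_key = tuple(
                lemmatize(t) for t in _TOKEN_RE.findall(definition) if t not in _PUNCT
            )
            for term in self._index.get(def_key, []):
                clone._add_surface(acronym, term)
        return clone


def _match_sentence(
    tokens: Sequence[Token], index: TermIndex
) -> list[tuple[int, int, list[TaxonomyTerm]]]:
    """Non-overlapping term matches, longest-match-first then leftmost."""
    lemmas = [t.lemma for t in tokens]
    candidates = []
    for start in range(len(lemmas)):
        for length in range(min(index.max_len, len(lemmas) - start), 0, -1):
            ngram = tuple(lemmas[start : start + length])
            terms = index.lookup(ngram)
            if terms:
                candidates.append((start, length, terms))
    candidates.sort(key=lambda c: (-c[1], c[0]))
    taken = [False] * len(lemmas)
    matches = []
    for start, length, terms in candidates:
        if any(taken[start : start + length]):
            continue
        for i in range(start, start + length):
            taken[i] = True
        matches.append((start, length, terms))
    matches.sort(key=lambda c: c[0])
    return matches


def annotate(
    doc: CorpusDocument,
    protein_tax: Iterable[TaxonomyTerm] | TermIndex,
    disease_tax: Iterable[TaxonomyTerm] | TermIndex,
) -> list[SentenceAnnotation]:
    """Annotate one document; keep sentences with a protein AND a disease hit.

    Acronyms defined anywhere in the document extend both synonym
    indexes for this document only, so a bare acronym in a later
    sentence inherits the term of its spelled-out definition.
    """
    protein_index = protein_tax if isinstance(protein_tax, TermIndex) else TermIndex(protein_tax)
    disease_index = disease_tax if isinstance(disease_tax, TermIndex) else TermIndex(disease_tax)
    sentences = split_sentences(doc.abstract)
    acronyms = []
    for tokens in sentences:
        acronyms.extend(detect_acronyms(tokens))
    if acronyms:
        protein_index = protein_index.with_acronyms(acronyms)
        disease_index = disease_index.with_acronyms(acronyms)
    annotations = []
    for idx, tokens in enumerate(sentences):
        protein_hits = {
            t.term_id
            for _, _, terms in _match_sentence(tokens, protein_index)
            for t in terms
        }
        disease_hits = {
            (t.term_id, t.cluster)
            for _, _, terms in _match_sentence(tokens, disease_index)
            for t in terms
        }
        if protein_hits and disease_hits:
            annotations.append(
                SentenceAnnotation(
                    doc_id=doc.doc_id,
                    sentence_index=idx,
                    protein_hits=frozenset(protein_hits),
                    disease_hits=frozenset(disease_hits),
                )
            )
    return annotations


def annotate_corpus(
    docs: Iterable[CorpusDocument],
    protein_tax: Iterable[TaxonomyTerm],
    disease_tax: Iterable[TaxonomyTerm],
    min_year: int = MIN_YEAR,
) -> list[SentenceAnnotation]:
    """Annotate every document at or after ``min_year``."""
    protein_index = TermIndex(protein_tax)
    disease_index = TermIndex(disease_tax)
    out: list[SentenceAnnotation] = []
    for doc in docs:
        if doc.year < min_year:
            continue
        out.extend(annotate(doc, protein_index, disease_index))
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_cooccurrence(
    annotations: Iterable[SentenceAnnotation],
) -> dict[str, dict[str, int]]:
    """Publication-level co-occurrence counts per protein per disease cluster.

    A (protein, cluster) pair counts at most once per document, however
    many sentences in that document qualify.
    """
    seen: set[tuple[str, str, str]] = set()
    for ann in annotations:
        clusters = {cluster for _, cluster in ann.disease_hits}
        for protein in ann.protein_hits:
            for cluster in clusters:
                seen.add((ann.doc_id, protein, cluster))
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for _, protein, cluster in seen:
        counts[protein][cluster] += 1
    return {p: dict(c) for p, c in counts.items()}


def disease_publication_counts(
    annotations: Iterable[SentenceAnnotation],
) -> dict[str, int]:
    """Distinct publications with a co-occurrence in any cluster, per protein."""
    docs: dict[str, set[str]] = defaultdict(set)
    for ann in annotations:
        for protein in ann.protein_hits:
            docs[protein].add(ann.doc_id)
    return {p: len(d) for p, d in docs.items()}


def protein_publication_counts(
    docs: Iterable[CorpusDocument],
    protein_tax: Iterable[TaxonomyTerm],
    min_year: int = MIN_YEAR,
) -> dict[str, int]:
    """Distinct publications mentioning each protein in any context."""
    index = TermIndex(protein_tax)
    pubs: dict[str, set[str]] = defaultdict(set)
    for doc in docs:
        if doc.year < min_year:
            continue
        sentences = split_sentences(doc.abstract)
        acronyms = []
        for tokens in sentences:
            acronyms.extend(detect_acronyms(tokens))
        doc_index = index.with_acronyms(acronyms) if acronyms else index
        for tokens in sentences:
            for _, _, terms in _match_sentence(tokens, doc_index):
                for term in terms:
                    pubs[term.term_id].add(doc.doc_id)
    return {p: len(d) for p, d in pubs.items()}


def score_fibrotic_neighbors(
    protein_id: str,
    ppi_table: pd.DataFrame,
    fibrosis_set: set[str],
    min_score: float = MIN_PPI_SCORE,
) -> tuple[int, int]:
    """(fibrotic_neighbors, total_neighbors) at high interaction confidence.

    Partners are counted once each, over rows in either orientation,
    with interaction score strictly greater than ``min_score``; the
    fibrotic subset is the intersection with ``fibrosis_set``. A
    protein absent from the table has (0, 0).
    """
    if ppi_table.empty:
        return 0, 0
    high = ppi_table[ppi_table["score"] > min_score]
    partners = set(high.loc[high["protein_a"] == protein_id, "protein_b"]) | set(
        high.loc[high["protein_b"] == protein_id, "protein_a"]
    )
    partners.discard(protein_id)
    return len(partners & fibrosis_set), len(partners)


def compute_rank_records(
    docs: Sequence[CorpusDocument],
    protein_tax: Sequence[TaxonomyTerm],
    disease_tax: Sequence[TaxonomyTerm],
    ppi_table: pd.DataFrame,
    hsc_cluster: str = "HSC",
    min_score: float = MIN_PPI_SCORE,
    min_year: int = MIN_YEAR,
    fibrosis_set: Optional[set[str]] = None,
) -> list[ProteinRankRecord]:
    """The four ranking measures for every protein in the taxonomy.

    ``fibrosis_set`` (proteins counted as disease-associated for hub
    scoring) defaults to the proteins with at least one disease
    co-occurrence in this corpus.
    """
    annotations = annotate_corpus(docs, protein_tax, disease_tax, min_year=min_year)
    cooc = score_cooccurrence(annotations)
    m4_counts = disease_publication_counts(annotations)
    total_pubs = protein_publication_counts(docs, protein_tax, min_year=min_year)
    if fibrosis_set is None:
        fibrosis_set = {p for p, n in m4_counts.items() if n > 0}
    records = []
    for term in sorted(protein_tax, key=lambda t: t.term_id):
        if term.kind != "protein":
            continue
        pid = term.term_id
        fib_nb, tot_nb = score_fibrotic_neighbors(pid, ppi_table, fibrosis_set, min_score)
        m4 = m4_counts.get(pid, 0)
        tot_p = total_pubs.get(pid, 0)
        ratio_pubs = m4 / tot_p if tot_p else 0.0
        ratio_nb = fib_nb / tot_nb if tot_nb else 0.0
        records.append(
            ProteinRankRecord(
                protein_id=pid,
                m1_hsc_pubs=cooc.get(pid, {}).get(hsc_cluster, 0),
                m2_fibrotic_neighbors=fib_nb,
                m3_ratio_sum=ratio_pubs + ratio_nb,
                m4_total_fibrosis_pubs=m4,
            )
        )
    return records


# ---------------------------------------------------------------------------
# ranking and selection
# ---------------------------------------------------------------------------

_MEASURES = (
    ("m1_hsc_pubs", "rank_m1"),
    ("m2_fibrotic_neighbors", "rank_m2"),
    ("m3_ratio_sum", "rank_m3"),
    ("m4_total_fibrosis_pubs", "rank_m4"),
)


def rank_and_select(
    records: Sequence[ProteinRankRecord],
    top_n: int = DEFAULT_TOP_N,
) -> set[str]:
    """Union of the top-N proteins under each of the four measures.

    Per measure, records are ordered by descending value with boundary
    ties broken by descending m4 then lexicographic identifier; dense
    ranks are written back onto the records. Fewer than N records under
    a measure simply selects them all. The result is independent of
    input order.
    """
    selected: set[str] = set()
    for measure, rank_attr in _MEASURES:
        ordered = sorted(
            records,
            key=lambda r: (
                -getattr(r, measure),
                -r.m4_total_fibrosis_pubs,
                r.protein_id,
            ),
        )
        # dense ranks: equal measure values share a rank
        rank = 0
        previous = object()
        for rec in ordered:
            value = getattr(rec, measure)
            if value != previous:
                rank += 1
                previous = value
            setattr(rec, rank_attr, rank)
        selected.update(rec.protein_id for rec in ordered[:top_n])
    return selected


def signature_recall(selected: set[str], signature: Sequence[str]) -> tuple[int, int]:
    """How many genes of a known disease signature the selection recovers."""
    sig = set(signature)
    return len(selected & sig), len(sig)


def records_to_frame(records: Sequence[ProteinRankRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "m1_hsc_pubs": r.m1_hsc_pubs,
                "m2_fibrotic_neighbors": r.m2_fibrotic_neighbors,
                "m3_ratio_sum": r.m3_ratio_sum,
                "m4_total_fibrosis_pubs": r.m4_total_fibrosis_pubs,
                "rank_m1": r.rank_m1,
                "rank_m2": r.rank_m2,
                "rank_m3": r.rank_m3,
                "rank_m4": r.rank_m4,
            }
            for r in records
        ]
    )
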