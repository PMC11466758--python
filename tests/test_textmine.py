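"""Text-mining stage: tokenization, acronyms, annotation, scoring, selection."""

from __future__ import annotations

import pandas as pd
import pytest

from netknock.fixtures import FixtureSpec, make_corpus_fixture
from netknock.textmine import (
    CorpusDocument,
    ProteinRankRecord,
    annotate,
    annotate_corpus,
    detect_acronyms,
    rank_and_select,
    score_cooccurrence,
    score_fibrotic_neighbors,
    signature_recall,
    split_sentences,
)


class TestSplitSentences:
    def test_two_terminal_periods_give_two_sentences(self):
        sentences = split_sentences("HSCs produce collagen. TGFB1 drives this.")
        assert len(sentences) == 2

    def test_empty_abstract_gives_empty_list(self):
        assert split_sentences("") == []

    def test_token_multiset_matches_hand_tokenization(self):
        text = (
            "Hepatic stellate cells produce collagen. "
            "TGFB1 activates them strongly. Fibrosis follows."
        )
        sentences = split_sentences(text)
        assert len(sentences) == 3
        observed = sorted(t.text for s in sentences for t in s)
        expected = sorted(
            [
                "Hepatic", "stellate", "cells", "produce", "collagen", ".",
                "TGFB1", "activates", "them", "strongly", ".",
                "Fibrosis", "follows", ".",
            ]
        )
        assert observed == expected
        # lemmas are case-folded and singularized
        lemmas = {t.lemma for s in sentences for t in s}
        assert "cell" in lemmas and "tgfb1" in lemmas

    def test_concatenated_sentences_cover_all_words(self):
        text = "One sentence here. Another one there."
        words_in = [w.strip(".") for w in text.split()]
        tokens = [t.text for s in split_sentences(text) for t in s if t.text != "."]
        assert tokens == words_in


class TestDetectAcronyms:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("hepatic stellate cell (HSC)", [("HSC", "hepatic stellate cell")]),
            ("(2015)", []),
            ("extracellular matrix (ECM) remodeling", [("ECM", "extracellular matrix")]),
            ("no parenthetical here", []),
        ],
    )
    def test_schwartz_hearst_rules(self, text, expected):
        tokens = split_sentences(text + ".")[0] if text else []
        assert detect_acronyms(tokens) == expected

    def test_definition_word_limit(self):
        # 2-letter acronym allows at most min(2+5, 2*2)=4 definition words,
        # so a definition needing 7 words is rejected
        tokens = split_sentences("quick a b c d e zebra (QZ).")[0]
        assert detect_acronyms(tokens) == []
        # within the limit the same letters are found
        tokens = split_sentences("quick zebra (QZ).")[0]
        assert detect_acronyms(tokens) == [("QZ", "quick zebra")]


class TestAnnotate:
    def test_sentence_with_both_hits_is_annotated(self, taxonomies):
        prot, dis = taxonomies
        doc = CorpusDocument("d1", 2020, "t", "TGFB1 drives hepatic stellate cell activation.")
        anns = annotate(doc, prot, dis)
        assert len(anns) == 1
        assert "TGFB1" in anns[0].protein_hits
        assert ("D:HSC_ACT", "HSC") in anns[0].disease_hits

    def test_protein_only_sentence_excluded(self, taxonomies):
        prot, dis = taxonomies
        doc = CorpusDocument("d1", 2020, "t", "TGFB1 was measured in plasma.")
        assert annotate(doc, prot, dis) == []

    def test_acronym_defined_early_resolves_later_bare_use(self, taxonomies):
        prot, dis = taxonomies
        doc = CorpusDocument(
            "d1",
            2020,
            "t",
            "Activation of the hepatic stellate cell (HSC) drives scarring. "
            "Controls were included. "
            "TGFB1 levels rise during HSC expansion.",
        )
        anns = annotate(doc, prot, dis)
        assert any(
            a.sentence_index == 2 and ("D:HSC_ACT", "HSC") in a.disease_hits for a in anns
        )

    def test_longest_match_wins_over_nested_term(self, taxonomies):
        prot, dis = taxonomies
        # "hepatic stellate cell activation" (canonical) contains the
        # shorter synonym "hepatic stellate cell"; only the long form hits
        doc = CorpusDocument("d1", 2020, "t", "TGFB1 causes hepatic stellate cell activation.")
        anns = annotate(doc, prot, dis)
        assert anns[0].disease_hits == frozenset({("D:HSC_ACT", "HSC")})


class TestScoreCooccurrence:
    def test_publication_level_counts_once_per_document(self, taxonomies):
        prot, dis = taxonomies
        sentence = "TGFB1 drives hepatic stellate cell activation."
        doc = CorpusDocument("d1", 2020, "t", " ".join([sentence] * 3))
        anns = annotate(doc, prot, dis)
        assert len(anns) == 3
        counts = score_cooccurrence(anns)
        assert counts["TGFB1"]["HSC"] == 1

    def test_empty_annotations_give_empty_map(self):
        assert score_cooccurrence([]) == {}

    def test_planted_corpus_counts_match_design(self, taxonomies):
        prot, dis = taxonomies
        planted = {("TGFB1", "HSC"): 3, ("EP300", "ECM"): 2, ("PDGFB", "CLINICAL"): 1}
        docs, truth = make_corpus_fixture(FixtureSpec(seed=11), prot, dis, planted=planted)
        counts = score_cooccurrence(annotate_corpus(docs, prot, dis))
        observed = {f"{p}|{c}": n for p, per in counts.items() for c, n in per.items()}
        assert observed == truth["planted_counts"]

    def test_duplicating_sentences_is_idempotent(self, taxonomies):
        prot, dis = taxonomies
        docs, _ = make_corpus_fixture(FixtureSpec(seed=5), prot, dis)
        base = score_cooccurrence(annotate_corpus(docs, prot, dis))
        doubled = [
            CorpusDocument(d.doc_id, d.year, d.title, d.abstract + " " + d.abstract)
            for d in docs
        ]
        assert score_cooccurrence(annotate_corpus(doubled, prot, dis)) == base

    def test_adding_a_document_never_decreases_counts(self, taxonomies):
        prot, dis = taxonomies
        docs, _ = make_corpus_fixture(FixtureSpec(seed=6), prot, dis)
        base = score_cooccurrence(annotate_corpus(docs, prot, dis))
        extra = CorpusDocument("dX", 2021, "t", "EP300 worsens liver fibrosis.")
        grown = score_cooccurrence(annotate_corpus(docs + [extra], prot, dis))
        for p, per in base.items():
            for c, n in per.items():
                assert grown[p][c] >= n


class TestFibroticNeighbors:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])

    def test_strict_threshold_keeps_only_above(self):
        table = self._table(
            [("P", "A", 0.95), ("P", "B", 0.9), ("P", "C", 0.3)]
        )
        assert score_fibrotic_neighbors("P", table, {"A"}) == (1, 1)

    def test_empty_table(self):
        assert score_fibrotic_neighbors("P", self._table([]), {"A"}) == (0, 0)

    def test_planted_neighbor_bookkeeping(self):
        rows = [("P", f"N{i}", 0.99) for i in range(10)]
        table = self._table(rows)
        fibrosis = {f"N{i}" for i in range(4)}
        assert score_fibrotic_neighbors("P", table, fibrosis) == (4, 10)

    def test_symmetric_rows_counted_once(self):
        table = self._table([("P", "A", 0.95), ("A", "P", 0.95)])
        assert score_fibrotic_neighbors("P", table, set()) == (0, 1)

    @pytest.mark.parametrize("lo,hi", [(0.5, 0.9), (0.7, 0.95)])
    def test_raising_min_score_never_increases_counts(self, lo, hi):
        rows = [("P", f"N{i}", 0.5 + 0.05 * i) for i in range(10)]
        table = self._table(rows)
        fibrosis = {"N8", "N9"}
        fib_lo, tot_lo = score_fibrotic_neighbors("P", table, fibrosis, min_score=lo)
        fib_hi, tot_hi = score_fibrotic_neighbors("P", table, fibrosis, min_score=hi)
        assert fib_hi <= fib_lo and tot_hi <= tot_lo


def _record(pid, m1=0, m2=0, m3=0.0, m4=0):
    return ProteinRankRecord(pid, m1, m2, m3, m4)


class TestRankAndSelect:
    def test_disjoint_top_lists_union(self):
        # four groups of proteins, each dominating exactly one measure
        records = []
        for i in range(3):
            records.append(_record(f"A{i}", m1=100 - i))
            records.append(_record(f"B{i}", m2=100 - i))
            records.append(_record(f"C{i}", m3=float(100 - i)))
            records.append(_record(f"D{i}", m4=100 - i))
        selected = rank_and_select(records, top_n=3)
        assert {f"A{i}" for i in range(3)} <= selected
        assert {f"B{i}" for i in range(3)} <= selected
        assert len(selected) == 12

    def test_identical_rankings_collapse_to_top_n(self):
        records = [_record(f"P{i:02d}", m1=50 - i, m2=50 - i, m3=float(50 - i), m4=50 - i)
                   for i in range(50)]
        assert len(rank_and_select(records, top_n=10)) == 10

    def test_fewer_records_than_top_n_selects_all(self):
        records = [_record(f"P{i}", m1=i) for i in range(5)]
        assert len(rank_and_select(records, top_n=600)) == 5

    def test_invariant_under_input_permutation(self):
        records = [
            _record(f"P{i:02d}", m1=i % 7, m2=i % 5, m3=i % 3 / 2, m4=i % 11)
            for i in range(40)
        ]
        forward = rank_and_select(list(records), top_n=8)
        backward = rank_and_select(list(reversed(records)), top_n=8)
        assert forward == backward

    def test_m3_ratio_sum_in_bounds(self, taxonomies):
        from netknock.fixtures import make_ppi_fixture
        from netknock.textmine import compute_rank_records

        prot, dis = taxonomies
        docs, _ = make_corpus_fixture(FixtureSpec(seed=9), prot, dis)
        ppi = make_ppi_fixture(FixtureSpec(seed=9), [t.term_id for t in prot])
        for rec in compute_rank_records(docs, prot, dis, ppi):
            assert 0.0 <= rec.m3_ratio_sum <= 2.0


class TestSignatureRecall:
    def test_full_recall(self):
        assert signature_recall({"A", "B", "C"}, ["A", "B"]) == (2, 2)

    def test_disjoint_sets(self):
        assert signature_recall({"A"}, ["X", "Y", "Z"]) == (0, 3)

    def test_empty_signature(self):
        assert signature_recall({"A"}, []) == (0, 0)

    def test_partial_recall_ratio(self):
        signature = [f"S{i}" for i in range(90)]
        selected = set(signature[:83]) | {"OTHER"}
        assert signature_recall(selected, signature) == (83, 90)
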