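"""Dictionary annotation engine: exact token-bounded matching, tf
aggregation, stop words, scope, idf."""

import math

import pytest

from litrdf import (
    AnnotatorConfig,
    CorpusStats,
    LexiconEntry,
    annotate_document,
    compute_idf,
    corpus_stats,
)
from litrdf.annotate import naive_count
from litrdf.fixtures import make_corpus, make_jats, tables_lexicon
from litrdf.jats import parse_jats
from litrdf.model import DocumentRecord, ParagraphNode, SectionNode


def doc_from_texts(pmcid, texts, title="", abstract=None):
    paragraphs = [
        ParagraphNode(paragraph_id=f"{pmcid}_paragraph_S_para_{i}", text=t)
        for i, t in enumerate(texts, start=1)
    ]
    return DocumentRecord(
        pmcid=pmcid,
        title=title,
        abstract=abstract,
        body=[SectionNode(section_id=f"{pmcid}_section_S", title="S", children=paragraphs)],
    )


class TestMatching:
    def test_pcr_sentence_matches_snomed_concept(self, snomed_lexicon):
        doc = doc_from_texts(
            "1", ["Genomic DNA was amplified by polymerase chain reaction."]
        )
        records = annotate_document(doc, snomed_lexicon)
        assert len(records) == 1
        rec = records[0]
        assert rec.body_text == "Polymerase chain reaction"
        assert rec.topics == {"http://purl.bioontology.org/ontology/SNOMEDCT/258066000"}
        assert rec.tf == 1

    def test_empty_body_yields_no_annotations(self, snomed_lexicon):
        doc = DocumentRecord(pmcid="1")
        assert annotate_document(doc, snomed_lexicon) == []

    def test_empty_lexicon_is_not_an_error(self):
        doc = doc_from_texts("1", ["Whole blood here."])
        assert annotate_document(doc, []) == []

    def test_same_surface_in_two_paragraphs_aggregates(self, snomed_lexicon):
        doc = doc_from_texts(
            "1", ["Samples of whole blood were drawn.", "More whole blood was stored."]
        )
        records = annotate_document(doc, snomed_lexicon)
        assert len(records) == 1
        assert records[0].tf == 2
        assert records[0].targets == [
            "1_paragraph_S_para_1",
            "1_paragraph_S_para_2",
        ]

    def test_multiple_hits_in_one_paragraph_counted_once_per_target(self, snomed_lexicon):
        doc = doc_from_texts("1", ["Tobacco and more tobacco, tobacco again."])
        (rec,) = annotate_document(doc, snomed_lexicon)
        assert rec.tf == 3
        assert rec.targets == ["1_paragraph_S_para_1"]

    def test_token_boundaries_prevent_substring_hits(self, snomed_lexicon):
        doc = doc_from_texts("1", ["The ajccx code and subAJCC variants do not count."])
        assert annotate_document(doc, snomed_lexicon) == []

    def test_longest_match_wins_over_embedded_term(self, snomed_lexicon):
        # "Deoxyribonucleic acid extraction technique" embeds no shorter
        # lexicon term, so add one that overlaps with "Tobacco user".
        doc = doc_from_texts("1", ["A tobacco user was enrolled."])
        records = annotate_document(doc, snomed_lexicon)
        assert [r.body_text for r in records] == ["Tobacco user"]

    def test_case_insensitive_by_default_case_sensitive_optional(self, snomed_lexicon):
        doc = doc_from_texts("1", ["CARCINOMA was diagnosed."])
        assert len(annotate_document(doc, snomed_lexicon)) == 1
        cfg = AnnotatorConfig(case_sensitive=True)
        assert annotate_document(doc, snomed_lexicon, cfg) == []

    def test_shared_surface_unions_topics(self):
        lex = [
            LexiconEntry("insulin", "http://x/ncit/1", "NCIT"),
            LexiconEntry("Insulin", "http://x/snomed/2", "SNOMEDCT"),
        ]
        doc = doc_from_texts("1", ["insulin signalling"])
        (rec,) = annotate_document(doc, lex)
        assert rec.topics == {"http://x/ncit/1", "http://x/snomed/2"}

    def test_ontology_restriction(self, extended_lexicon):
        doc = doc_from_texts("1", ["Chloroplast DNA and whole blood."])
        cfg = AnnotatorConfig(ontologies=frozenset({"SNOMEDCT"}))
        records = annotate_document(doc, extended_lexicon, cfg)
        assert [r.body_text for r in records] == ["Whole blood"]


class TestStopWords:
    def test_stop_word_removes_exactly_that_surface(self, snomed_lexicon):
        doc = doc_from_texts("1", ["Tobacco and whole blood and carcinoma."])
        base = annotate_document(doc, snomed_lexicon)
        cfg = AnnotatorConfig(stop_words=frozenset({"tobacco"}))
        filtered = annotate_document(doc, snomed_lexicon, cfg)
        assert {r.body_text for r in base} - {r.body_text for r in filtered} == {"Tobacco"}
        kept = {r.body_text: (r.tf, tuple(r.targets)) for r in filtered}
        for rec in base:
            if rec.body_text != "Tobacco":
                assert kept[rec.body_text] == (rec.tf, tuple(rec.targets))


class TestScope:
    def test_title_abstract_scope_subset_of_full_text(self, snomed_lexicon):
        doc = doc_from_texts(
            "1",
            ["Carcinoma in the body twice: carcinoma."],
            title="Carcinoma study",
            abstract="We studied whole blood.",
        )
        full = {r.body_text: r.tf for r in annotate_document(doc, snomed_lexicon)}
        ta = {
            r.body_text: r.tf
            for r in annotate_document(
                doc, snomed_lexicon, AnnotatorConfig(scope="title_abstract")
            )
        }
        assert set(ta) <= set(full)
        for surface, tf in ta.items():
            assert tf <= full[surface]
        assert full["Carcinoma"] == 3 and ta["Carcinoma"] == 1


class TestOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_tf_matches_naive_scan_on_seeded_corpora(self, seed, snomed_lexicon):
        planted = {
            "Carcinoma": ([0, 1], 2 + seed % 3),
            "Whole blood": ([1], 1 + seed % 2),
            "Polymerase chain reaction": ([0], 1),
        }
        streams, truth = make_corpus(2, snomed_lexicon, planted, seed=seed)
        for stream in streams:
            doc = parse_jats(stream)
            records = annotate_document(doc, snomed_lexicon)
            full_text = " ".join(p.text for p in doc.all_paragraphs())
            for rec in records:
                assert rec.tf == naive_count(full_text, rec.body_text)


class TestFrequencies:
    def test_corpus_stats_counts_documents_not_occurrences(self, snomed_lexicon):
        docs = [
            doc_from_texts("1", ["carcinoma carcinoma"]),
            doc_from_texts("2", ["carcinoma and tobacco"]),
            doc_from_texts("3", ["nothing of note"]),
        ]
        stats = corpus_stats({d.pmcid: annotate_document(d, snomed_lexicon) for d in docs})
        carcinoma = "http://purl.bioontology.org/ontology/SNOMEDCT/68453008"
        assert stats.n_docs == 3
        assert stats.df[carcinoma] == 2

    def test_empty_corpus(self):
        stats = corpus_stats({})
        assert stats.n_docs == 0 and stats.df == {}

    @pytest.mark.parametrize(
        "n,df,expected", [(7, 7, 0.0), (10, 1, 1.0), (100, 10, 1.0)]
    )
    def test_idf_log10(self, n, df, expected):
        stats = CorpusStats(n_docs=n, df={"c": df})
        assert compute_idf(stats, "c") == pytest.approx(expected)

    def test_idf_zero_iff_concept_in_every_document(self):
        stats = CorpusStats(n_docs=5, df={"everywhere": 5, "rare": 2})
        assert compute_idf(stats, "everywhere") == 0.0
        assert compute_idf(stats, "rare") == pytest.approx(math.log10(2.5))

    def test_idf_undefined_for_unseen_concept(self):
        with pytest.raises(ValueError):
            compute_idf(CorpusStats(n_docs=3, df={}), "missing")
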