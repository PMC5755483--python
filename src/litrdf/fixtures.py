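"""Synthetic JATS documents, lexicons and corpora with known ground truth.

Every pipeline stage is testable offline: :func:`make_jats` emits a
well-formed JATS article whose parse yields exactly the requested
counts and order; :func:`make_corpus` plants lexicon terms at known
frequencies and returns the ground-truth tf table alongside the XML;
:func:`tables_lexicon` is a small built-in SNOMED CT lexicon (cancer,
patient, sample and method terms from a published worked example).

Filler text is drawn from a fixed list of nonsense words disjoint from
every lexicon surface, so planted frequencies are exact by
construction.
"""

from __future__ import annotations

import random
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from lxml import etree

from .annotate import LexiconEntry

__all__ = ["make_jats", "make_corpus", "tables_lexicon", "SNOMEDCT_BASE", "FILLER_WORDS"]

SNOMEDCT_BASE = "http://purl.bioontology.org/ontology/SNOMEDCT/"

#: 13 SNOMED CT rows: cancer-related, patient-describing, sample-related
#: and method-related terms.
_SNOMED_ROWS: List[Tuple[str, str]] = [
    ("Carcinoma", "68453008"),
    ("Malignant neoplastic disease", "363346000"),
    ("Neoplasm", "108369006"),
    ("Neoplasm, malignant (primary)", "86049000"),
    ("Tobacco user", "110483000"),
    ("Tobacco", "39953003"),
    ("Taiwanese", "63736003"),
    ("AJCC", "258236004"),
    ("Whole blood", "420135007"),
    ("Ethylenediamine tetra-acetate", "69519002"),
    ("Probe with target amplification", "702675006"),
    ("Polymerase chain reaction", "258066000"),
    ("Deoxyribonucleic acid extraction technique", "702943006"),
]

#: Nonsense filler vocabulary, disjoint from every lexicon surface.
FILLER_WORDS = [
    "zorvex", "plimth", "gruntle", "vashidor", "quembly", "tarnquill",
    "obrelune", "snickmore", "drovanth", "eximbral", "pholtig",
    "wrenlock", "ambrevick", "clotherby", "dunmoral", "fexilart",
]


def tables_lexicon() -> List[LexiconEntry]:
    """Built-in 13-term SNOMED CT lexicon."""
    return [
        LexiconEntry(surface=s, concept_iri=SNOMEDCT_BASE + sid, ontology="SNOMEDCT")
        for s, sid in _SNOMED_ROWS
    ]


def _sentence(rng: random.Random, n_words: int = 8) -> str:
    words = [rng.choice(FILLER_WORDS) for _ in range(n_words)]
    return " ".join(words).capitalize() + "."


SectionSpec = Tuple[Optional[str], Union[int, Sequence[str]]]


def make_jats(
    spec: Mapping[str, object],
    seed: int = 0,
) -> bytes:
    """Build a JATS/XML article from a declarative spec.

    Recognized keys: ``pmcid`` (required), ``pmid``, ``doi``, ``title``,
    ``abstract``, ``journal_title``, ``issn``, ``n_authors``,
    ``sections`` (list of ``(title, n_paragraphs)`` or
    ``(title, [paragraph texts])``), ``refs`` (list of publication-type
    strings, e.g. ``"journal"``, ``"book"``).

    Seeded filler generation is reproducible: identical (spec, seed)
    yield identical bytes.
    """
    pmcid = spec.get("pmcid")
    if not pmcid:
        raise ValueError("spec requires a non-empty pmcid")
    rng = random.Random(seed)

    article = etree.Element("article", {"article-type": "research-article"})
    front = etree.SubElement(article, "front")

    jmeta = etree.SubElement(front, "journal-meta")
    jtg = etree.SubElement(jmeta, "journal-title-group")
    etree.SubElement(jtg, "journal-title").text = str(
        spec.get("journal_title", "Journal of Synthetic Examples")
    )
    if spec.get("issn"):
        etree.SubElement(jmeta, "issn", {"pub-type": "epub"}).text = str(spec["issn"])
    publisher = etree.SubElement(jmeta, "publisher")
    etree.SubElement(publisher, "publisher-name").text = "Synthetic Press"

    meta = etree.SubElement(front, "article-meta")
    etree.SubElement(meta, "article-id", {"pub-id-type": "pmc"}).text = str(pmcid)
    if spec.get("pmid"):
        etree.SubElement(meta, "article-id", {"pub-id-type": "pmid"}).text = str(spec["pmid"])
    if spec.get("doi"):
        etree.SubElement(meta, "article-id", {"pub-id-type": "doi"}).text = str(spec["doi"])
    tg = etree.SubElement(meta, "title-group")
    etree.SubElement(tg, "article-title").text = str(
        spec.get("title", f"A synthetic article {pmcid}")
    )

    n_authors = int(spec.get("n_authors", 1))
    if n_authors > 0:
        cg = etree.SubElement(meta, "contrib-group")
        for i in range(1, n_authors + 1):
            contrib = etree.SubElement(cg, "contrib", {"contrib-type": "author"})
            name = etree.SubElement(contrib, "name")
            etree.SubElement(name, "surname").text = f"{rng.choice(FILLER_WORDS).capitalize()}{i}"
            etree.SubElement(name, "given-names").text = f"Auth{i}"

    pub_date = etree.SubElement(meta, "pub-date", {"pub-type": "epub"})
    etree.SubElement(pub_date, "day").text = "13"
    etree.SubElement(pub_date, "month").text = "12"
    etree.SubElement(pub_date, "year").text = "2013"
    etree.SubElement(meta, "volume").text = "8"
    etree.SubElement(meta, "fpage").text = "1"
    etree.SubElement(meta, "lpage").text = "9"
    if spec.get("abstract"):
        abstract = etree.SubElement(meta, "abstract")
        etree.SubElement(abstract, "p").text = str(spec["abstract"])

    sections: Sequence[SectionSpec] = spec.get("sections", [])  # type: ignore[assignment]
    if sections:
        body = etree.SubElement(article, "body")
        for title, paras in sections:
            sec = etree.SubElement(body, "sec")
            if title:
                etree.SubElement(sec, "title").text = title
            if isinstance(paras, int):
                if paras < 0:
                    raise ValueError("paragraph count must be >= 0")
                texts = [_sentence(rng) for _ in range(paras)]
            else:
                texts = list(paras)
            for text in texts:
                etree.SubElement(sec, "p").text = text
    elif "sections" in spec:
        etree.SubElement(article, "body")

    refs: Sequence[str] = spec.get("refs", [])  # type: ignore[assignment]
    if refs:
        back = etree.SubElement(article, "back")
        ref_list = etree.SubElement(back, "ref-list")
        for i, kind in enumerate(refs, start=1):
            ref = etree.SubElement(ref_list, "ref", {"id": f"B{i}"})
            cit = etree.SubElement(ref, "element-citation", {"publication-type": kind})
            etree.SubElement(cit, "article-title").text = f"Cited work {i}"
            etree.SubElement(cit, "source").text = "Some Source"
            etree.SubElement(cit, "year").text = "2010"
            etree.SubElement(cit, "pub-id", {"pub-id-type": "pmid"}).text = str(20000000 + i)

    return etree.tostring(
        article, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def make_corpus(
    n_docs: int,
    lexicon: Iterable[LexiconEntry],
    planted: Mapping[str, Tuple[Sequence[int], int]],
    seed: int = 0,
) -> Tuple[List[bytes], pd.DataFrame]:
    """Corpus of JATS articles with planted term frequencies.

    ``planted`` maps a concept IRI or surface form to ``(doc_indices,
    per_doc_tf)``; each designated document carries exactly that many
    token-bounded, non-overlapping occurrences of the term in its body.
    Returns the XML byte streams plus the ground-truth table (columns:
    doc, surface, concept_iri, tf).
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    lex = list(lexicon)
    by_iri = {e.concept_iri: e for e in lex}
    by_surface = {e.surface.lower(): e for e in lex}

    plants_per_doc: Dict[int, List[Tuple[LexiconEntry, int]]] = {i: [] for i in range(n_docs)}
    for key, (doc_indices, tf) in planted.items():
        entry = by_iri.get(key) or by_surface.get(key.lower())
        if entry is None:
            raise ValueError(f"planted term {key!r} is not in the lexicon")
        if tf < 1:
            raise ValueError(f"planted tf must be >= 1, got {tf} for {key!r}")
        for idx in doc_indices:
            if not 0 <= idx < n_docs:
                raise ValueError(f"planted doc index {idx} out of range for n_docs={n_docs}")
            plants_per_doc[idx].append((entry, tf))

    rng = random.Random(seed)
    streams: List[bytes] = []
    truth_rows: List[Dict[str, object]] = []
    for i in range(n_docs):
        pmcid = str(1000001 + i)
        paragraphs: List[str] = [_sentence(rng)]
        for entry, tf in plants_per_doc[i]:
            # Spread occurrences over at most two paragraphs, separated by
            # filler so every occurrence is token-bounded and disjoint.
            occurrences = [
                f"{_sentence(rng, 3)[:-1]} {entry.surface} {rng.choice(FILLER_WORDS)}."
                for _ in range(tf)
            ]
            half = (len(occurrences) + 1) // 2
            paragraphs.append(" ".join(occurrences[:half]))
            if occurrences[half:]:
                paragraphs.append(" ".join(occurrences[half:]))
            truth_rows.append(
                {
                    "doc": pmcid,
                    "surface": entry.surface,
                    "concept_iri": entry.concept_iri,
                    "tf": tf,
                }
            )
        paragraphs.append(_sentence(rng))
        streams.append(
            make_jats(
                {
                    "pmcid": pmcid,
                    "pmid": str(24000000 + i),
                    "sections": [("Introduction", paragraphs)],
                },
                seed=rng.randrange(2**31),
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["doc", "surface", "concept_iri", "tf"])
    return streams, truth
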