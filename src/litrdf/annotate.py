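"""Dictionary-based ontology concept recognition and frequency stats.

The engine does exact, token-boundary-respecting matching of lexicon
surfaces against document text: case-insensitive by default,
longest-match-wins on overlaps, leftmost-wins on equal-length ties,
non-overlapping counting.  Token boundaries are transitions between
alphanumerics and non-alphanumerics, so hyphens and spaces inside
multiword lexicon terms are respected while ``pcr`` never fires inside
``pcra``.

There is no stemming, no lexical variants and no disambiguation — the
back-end is pluggable, and any external annotation producer that yields
:class:`AnnotationRecord` objects (for example a concept-recognition web
service or human annotations) can feed the downstream serializers.

Term frequency (tf) is document-scoped: one record per distinct surface
per document, with ``tf`` the total occurrence count in the annotated
scope and ``targets`` the paragraphs containing at least one hit, in
document order.  Inverse document frequency is ``log10(N / df)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .model import DocumentRecord

__all__ = [
    "LexiconEntry",
    "AnnotatorConfig",
    "AnnotationRecord",
    "CorpusStats",
    "annotate_document",
    "corpus_stats",
    "compute_idf",
    "load_lexicon",
    "load_stopwords",
    "naive_count",
]


@dataclass(frozen=True)
class LexiconEntry:
    """One dictionary row: a surface form bound to an ontology concept."""

    surface: str
    concept_iri: str
    ontology: str

    def __post_init__(self) -> None:
        if not self.surface.strip():
            raise ValueError("lexicon surface must be non-empty")
        if not self.concept_iri.startswith(("http://", "https://", "urn:")):
            raise ValueError(f"concept IRI must be absolute: {self.concept_iri!r}")


@dataclass(frozen=True)
class AnnotatorConfig:
    ontologies: Optional[frozenset] = None  # None = all ontologies in the lexicon
    stop_words: frozenset = frozenset()
    scope: str = "full_text"  # "full_text" | "title_abstract"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.scope not in {"full_text", "title_abstract"}:
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class AnnotationRecord:
    """One recognized concept surface in one document."""

    doc: str
    body_text: str
    topics: Set[str]
    targets: List[str]
    tf: int

    def __post_init__(self) -> None:
        if self.tf < 1:
            raise ValueError("tf must be >= 1")
        if not self.targets:
            raise ValueError("annotation must have at least one target")


@dataclass
class CorpusStats:
    """Corpus size and per-concept document frequency."""

    n_docs: int
    df: Dict[str, int] = field(default_factory=dict)


def load_lexicon(path) -> List[LexiconEntry]:
    """Read a tab-separated lexicon (surface, concept_iri, ontology).

    ``#`` starts a comment line; blank lines are ignored.
    """
    entries: List[LexiconEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            entries.append(LexiconEntry(*(p.strip() for p in parts)))
    return entries


def load_stopwords(path) -> frozenset:
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def _scope_segments(doc: DocumentRecord, scope: str) -> List[Tuple[str, str]]:
    """(target_id, text) pairs covered by the requested annotation scope."""
    segments: List[Tuple[str, str]] = []
    if doc.title:
        segments.append((f"{doc.pmcid}_title", doc.title))
    if doc.abstract:
        segments.append((f"{doc.pmcid}_abstract", doc.abstract))
    if scope == "full_text":
        for p in doc.all_paragraphs():
            segments.append((p.paragraph_id, p.text))
    return segments


def _build_matcher(surfaces: Sequence[str], case_sensitive: bool) -> Optional[re.Pattern]:
    if not surfaces:
        return None
    # Longest-first alternation gives longest-match-wins at each position;
    # the scan itself is leftmost and non-overlapping.
    ordered = sorted(surfaces, key=lambda s: (-len(s), s))
    pattern = (
        r"(?<![0-9A-Za-z])(?:" + "|".join(re.escape(s) for s in ordered) + r")(?![0-9A-Za-z])"
    )
    return re.compile(pattern, 0 if case_sensitive else re.IGNORECASE)


def annotate_document(
    doc: DocumentRecord,
    lexicon: Iterable[LexiconEntry],
    cfg: AnnotatorConfig = AnnotatorConfig(),
) -> List[AnnotationRecord]:
    """Recognize lexicon concepts in one document.

    Returns one record per distinct matched surface, ordered by first
    occurrence in the document.  An empty lexicon yields an empty list.
    """
    fold = (lambda s: s) if cfg.case_sensitive else str.lower
    stop = {fold(w) for w in cfg.stop_words}

    surface_topics: Dict[str, Set[str]] = {}
    canonical: Dict[str, str] = {}
    for entry in lexicon:
        if cfg.ontologies is not None and entry.ontology not in cfg.ontologies:
            continue
        key = fold(entry.surface)
        if key in stop:
            continue
        surface_topics.setdefault(key, set()).add(entry.concept_iri)
        canonical.setdefault(key, entry.surface)

    matcher = _build_matcher(sorted(surface_topics), cfg.case_sensitive)
    if matcher is None:
        return []

    order: List[str] = []
    tf: Dict[str, int] = {}
    targets: Dict[str, List[str]] = {}
    for target_id, text in _scope_segments(doc, cfg.scope):
        for m in matcher.finditer(text):
            key = fold(m.group(0))
            if key not in surface_topics:  # defensive; pattern only holds lexicon terms
                continue
            if key not in tf:
                order.append(key)
                tf[key] = 0
                targets[key] = []
            tf[key] += 1
            if not targets[key] or targets[key][-1] != target_id:
                if target_id not in targets[key]:
                    targets[key].append(target_id)
    return [
        AnnotationRecord(
            doc=doc.pmcid,
            body_text=canonical[key],
            topics=set(surface_topics[key]),
            targets=targets[key],
            tf=tf[key],
        )
        for key in order
    ]


def corpus_stats(
    annotations: Union[Mapping[str, List[AnnotationRecord]], Iterable[List[AnnotationRecord]]],
) -> CorpusStats:
    """Aggregate document frequencies over per-document annotation lists.

    ``n_docs`` counts every processed document, including those with no
    annotations.
    """
    doc_lists = (
        list(annotations.values())
        if isinstance(annotations, Mapping)
        else list(annotations)
    )
    df: Dict[str, int] = {}
    for records in doc_lists:
        concepts: Set[str] = set()
        for rec in records:
            concepts.update(rec.topics)
        for c in concepts:
            df[c] = df.get(c, 0) + 1
    return CorpusStats(n_docs=len(doc_lists), df=df)


def compute_idf(stats: CorpusStats, concept: str) -> float:
    """idf(c) = log10(N / df(c)); zero exactly when c is in every document."""
    if concept not in stats.df or stats.df[concept] < 1:
        raise ValueError(f"idf undefined: concept {concept!r} has no document frequency")
    return math.log10(stats.n_docs / stats.df[concept])


def naive_count(text: str, surface: str, case_sensitive: bool = False) -> int:
    """Independent occurrence counter used as a test oracle.

    Counts non-overlapping, token-bounded occurrences of ``surface`` in
    ``text`` by direct scanning, without the alternation machinery of
    the annotator.
    """
    if not case_sensitive:
        text, surface = text.lower(), surface.lower()
    count = 0
    start = 0
    n = len(surface)
    while True:
        idx = text.find(surface, start)
        if idx < 0:
            return count
        before_ok = idx == 0 or not text[idx - 1].isalnum()
        after = idx + n
        after_ok = after >= len(text) or not text[after].isalnum()
        if before_ok and after_ok:
            count += 1
            start = after
        else:
            start = idx + 1
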