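"""JATS/XML ingestion.

Parses articles in the NISO JATS tag suite (the PMC open-access dialect)
into :class:`~litrdf.model.DocumentRecord`.  Both archiving and
publishing dialects are accepted by tolerating unknown elements; inline
markup (italic, xref, sup/sub, ...) inside paragraphs is flattened to
plain text, since downstream the paragraph text is carried as a single
literal value.

Paragraph identifiers follow the convention
``<pmcid>_paragraph_<SectionLabel>_para_<n>`` where ``SectionLabel`` is
the nearest enclosing section title with spaces removed and
non-alphanumerics dropped, and ``n`` is a 1-based ordinal within that
label scope.
"""

from __future__ import annotations

import re
from typing import Dict, List, Optional, Sequence, Union

from lxml import etree

from .model import (
    ContributorRecord,
    DocumentRecord,
    JournalInfo,
    ParagraphNode,
    RefKind,
    ReferenceRecord,
    SectionNode,
    ValidationError,
)

__all__ = [
    "JatsParseError",
    "parse_jats",
    "paragraph_id_for",
    "normalize_whitespace",
    "section_label",
]


class JatsParseError(ValueError):
    """Raised for malformed XML; carries the parser's position report."""


_WS_RE = re.compile(r"\s+")


def normalize_whitespace(text: str) -> str:
    """Collapse whitespace runs to single spaces and trim the ends.

    Idempotent: ``normalize_whitespace(normalize_whitespace(s)) ==
    normalize_whitespace(s)``.
    """
    return _WS_RE.sub(" ", text).strip()


def section_label(title: Optional[str]) -> str:
    """Canonical section label: spaces removed, non-alphanumerics dropped.

    ``"Materials and Methods"`` -> ``"MaterialsandMethods"``.
    """
    if not title:
        return ""
    return re.sub(r"[^0-9A-Za-z]", "", title)


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _find(el: etree._Element, path: Sequence[str]) -> Optional[etree._Element]:
    """Descend through the first child matching each local name in turn."""
    cur: Optional[etree._Element] = el
    for name in path:
        if cur is None:
            return None
        cur = next((c for c in cur if _localname(c) == name), None)
    return cur


def _iter_descendants(el: etree._Element, name: str) -> List[etree._Element]:
    return [d for d in el.iter() if isinstance(d.tag, str) and _localname(d) == name]


def _text_of(el: Optional[etree._Element]) -> str:
    if el is None:
        return ""
    return normalize_whitespace("".join(el.itertext()))


_REF_KIND_MAP = {
    "journal": RefKind.ARTICLE,
    "article": RefKind.ARTICLE,
    "journal-article": RefKind.ARTICLE,
    "book": RefKind.BOOK,
    "chapter": RefKind.CHAPTER,
    "book-chapter": RefKind.CHAPTER,
    "confproc": RefKind.PROCEEDINGS,
    "proceedings": RefKind.PROCEEDINGS,
}


def parse_jats(xml_bytes: bytes) -> DocumentRecord:
    """Parse one JATS article into a validated :class:`DocumentRecord`.

    Identifiers come from ``article-id`` elements keyed by
    ``pub-id-type`` (pmc, pmid, doi); sections and paragraphs are
    enumerated depth-first in document order.

    Raises
    ------
    JatsParseError
        If the input is not well-formed XML (message carries the
        parser's line/column position).
    ValidationError
        If the PMC id is missing or a model invariant fails.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise JatsParseError(f"malformed XML: {exc}") from exc

    meta = _find(root, ["front", "article-meta"])
    if meta is None:
        raise ValidationError("missing front/article-meta (no pmc article-id)")

    ids: Dict[str, str] = {}
    for aid in _iter_descendants(meta, "article-id"):
        kind = (aid.get("pub-id-type") or "").lower()
        value = _text_of(aid)
        if kind in {"pmc", "pmcid"}:
            ids["pmc"] = value.removeprefix("PMC")
        elif kind in {"pmid", "pubmed"}:
            ids["pmid"] = value
        elif kind == "doi":
            ids["doi"] = value
    if not ids.get("pmc"):
        raise ValidationError("missing required article-id pub-id-type='pmc'")

    doc = DocumentRecord(
        pmcid=ids["pmc"],
        pmid=ids.get("pmid"),
        doi=ids.get("doi"),
        title=_text_of(_find(meta, ["title-group", "article-title"])),
        abstract=_parse_abstract(meta),
        keywords=[_text_of(k) for k in _iter_descendants(meta, "kwd")],
        journal=_parse_journal(root, meta),
        issued_date=_parse_date(meta),
        authors=_parse_contributors(meta),
        references=_parse_references(root),
    )
    body = _find(root, ["body"])
    if body is not None:
        doc.body = _parse_body(body, doc.pmcid)
    doc.validate()
    return doc


def _parse_abstract(meta: etree._Element) -> Optional[str]:
    # One abstract per article: structured abstracts are flattened into a
    # single text block.
    abstract = next(
        (c for c in meta if _localname(c) == "abstract" and not c.get("abstract-type")),
        None,
    )
    if abstract is None:
        abstract = next((c for c in meta if _localname(c) == "abstract"), None)
    if abstract is None:
        return None
    text = _text_of(abstract)
    return text or None


def _parse_journal(root: etree._Element, meta: etree._Element) -> JournalInfo:
    jmeta = _find(root, ["front", "journal-meta"])
    info = JournalInfo()
    if jmeta is not None:
        titles = _iter_descendants(jmeta, "journal-title")
        if titles:
            info.journal_title = _text_of(titles[0])
        issns = _iter_descendants(jmeta, "issn")
        if issns:
            info.issn = _text_of(issns[0])
        pub = _find(jmeta, ["publisher", "publisher-name"])
        if pub is not None:
            info.publisher = _text_of(pub) or None
    for tag, attr in (
        ("volume", "volume"),
        ("issue", "issue"),
        ("fpage", "page_start"),
        ("lpage", "page_end"),
    ):
        el = next((c for c in meta if _localname(c) == tag), None)
        if el is not None:
            setattr(info, attr, _text_of(el) or None)
    return info


def _parse_date(meta: etree._Element) -> Optional[str]:
    dates = [c for c in meta if _localname(c) == "pub-date"]
    if not dates:
        return None
    # Prefer an electronic publication date, else the first listed.
    chosen = next(
        (d for d in dates if (d.get("pub-type") or "").startswith("e")), dates[0]
    )
    year = _text_of(_find(chosen, ["year"]))
    month = _text_of(_find(chosen, ["month"]))
    day = _text_of(_find(chosen, ["day"]))
    if not year:
        return None
    if month.isdigit() and day.isdigit():
        return f"{year}-{int(month):02d}-{int(day):02d}"
    if month.isdigit():
        return f"{year}-{int(month):02d}"
    return year


def _parse_contributor(contrib: etree._Element) -> Optional[ContributorRecord]:
    collab = next((c for c in contrib.iter() if _localname(c) == "collab"), None)
    if collab is not None:
        name = _text_of(collab)
        return ContributorRecord(full_name=name, is_organization=True) if name else None
    name_el = next((c for c in contrib.iter() if _localname(c) == "name"), None)
    given = family = None
    if name_el is not None:
        family = _text_of(_find(name_el, ["surname"])) or None
        given = _text_of(_find(name_el, ["given-names"])) or None
    email_el = next((c for c in contrib.iter() if _localname(c) == "email"), None)
    full = " ".join(part for part in (given, family) if part)
    if not full:
        return None
    return ContributorRecord(
        full_name=full,
        given_name=given,
        family_name=family,
        email=_text_of(email_el) or None,
    )


def _parse_contributors(meta: etree._Element) -> List[ContributorRecord]:
    out: List[ContributorRecord] = []
    for group in (c for c in meta if _localname(c) == "contrib-group"):
        for contrib in (c for c in group if _localname(c) == "contrib"):
            if contrib.get("contrib-type") not in (None, "author"):
                continue
            rec = _parse_contributor(contrib)
            if rec is not None:
                out.append(rec)
    return out


def _parse_references(root: etree._Element) -> List[ReferenceRecord]:
    back = _find(root, ["back"])
    if back is None:
        return []
    out: List[ReferenceRecord] = []
    for ref in _iter_descendants(back, "ref"):
        cit = next(
            (
                c
                for c in ref
                if _localname(c)
                in {"element-citation", "mixed-citation", "citation", "nlm-citation"}
            ),
            None,
        )
        if cit is None:
            continue
        pub_type = (cit.get("publication-type") or cit.get("citation-type") or "").lower()
        rec = ReferenceRecord(ref_kind=_REF_KIND_MAP.get(pub_type, RefKind.OTHER))
        title_el = next(
            (c for c in cit.iter() if _localname(c) in {"article-title", "chapter-title"}),
            None,
        )
        rec.title = _text_of(title_el) or None
        source = next((c for c in cit.iter() if _localname(c) == "source"), None)
        rec.source = _text_of(source) or None
        year = next((c for c in cit.iter() if _localname(c) == "year"), None)
        rec.year = _text_of(year) or None
        for pid in _iter_descendants(cit, "pub-id"):
            kind = (pid.get("pub-id-type") or "").lower()
            if kind == "pmid":
                rec.pmid = _text_of(pid)
            elif kind == "doi":
                rec.doi = _text_of(pid)
        for name_el in _iter_descendants(cit, "name"):
            family = _text_of(_find(name_el, ["surname"])) or None
            given = _text_of(_find(name_el, ["given-names"])) or None
            full = " ".join(p for p in (given, family) if p)
            if full:
                rec.authors.append(
                    ContributorRecord(full_name=full, given_name=given, family_name=family)
                )
        out.append(rec)
    return out


class _IdMinter:
    """Per-label paragraph counters; continues counting on label reuse so
    ids stay unique even when two sections share a title."""

    def __init__(self, pmcid: str):
        self.pmcid = pmcid
        self.para_counts: Dict[str, int] = {}
        self.section_counts: Dict[str, int] = {}
        self.anon_sections = 0

    def paragraph_id(self, label: str) -> str:
        n = self.para_counts.get(label, 0) + 1
        self.para_counts[label] = n
        return f"{self.pmcid}_paragraph_{label}_para_{n}"

    def section_id(self, label: str) -> str:
        n = self.section_counts.get(label, 0) + 1
        self.section_counts[label] = n
        if n == 1:
            return f"{self.pmcid}_section_{label}"
        return f"{self.pmcid}_section_{label}_{n}"

    def anon_label(self) -> str:
        self.anon_sections += 1
        return f"Section{self.anon_sections}"


def _parse_body(body: etree._Element, pmcid: str) -> List[SectionNode]:
    minter = _IdMinter(pmcid)
    sections: List[SectionNode] = []
    loose: List[etree._Element] = []
    for child in body:
        if _localname(child) == "sec":
            sections.append(_parse_section(child, minter, inherited_label=None))
        elif _localname(child) == "p":
            loose.append(child)
    if loose:
        # Body-level paragraphs outside any <sec> get a synthetic wrapper
        # section so every paragraph has an addressable container.
        label = "Body"
        wrapper = SectionNode(section_id=minter.section_id(label), title=None)
        for p in loose:
            text = _text_of(p)
            if text:
                wrapper.children.append(
                    ParagraphNode(paragraph_id=minter.paragraph_id(label), text=text)
                )
        sections.insert(0, wrapper)
    return sections


def _parse_section(
    sec: etree._Element, minter: _IdMinter, inherited_label: Optional[str]
) -> SectionNode:
    title_el = next((c for c in sec if _localname(c) == "title"), None)
    title = _text_of(title_el) or None
    label = section_label(title) or inherited_label or minter.anon_label()
    node = SectionNode(section_id=minter.section_id(label), title=title)
    for child in sec:
        name = _localname(child)
        if name == "p":
            text = _text_of(child)
            if text:
                node.children.append(
                    ParagraphNode(paragraph_id=minter.paragraph_id(label), text=text)
                )
        elif name == "sec":
            node.children.append(_parse_section(child, minter, inherited_label=label))
        elif name in {"table-wrap", "fig"}:
            # Recorded as typed hooks; internal content is not decomposed.
            kind = "table" if name == "table-wrap" else "figure"
            hook_label = f"{label}{kind.capitalize()}"
            node.children.append(
                SectionNode(
                    section_id=minter.section_id(hook_label),
                    title=None,
                    kind=kind,
                )
            )
    return node


def paragraph_id_for(
    doc: DocumentRecord, section_path: Sequence[str], ordinal: int
) -> str:
    """Deterministic paragraph id for the ``ordinal``-th paragraph under
    the section reached by following ``section_path`` titles from the top.

    Raises ``ValueError`` on ordinal < 1 and ``KeyError`` when the title
    path does not exist in the document.
    """
    if ordinal < 1:
        raise ValueError(f"ordinal must be >= 1, got {ordinal}")
    current: List[SectionNode] = doc.body
    target: Optional[SectionNode] = None
    for title in section_path:
        target = next((s for s in current if s.title == title), None)
        if target is None:
            raise KeyError(f"section path {list(section_path)!r} not found")
        current = target.subsections()
    assert target is not None
    label = section_label(target.title)
    return f"{doc.pmcid}_paragraph_{label}_para_{ordinal}"
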