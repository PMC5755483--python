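"""In-memory document model for parsed scholarly articles.

The model mirrors what a JATS/XML article exposes to the RDFization
pipeline: identifiers, bibliographic metadata, an ordered author list,
an ordered reference list, and the body as a tree of sections holding
whitespace-normalized paragraphs.  No RDF concerns live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Union


class ValidationError(ValueError):
    """A document violates a model invariant (e.g. missing PMC id)."""


class RefKind(str, Enum):
    """Closed set of reference publication types; unknowns map to OTHER."""

    ARTICLE = "article"
    BOOK = "book"
    CHAPTER = "chapter"
    PROCEEDINGS = "proceedings"
    OTHER = "other"


@dataclass
class JournalInfo:
    journal_title: str = ""
    issn: Optional[str] = None
    volume: Optional[str] = None
    issue: Optional[str] = None
    page_start: Optional[str] = None
    page_end: Optional[str] = None
    publisher: Optional[str] = None

    def validate(self) -> None:
        if (
            self.page_start is not None
            and self.page_end is not None
            and self.page_start.isdigit()
            and self.page_end.isdigit()
            and int(self.page_end) < int(self.page_start)
        ):
            raise ValidationError(
                f"page_end {self.page_end} precedes page_start {self.page_start}"
            )


@dataclass
class ContributorRecord:
    """An author: a person (given/family name) or an organization."""

    full_name: str
    given_name: Optional[str] = None
    family_name: Optional[str] = None
    email: Optional[str] = None
    is_organization: bool = False

    def validate(self) -> None:
        if not self.full_name:
            raise ValidationError("contributor full_name must be non-empty")
        if self.is_organization and (self.given_name or self.family_name):
            raise ValidationError(
                "organization contributors carry no given/family name"
            )


@dataclass
class ReferenceRecord:
    ref_kind: RefKind = RefKind.OTHER
    title: Optional[str] = None
    authors: List[ContributorRecord] = field(default_factory=list)
    year: Optional[str] = None
    source: Optional[str] = None
    pmid: Optional[str] = None
    doi: Optional[str] = None


@dataclass
class ParagraphNode:
    """A paragraph: plain Unicode text with inline markup stripped.

    ``text`` is whitespace-normalized (runs collapsed to single spaces,
    ends trimmed); the normalization is idempotent so annotation targets
    have a canonical text form.
    """

    paragraph_id: str
    text: str


@dataclass
class SectionNode:
    section_id: str
    title: Optional[str] = None
    children: List[Union["SectionNode", ParagraphNode]] = field(default_factory=list)
    kind: str = "section"  # "section" | "table" | "figure" typing hook

    def paragraphs(self) -> List[ParagraphNode]:
        """All paragraphs under this section, depth-first in document order."""
        out: List[ParagraphNode] = []
        for child in self.children:
            if isinstance(child, ParagraphNode):
                out.append(child)
            else:
                out.extend(child.paragraphs())
        return out

    def subsections(self) -> List["SectionNode"]:
        return [c for c in self.children if isinstance(c, SectionNode)]

    def direct_paragraphs(self) -> List[ParagraphNode]:
        return [c for c in self.children if isinstance(c, ParagraphNode)]


@dataclass
class DocumentRecord:
    """One parsed article; the unit every downstream stage consumes."""

    pmcid: str
    pmid: Optional[str] = None
    doi: Optional[str] = None
    title: str = ""
    abstract: Optional[str] = None
    keywords: List[str] = field(default_factory=list)
    journal: JournalInfo = field(default_factory=JournalInfo)
    issued_date: Optional[str] = None
    authors: List[ContributorRecord] = field(default_factory=list)
    references: List[ReferenceRecord] = field(default_factory=list)
    body: List[SectionNode] = field(default_factory=list)

    def validate(self) -> None:
        if not self.pmcid:
            raise ValidationError("pmcid is required and must be non-empty")
        for author in self.authors:
            author.validate()
        self.journal.validate()
        seen: set[str] = set()
        for p in self.all_paragraphs():
            if not p.paragraph_id:
                raise ValidationError("paragraph with empty id")
            if p.paragraph_id in seen:
                raise ValidationError(
                    f"duplicate paragraph id {p.paragraph_id!r}"
                )
            seen.add(p.paragraph_id)

    def all_paragraphs(self) -> List[ParagraphNode]:
        out: List[ParagraphNode] = []
        for sec in self.body:
            out.extend(sec.paragraphs())
        return out

    def all_sections(self) -> List[SectionNode]:
        """Every section node, depth-first in document order."""
        out: List[SectionNode] = []

        def walk(sec: SectionNode) -> None:
            out.append(sec)
            for sub in sec.subsections():
                walk(sub)

        for sec in self.body:
            walk(sec)
        return out
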