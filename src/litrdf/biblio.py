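"""Metadata + references graph: the first output of publication parsing.

The article becomes a ``bibo:AcademicArticle`` carrying its identifiers,
title, abstract, issue/volume/pagination, an ordered author list
(``rdf:Seq`` via ``biotea:authorList``), links to external
representations of the same article (``owl:sameAs`` into Bio2RDF,
identifiers.org and the DOI resolver; ``rdfs:seeAlso`` to the PubMed and
identifiers.org info pages) and provenance.  References get one node
each, typed by publication kind, wired symmetrically with ``bibo:cites``
/ ``bibo:citedBy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, FOAF, OWL, PROV, RDF, RDFS, XSD

from .model import ContributorRecord, DocumentRecord, RefKind
from .rdfcommon import BIBO, BIOTEA, UriPolicy, article_uri, default_policy, new_graph

__all__ = ["BiblioGraphConfig", "build_metadata_graph", "build_references_graph"]

#: Generating-software IRI used in prov:wasAttributedTo by default.
DEFAULT_AGENT = URIRef("http://purl.org/litrdf/agent")

_REF_TYPE = {
    RefKind.ARTICLE: BIBO.AcademicArticle,
    RefKind.BOOK: BIBO.Book,
    RefKind.CHAPTER: BIBO.Chapter,
    RefKind.PROCEEDINGS: BIBO.Proceedings,
    RefKind.OTHER: BIBO.Document,
}


@dataclass(frozen=True)
class BiblioGraphConfig:
    """Shared configuration for the bibliographic graph builders.

    ``creation_time`` is an ISO-8601 timestamp or the string ``"now"``;
    tests fix it so identical inputs serialize identically.
    """

    policy: UriPolicy = field(default_factory=default_policy)
    creation_time: str = "now"
    agent: URIRef = DEFAULT_AGENT
    keyword_predicate: URIRef = DCTERMS.subject
    source_iri_template: str = "https://www.ncbi.nlm.nih.gov/pmc/articles/PMC{}/"

    def timestamp(self) -> Literal:
        value = self.creation_time
        if value == "now":
            value = datetime.now(timezone.utc).isoformat(timespec="seconds")
        return Literal(value, datatype=XSD.dateTime)


def _add_provenance(g: Graph, subject: URIRef, doc: DocumentRecord, cfg: BiblioGraphConfig) -> None:
    g.add((subject, PROV.generatedAtTime, cfg.timestamp()))
    g.add((subject, PROV.wasAttributedTo, cfg.agent))
    g.add(
        (subject, PROV.wasDerivedFrom, URIRef(cfg.source_iri_template.format(doc.pmcid)))
    )


def _add_person(
    g: Graph, node: URIRef, person: ContributorRecord
) -> None:
    g.add((node, RDF.type, FOAF.Organization if person.is_organization else FOAF.Person))
    g.add((node, FOAF.name, Literal(person.full_name)))
    if person.given_name:
        g.add((node, FOAF.givenName, Literal(person.given_name)))
    if person.family_name:
        g.add((node, FOAF.familyName, Literal(person.family_name)))
    if person.email:
        g.add((node, FOAF.mbox, URIRef(f"mailto:{person.email}")))


def _add_author_list(
    g: Graph,
    owner: URIRef,
    authors: list[ContributorRecord],
    policy: UriPolicy,
    local_prefix: str,
) -> None:
    """Ordered author container: rdf:Seq with 1-based ordinal members."""
    list_node = policy.resource(f"{local_prefix}_authorList")
    g.add((owner, BIOTEA.authorList, list_node))
    g.add((list_node, RDF.type, RDF.Seq))
    for i, person in enumerate(authors, start=1):
        person_node = policy.resource(f"{local_prefix}_author_{i}")
        g.add((list_node, URIRef(f"{RDF}_{i}"), person_node))
        _add_person(g, person_node, person)


def _add_external_links(
    g: Graph, node: URIRef, pmid: Optional[str], doi: Optional[str], policy: UriPolicy
) -> None:
    """owl:sameAs / rdfs:seeAlso links, each emitted only when its id exists."""
    if pmid:
        g.add((node, OWL.sameAs, policy.external("bio2rdf_pubmed", pmid)))
        g.add((node, OWL.sameAs, policy.external("identifiers_org_pubmed", pmid)))
        g.add((node, RDFS.seeAlso, policy.external("pubmed_page", pmid)))
        g.add((node, RDFS.seeAlso, policy.external("identifiers_info_page", pmid)))
    if doi:
        g.add((node, OWL.sameAs, policy.external("doi", doi)))


def build_metadata_graph(doc: DocumentRecord, cfg: BiblioGraphConfig) -> Graph:
    """Bibliographic metadata graph for one article."""
    doc.validate()
    g = new_graph()
    policy = cfg.policy
    article = article_uri(policy, doc.pmcid)

    g.add((article, RDF.type, BIBO.AcademicArticle))
    g.add((article, BIBO.identifier, Literal(doc.pmcid)))
    if doc.pmid:
        g.add((article, BIBO.pmid, Literal(doc.pmid)))
    if doc.doi:
        g.add((article, BIBO.doi, Literal(doc.doi)))
    if doc.title:
        g.add((article, DCTERMS.title, Literal(doc.title)))
    if doc.abstract:
        g.add((article, BIBO.shortDescription, Literal(doc.abstract)))
        g.add((article, DCTERMS.description, Literal(doc.abstract)))
    if doc.issued_date:
        g.add((article, DCTERMS.issued, Literal(doc.issued_date)))
    for kw in doc.keywords:
        g.add((article, cfg.keyword_predicate, Literal(kw)))

    _add_external_links(g, article, doc.pmid, doc.doi, policy)

    j = doc.journal
    if j.journal_title or j.issn:
        journal_node = policy.resource(f"{doc.pmcid}_journal")
        g.add((article, DCTERMS.isPartOf, journal_node))
        g.add((journal_node, RDF.type, BIBO.Journal))
        if j.journal_title:
            g.add((journal_node, DCTERMS.title, Literal(j.journal_title)))
        if j.issn:
            g.add((journal_node, BIBO.issn, Literal(j.issn)))
    if j.volume:
        g.add((article, BIBO.volume, Literal(j.volume)))
    if j.issue:
        g.add((article, BIBO.issue, Literal(j.issue)))
    if j.page_start:
        g.add((article, BIBO.pageStart, Literal(j.page_start)))
    if j.page_end:
        g.add((article, BIBO.pageEnd, Literal(j.page_end)))
    if (
        j.page_start
        and j.page_end
        and j.page_start.isdigit()
        and j.page_end.isdigit()
    ):
        g.add(
            (
                article,
                BIBO.numPages,
                Literal(int(j.page_end) - int(j.page_start) + 1),
            )
        )
    if j.publisher:
        g.add((article, DCTERMS.publisher, Literal(j.publisher)))

    _add_author_list(g, article, doc.authors, policy, doc.pmcid)
    _add_provenance(g, article, doc, cfg)
    return g


def build_references_graph(doc: DocumentRecord, cfg: BiblioGraphConfig) -> Graph:
    """References graph: cites/citedBy symmetric, one typed node per reference."""
    doc.validate()
    g = new_graph()
    policy = cfg.policy
    article = article_uri(policy, doc.pmcid)
    for i, ref in enumerate(doc.references, start=1):
        node = policy.resource(f"{doc.pmcid}_reference_{i}")
        g.add((node, RDF.type, _REF_TYPE[ref.ref_kind]))
        g.add((article, BIBO.cites, node))
        g.add((node, BIBO.citedBy, article))
        if ref.title:
            g.add((node, DCTERMS.title, Literal(ref.title)))
        if ref.year:
            g.add((node, DCTERMS.issued, Literal(ref.year)))
        if ref.source:
            g.add((node, DCTERMS.source, Literal(ref.source)))
        if ref.pmid:
            g.add((node, BIBO.pmid, Literal(ref.pmid)))
        if ref.doi:
            g.add((node, BIBO.doi, Literal(ref.doi)))
        _add_external_links(g, node, ref.pmid, ref.doi, policy)
        if ref.authors:
            _add_author_list(g, node, ref.authors, policy, f"{doc.pmcid}_reference_{i}")
    return g
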