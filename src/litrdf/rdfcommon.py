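"""URI policy, namespace registry and graph plumbing shared by every
RDF-producing stage.

Graphs are carried as :class:`rdflib.Graph`; this module owns the prefix
bindings, the IRI-minting policy for article and derived resources, and
the serializers (RDF/XML, JSON-LD, with N-Triples available for test
canonicalization).  Derived resources (selectors, annotations, list
nodes) always get minted IRIs under ``resource_base`` — blank nodes are
avoided throughout so outputs are byte-stable and joinable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from rdflib import Graph, Namespace, URIRef
from rdflib.namespace import DCTERMS, FOAF, OWL, PROV, RDF, RDFS, XSD

__all__ = [
    "NAMESPACES",
    "BIBO",
    "BIOTEA",
    "DOCO",
    "AO",
    "AOT",
    "OA",
    "PAV",
    "SIO",
    "UriPolicy",
    "default_policy",
    "bio2rdf_policy",
    "new_graph",
    "article_uri",
    "serialize",
    "parse_graph",
    "expand_curie",
]

BIBO = Namespace("http://purl.org/ontology/bibo/")
BIOTEA = Namespace("http://purl.org/biotea/ontology#")
DOCO = Namespace("http://purl.org/spar/doco/")
AO = Namespace("http://purl.org/ao/core/")
AOT = Namespace("http://purl.org/ao/types/")
OA = Namespace("http://www.w3.org/ns/oa#")
PAV = Namespace("http://purl.org/pav/")
SIO = Namespace("http://semanticscience.org/resource/")

NAMESPACES: Dict[str, Namespace] = {
    "rdf": Namespace(str(RDF)),
    "rdfs": Namespace(str(RDFS)),
    "owl": Namespace(str(OWL)),
    "xsd": Namespace(str(XSD)),
    "dcterms": Namespace(str(DCTERMS)),
    "foaf": Namespace(str(FOAF)),
    "prov": Namespace(str(PROV)),
    "bibo": BIBO,
    "biotea": BIOTEA,
    "doco": DOCO,
    "ao": AO,
    "aot": AOT,
    "oa": OA,
    "pav": PAV,
    "sio": SIO,
}

#: IRI templates for links to external representations of an article;
#: each contains exactly one substitution slot.
DEFAULT_EXTERNAL_TEMPLATES: Dict[str, str] = {
    "bio2rdf_pubmed": "http://bio2rdf.org/pubmed:{}",
    "identifiers_org_pubmed": "http://identifiers.org/pubmed/{}",
    "doi": "http://dx.doi.org/{}",
    "pubmed_page": "http://www.ncbi.nlm.nih.gov/pubmed/{}",
    "identifiers_info_page": "http://info.identifiers.org/pubmed/{}",
}


@dataclass(frozen=True)
class UriPolicy:
    """Where article resources and derived resources are minted.

    Two published schemes exist for the same data (a ``linkingdata.io``
    document space and a ``bio2rdf.org`` resource space), so the bases
    are configuration, defaulting to the ``linkingdata.io`` scheme.
    """

    doc_base: str = "http://linkingdata.io/pmcdoc/pmc/"
    resource_base: str = "http://linkingdata.io/pmcres/pmc/"
    external_templates: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EXTERNAL_TEMPLATES)
    )

    def __post_init__(self) -> None:
        for base in (self.doc_base, self.resource_base):
            if not base.startswith(("http://", "https://")):
                raise ValueError(f"base must be an absolute HTTP IRI: {base!r}")
        for key, tpl in self.external_templates.items():
            if tpl.count("{}") != 1:
                raise ValueError(
                    f"template {key!r} must contain exactly one substitution slot"
                )

    def external(self, kind: str, value: str) -> URIRef:
        return URIRef(self.external_templates[kind].format(value))

    def resource(self, local: str) -> URIRef:
        return URIRef(self.resource_base + local)


def default_policy() -> UriPolicy:
    return UriPolicy()


def bio2rdf_policy() -> UriPolicy:
    """The bio2rdf.org naming scheme (``pmc:`` / ``pmc_resource:`` CURIE style)."""
    return UriPolicy(
        doc_base="http://bio2rdf.org/pmc:",
        resource_base="http://bio2rdf.org/pmc_resource:",
    )


def article_uri(policy: UriPolicy, pmcid: str) -> URIRef:
    """IRI of the article resource: ``doc_base + pmcid``."""
    if not pmcid:
        raise ValueError("pmcid must be non-empty")
    return URIRef(policy.doc_base + pmcid)


def new_graph() -> Graph:
    """Fresh graph with the full prefix registry bound."""
    g = Graph()
    for prefix, ns in NAMESPACES.items():
        g.bind(prefix, ns, override=True)
    return g


_SYNTAX_FORMATS = {"rdfxml": "pretty-xml", "jsonld": "json-ld", "ntriples": "nt"}


def serialize(graph: Graph, syntax: str = "rdfxml") -> bytes:
    """Serialize to RDF/XML or JSON-LD (N-Triples for canonicalization).

    Round-trip safe: the output reparses to a graph isomorphic to the
    input.
    """
    try:
        fmt = _SYNTAX_FORMATS[syntax]
    except KeyError:
        raise ValueError(
            f"unknown syntax {syntax!r}; expected one of {sorted(_SYNTAX_FORMATS)}"
        ) from None
    return graph.serialize(format=fmt, encoding="utf-8")


def parse_graph(data: bytes, syntax: str = "rdfxml") -> Graph:
    try:
        fmt = {"rdfxml": "xml", "jsonld": "json-ld", "ntriples": "nt"}[syntax]
    except KeyError:
        raise ValueError(f"unknown syntax {syntax!r}") from None
    g = new_graph()
    g.parse(data=data, format=fmt)
    return g


def expand_curie(curie: str, extra: Optional[Dict[str, str]] = None) -> URIRef:
    """Resolve ``prefix:local`` against the namespace registry.

    Absolute IRIs pass through unchanged.
    """
    if curie.startswith(("http://", "https://", "urn:")):
        return URIRef(curie)
    prefix, _, local = curie.partition(":")
    if extra and prefix in extra:
        return URIRef(extra[prefix] + local)
    if prefix in NAMESPACES and local:
        return URIRef(str(NAMESPACES[prefix]) + local)
    raise ValueError(f"cannot resolve CURIE {curie!r}: unknown prefix {prefix!r}")
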