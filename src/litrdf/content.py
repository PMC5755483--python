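"""Structure + content graph: the second output of publication parsing.

Sections are ``doco:Section`` nodes aggregated in an order-preserving
``rdf:Seq`` (``biotea:sectionList``); the hierarchy among the section
list, sections and subsections is expressed with ``dcterms:hasPart``.
Paragraphs are ``doco:Paragraph`` nodes in a per-section
``biotea:paragraphList``, each carrying its text byte-exact as an
``rdf:value`` literal (untagged: the corpus is mixed-language).
"""

from __future__ import annotations

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, RDF

from .biblio import BiblioGraphConfig, _add_provenance
from .model import DocumentRecord, ParagraphNode, SectionNode
from .rdfcommon import BIOTEA, DOCO, UriPolicy, article_uri, new_graph

__all__ = ["build_structure_graph", "paragraph_uri", "section_uri"]

_SECTION_TYPE = {"section": DOCO.Section, "table": DOCO.Table, "figure": DOCO.Figure}


def paragraph_uri(policy: UriPolicy, paragraph_id: str) -> URIRef:
    return policy.resource(paragraph_id)


def section_uri(policy: UriPolicy, section_id: str) -> URIRef:
    return policy.resource(section_id)


def _emit_section(g: Graph, sec: SectionNode, policy: UriPolicy) -> URIRef:
    node = section_uri(policy, sec.section_id)
    g.add((node, RDF.type, _SECTION_TYPE.get(sec.kind, DOCO.Section)))
    if sec.title:
        g.add((node, DCTERMS.title, Literal(sec.title)))
    direct_paragraphs = []
    for child in sec.children:
        if isinstance(child, ParagraphNode):
            p_node = paragraph_uri(policy, child.paragraph_id)
            g.add((node, DCTERMS.hasPart, p_node))
            g.add((p_node, RDF.type, DOCO.Paragraph))
            g.add((p_node, RDF.value, Literal(child.text)))
            direct_paragraphs.append(p_node)
        else:
            sub = _emit_section(g, child, policy)
            g.add((node, DCTERMS.hasPart, sub))
    if direct_paragraphs:
        plist = policy.resource(f"{sec.section_id}_paragraphList")
        g.add((node, BIOTEA.paragraphList, plist))
        g.add((plist, RDF.type, RDF.Seq))
        for i, p_node in enumerate(direct_paragraphs, start=1):
            g.add((plist, URIRef(f"{RDF}_{i}"), p_node))
    return node


def build_structure_graph(doc: DocumentRecord, cfg: BiblioGraphConfig) -> Graph:
    """Section/paragraph graph for one article, order preserving."""
    doc.validate()
    g = new_graph()
    policy = cfg.policy
    article = article_uri(policy, doc.pmcid)
    section_list = policy.resource(f"{doc.pmcid}_sectionList")
    g.add((article, BIOTEA.sectionList, section_list))
    g.add((section_list, RDF.type, RDF.Seq))
    for i, sec in enumerate(doc.body, start=1):
        node = _emit_section(g, sec, policy)
        g.add((section_list, URIRef(f"{RDF}_{i}"), node))
        g.add((section_list, DCTERMS.hasPart, node))
    _add_provenance(g, article, doc, cfg)
    return g
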