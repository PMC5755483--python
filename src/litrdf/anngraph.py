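"""Annotation serialization: Annotation Ontology (AO) and the Open
Annotation Data Model (OADM).

AO annotations are ``aot:ExactQualifier`` nodes: the matched surface as
``ao:body``, concept links via ``ao:hasTopic``, the document via
``ao:annotatesResource``, and one ``biotea:ElementSelector`` per target
paragraph reached through ``ao:context`` — annotations are localized
against the RDFized paragraph, never by character offsets into the
source file.

OADM annotations are ``oa:Annotation`` nodes carrying two body forms (a
``oa:TextualBody`` whose ``rdf:value`` is the surface text, plus direct
``oa:hasBody`` links to each concept IRI), ``oa:hasTarget`` straight to
each target paragraph resource and ``oa:hasSource`` to the document.
OADM is the default model.

Frequency terms (``biotea:tf``, ``biotea:idf``) are attached to each
annotation when enabled; idf literals are written with 6 decimal places
so output graphs compare stably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import List, Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, PROV, RDF, XSD

from .annotate import AnnotationRecord, CorpusStats, compute_idf
from .rdfcommon import AO, AOT, BIOTEA, OA, UriPolicy, default_policy, new_graph

__all__ = [
    "AnnotationGraphConfig",
    "to_ao_graph",
    "to_oadm_graph",
    "to_annotation_graph",
    "records_from_graph",
]


@dataclass(frozen=True)
class AnnotationGraphConfig:
    model: str = "OADM"  # default annotation model
    syntax: str = "rdfxml"
    policy: UriPolicy = field(default_factory=default_policy)
    creator: str = "http://purl.org/litrdf/agent"
    creation_time: str = "now"
    emit_frequency: bool = True
    stats: Optional[CorpusStats] = None  # enables biotea:idf emission

    def __post_init__(self) -> None:
        if self.model not in {"AO", "OADM"}:
            raise ValueError(f"unknown annotation model {self.model!r}")

    def timestamp(self) -> Literal:
        value = self.creation_time
        if value == "now":
            value = datetime.now(timezone.utc).isoformat(timespec="seconds")
        return Literal(value, datatype=XSD.dateTime)

    def creator_node(self) -> URIRef:
        if self.creator.startswith(("http://", "https://", "mailto:")):
            return URIRef(self.creator)
        return URIRef(f"mailto:{self.creator}")


def _add_header(g: Graph, doc_iri: URIRef, cfg: AnnotationGraphConfig) -> None:
    g.add((doc_iri, PROV.generatedAtTime, cfg.timestamp()))
    g.add((doc_iri, PAV_createdBy, cfg.creator_node()))


PAV_createdBy = URIRef("http://purl.org/pav/createdBy")


def _validate(records: List[AnnotationRecord]) -> None:
    for rec in records:
        if not rec.targets:
            raise ValueError(f"annotation {rec.body_text!r} has no targets")


def _add_frequency(
    g: Graph, ann: URIRef, rec: AnnotationRecord, cfg: AnnotationGraphConfig
) -> None:
    if not cfg.emit_frequency:
        return
    g.add((ann, BIOTEA.tf, Literal(rec.tf, datatype=XSD.integer)))
    if cfg.stats is not None:
        idfs = [
            compute_idf(cfg.stats, c) for c in sorted(rec.topics) if c in cfg.stats.df
        ]
        if idfs:
            # One idf literal per annotation; topics sharing a surface get
            # the minimum (most frequent concept) for a conservative weight.
            g.add(
                (ann, BIOTEA.idf, Literal(f"{min(idfs):.6f}", datatype=XSD.decimal))
            )


def to_ao_graph(
    records: List[AnnotationRecord], doc_iri: URIRef, cfg: AnnotationGraphConfig
) -> Graph:
    """Annotation Ontology serialization (ExactQualifier + ElementSelector)."""
    _validate(records)
    g = new_graph()
    policy = cfg.policy
    _add_header(g, doc_iri, cfg)
    selector_counter = 0
    for k, rec in enumerate(records, start=1):
        ann = policy.resource(f"{rec.doc}_annotationAO_{k}")
        g.add((ann, RDF.type, AOT.ExactQualifier))
        g.add((ann, AO.body, Literal(rec.body_text, datatype=XSD.string)))
        for topic in sorted(rec.topics):
            g.add((ann, AO.hasTopic, URIRef(topic)))
        g.add((ann, AO.annotatesResource, doc_iri))
        for target_id in rec.targets:
            selector_counter += 1
            sel = policy.resource(f"{rec.doc}_selector_{selector_counter}")
            g.add((ann, AO.context, sel))
            g.add((sel, RDF.type, BIOTEA.ElementSelector))
            g.add((sel, DCTERMS.references, policy.resource(target_id)))
            g.add((sel, AO.onResource, doc_iri))
        _add_frequency(g, ann, rec, cfg)
        g.add((ann, PAV_createdBy, cfg.creator_node()))
        g.add((ann, PROV.generatedAtTime, cfg.timestamp()))
    return g


def to_oadm_graph(
    records: List[AnnotationRecord], doc_iri: URIRef, cfg: AnnotationGraphConfig
) -> Graph:
    """Open Annotation Data Model serialization (hasBody/hasTarget/hasSource)."""
    _validate(records)
    g = new_graph()
    policy = cfg.policy
    _add_header(g, doc_iri, cfg)
    for k, rec in enumerate(records, start=1):
        ann = policy.resource(f"{rec.doc}_annotationOADM_{k}")
        g.add((ann, RDF.type, OA.Annotation))
        body = policy.resource(f"{rec.doc}_annotationOADM_{k}_body")
        g.add((ann, OA.hasBody, body))
        g.add((body, RDF.type, OA.TextualBody))
        g.add((body, RDF.value, Literal(rec.body_text)))
        for topic in sorted(rec.topics):
            g.add((ann, OA.hasBody, URIRef(topic)))
        for target_id in rec.targets:
            g.add((ann, OA.hasTarget, policy.resource(target_id)))
        g.add((ann, OA.hasSource, doc_iri))
        _add_frequency(g, ann, rec, cfg)
        g.add((ann, PAV_createdBy, cfg.creator_node()))
        g.add((ann, PROV.generatedAtTime, cfg.timestamp()))
    return g


def _numeric_aware_key(iri: str):
    import re as _re

    return [int(p) if p.isdigit() else p for p in _re.split(r"(\d+)", iri)]


def records_from_graph(g: Graph, policy: UriPolicy) -> List[AnnotationRecord]:
    """Recover :class:`AnnotationRecord` objects from an AO or OADM graph.

    This is the read-back path the clustering stage uses on serialized
    annotation files; record order follows the minted annotation IRIs.
    """

    def local(iri: URIRef, base: str) -> str:
        s = str(iri)
        return s[len(base):] if s.startswith(base) else s

    records: List[AnnotationRecord] = []
    oadm_anns = sorted(g.subjects(RDF.type, OA.Annotation), key=lambda s: _numeric_aware_key(str(s)))
    for ann in oadm_anns:
        body_text = ""
        topics = set()
        for b in g.objects(ann, OA.hasBody):
            value = g.value(b, RDF.value)
            if value is not None:
                body_text = str(value)
            else:
                topics.add(str(b))
        targets = sorted(
            (local(t, policy.resource_base) for t in g.objects(ann, OA.hasTarget)),
            key=_numeric_aware_key,
        )
        doc_iri = g.value(ann, OA.hasSource)
        tf = g.value(ann, BIOTEA.tf)
        records.append(
            AnnotationRecord(
                doc=local(doc_iri, policy.doc_base) if doc_iri else "",
                body_text=body_text,
                topics=topics,
                targets=targets,
                tf=int(tf) if tf is not None else 1,
            )
        )
    ao_anns = sorted(
        g.subjects(RDF.type, AOT.ExactQualifier), key=lambda s: _numeric_aware_key(str(s))
    )
    for ann in ao_anns:
        body = g.value(ann, AO.body)
        topics = {str(t) for t in g.objects(ann, AO.hasTopic)}
        targets = []
        for sel in g.objects(ann, AO.context):
            for ref in g.objects(sel, DCTERMS.references):
                targets.append(local(ref, policy.resource_base))
        targets.sort(key=_numeric_aware_key)
        doc_iri = g.value(ann, AO.annotatesResource)
        tf = g.value(ann, BIOTEA.tf)
        records.append(
            AnnotationRecord(
                doc=local(doc_iri, policy.doc_base) if doc_iri else "",
                body_text=str(body) if body is not None else "",
                topics=topics,
                targets=targets,
                tf=int(tf) if tf is not None else 1,
            )
        )
    return records


def to_annotation_graph(
    records: List[AnnotationRecord], doc_iri: URIRef, cfg: AnnotationGraphConfig
) -> Graph:
    """Dispatch on ``cfg.model``."""
    if cfg.model == "AO":
        return to_ao_graph(records, doc_iri, cfg)
    return to_oadm_graph(records, doc_iri, cfg)
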