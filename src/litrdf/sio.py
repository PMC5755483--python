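"""Rewrite a bibliographic/annotation graph into a SIO-compliant graph.

SIO (the Semanticscience Integrated Ontology) has a single datatype
property, ``sio:has-value``, so datatype statements cannot be mapped
property-for-property.  Each mapped datatype statement ``(s, p, "v")``
is encapsulated: ``s`` gets an object property to a minted node, the
node is typed with the mapped class, and the value (with a rule-level
prefix such as ``pmid:``) hangs off the node via ``sio:has-value``.

The rewrite is driven entirely by a key=value mapping file; mappings are
strictly 1-to-1 within each map (two sources sharing a target is a
configuration error, surfaced at load time, not silently collapsed).
Statements with no applicable rule are dropped with a logged warning so
the output can claim SIO compliance; pass-through is available behind a
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from .rdfcommon import SIO, expand_curie, new_graph

__all__ = ["MappingTable", "MappingError", "load_mapping", "map_graph", "default_sio_mapping"]

logger = logging.getLogger(__name__)

SIO_HAS_VALUE = SIO["has-value"]

#: minted encapsulation nodes live under this base by default
DEFAULT_VALUE_NODE_BASE = "http://linkingdata.io/pmcres/pmc/"


class MappingError(ValueError):
    """Invalid mapping file (syntax or a violated 1-to-1 constraint)."""


@dataclass
class MappingTable:
    """Class/object-property correspondences plus datatype-encapsulation rules."""

    class_map: Dict[URIRef, URIRef] = field(default_factory=dict)
    objprop_map: Dict[URIRef, URIRef] = field(default_factory=dict)
    dataprop_rules: Dict[URIRef, Tuple[URIRef, URIRef, str]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, mapping in (("class", self.class_map), ("objprop", self.objprop_map)):
            seen: Dict[URIRef, URIRef] = {}
            for src, dst in mapping.items():
                if dst in seen:
                    raise MappingError(
                        f"{name} mapping is not 1-to-1: {seen[dst]} and {src} "
                        f"both map to {dst}"
                    )
                seen[dst] = src
        seen_obj: Dict[Tuple[URIRef, URIRef, str], URIRef] = {}
        for src, rule in self.dataprop_rules.items():
            if rule in seen_obj:
                raise MappingError(
                    f"datatype rules are not 1-to-1: {seen_obj[rule]} and {src} "
                    f"both map to {rule}"
                )
            seen_obj[rule] = src


def _parse_line(line: str) -> Tuple[str, str]:
    if "=" not in line:
        raise MappingError(f"expected key=value, got {line!r}")
    key, _, value = line.partition("=")
    return key.strip(), value.strip()


def load_mapping(path) -> MappingTable:
    """Read a key=value mapping file.

    Keys are CURIEs (resolved against the namespace registry) prefixed
    by their section: ``class.``, ``objprop.`` or ``dataprop.``; a
    datatype rule value is ``objprop;class;prefix``.
    """
    table = MappingTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "!")):
                continue
            try:
                key, value = _parse_line(line)
                section, _, curie = key.partition(".")
                if section == "class":
                    table.class_map[expand_curie(curie)] = expand_curie(value)
                elif section == "objprop":
                    table.objprop_map[expand_curie(curie)] = expand_curie(value)
                elif section == "dataprop":
                    parts = value.split(";")
                    if len(parts) != 3:
                        raise MappingError(
                            "datatype rule value must be 'objprop;class;prefix'"
                        )
                    table.dataprop_rules[expand_curie(curie)] = (
                        expand_curie(parts[0]),
                        expand_curie(parts[1]),
                        parts[2],
                    )
                else:
                    raise MappingError(f"unknown section {section!r}")
            except MappingError as exc:
                raise MappingError(f"{path}:{lineno}: {exc}") from None
    table.validate()
    return table


def map_graph(
    g: Graph,
    table: MappingTable,
    value_node_base: str = DEFAULT_VALUE_NODE_BASE,
    passthrough: bool = False,
) -> Graph:
    """Apply the mapping table to every statement of ``g``.

    Deterministic: statements are processed in sorted order, and the
    minted encapsulation nodes are numbered in that order, so identical
    inputs yield isomorphic (indeed identical) outputs.
    """
    out = new_graph()
    counter = 0
    for s, p, o in sorted(g):
        if p == RDF.type:
            if o in table.class_map:
                out.add((s, RDF.type, table.class_map[o]))
            elif passthrough:
                out.add((s, p, o))
            else:
                logger.warning("dropping unmapped type statement: %s a %s", s, o)
        elif isinstance(o, Literal):
            if p in table.dataprop_rules:
                objprop, cls, prefix = table.dataprop_rules[p]
                counter += 1
                node = URIRef(f"{value_node_base}value_{counter}")
                out.add((s, objprop, node))
                out.add((node, RDF.type, cls))
                out.add((node, SIO_HAS_VALUE, Literal(prefix + str(o))))
            elif passthrough:
                out.add((s, p, o))
            else:
                logger.warning("dropping unmapped datatype statement: %s %s", s, p)
        else:
            if p in table.objprop_map:
                out.add((s, table.objprop_map[p], o))
            elif passthrough:
                out.add((s, p, o))
            else:
                logger.warning("dropping unmapped object statement: %s %s", s, p)
    return out


def default_sio_mapping_path():
    """Filesystem path of the shipped Biotea-vocabulary → SIO profile."""
    from importlib.resources import as_file, files

    ref = files("litrdf.data").joinpath("sio_mapping.properties")
    with as_file(ref) as path:
        return path


def default_sio_mapping() -> MappingTable:
    """The shipped Biotea-vocabulary → SIO profile."""
    return load_mapping(default_sio_mapping_path())
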