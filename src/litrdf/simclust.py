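"""Annotation-vector similarity and document clustering.

Per-document feature vectors map ontology concepts to weights (raw term
frequency, tf·idf, or binary presence), optionally restricted to the
concepts of selected ontologies.  Document similarity is the cosine
over the union of concepts; distance is ``1 − cosine``.  Corpora are
clustered by hierarchical agglomeration with the complete-linkage
criterion (inter-cluster distance = maximum pairwise member distance),
which is monotone, so merge heights never decrease.  Ties are broken by
the lexicographically smallest member id so runs are reproducible.

Dendrograms export to Newick with ultrametric branch lengths (leaf
depth = merge height / 2); distance matrices export to symmetric CSV
with document-id headers, ready for any heatmap renderer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotate import AnnotationRecord, CorpusStats, LexiconEntry, compute_idf

__all__ = [
    "FeatureVector",
    "Dendrogram",
    "concept_ontologies",
    "build_vectors",
    "cosine_similarity",
    "cosine_distance",
    "distance_matrix",
    "cluster_complete_linkage",
    "export_newick",
    "export_heatmap",
]


@dataclass
class FeatureVector:
    """Concept→weight map for one document; zero weights are never stored."""

    doc: str
    weights: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = {c: float(w) for c, w in self.weights.items() if w != 0}

    def norm(self) -> float:
        # hypot is under/overflow-safe for extreme weights
        return math.hypot(*self.weights.values()) if self.weights else 0.0


def concept_ontologies(lexicon: Iterable[LexiconEntry]) -> Dict[str, str]:
    """concept IRI → ontology acronym, derived from a lexicon."""
    return {e.concept_iri: e.ontology for e in lexicon}


def build_vectors(
    annotations: Mapping[str, List[AnnotationRecord]],
    ontology_filter: Optional[Iterable[str]] = None,
    weighting: str = "tf",
    stats: Optional[CorpusStats] = None,
    concept_ontology: Optional[Mapping[str, str]] = None,
) -> List[FeatureVector]:
    """One feature vector per document, in the input document order.

    ``weighting`` is ``tf`` (raw counts), ``tfidf`` (counts scaled by
    log10(N/df); requires ``stats``) or ``binary``.  When
    ``ontology_filter`` is given, ``concept_ontology`` must map concept
    IRIs to acronyms (see :func:`concept_ontologies`).
    """
    if weighting not in {"tf", "tfidf", "binary"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "tfidf" and stats is None:
        raise ValueError("tfidf weighting requires corpus stats")
    wanted = set(ontology_filter) if ontology_filter is not None else None
    if wanted is not None and concept_ontology is None:
        raise ValueError("ontology_filter requires a concept→ontology map")

    vectors: List[FeatureVector] = []
    for doc, records in annotations.items():
        tf: Dict[str, float] = {}
        for rec in records:
            for concept in rec.topics:
                if wanted is not None and concept_ontology.get(concept) not in wanted:
                    continue
                tf[concept] = tf.get(concept, 0.0) + rec.tf
        if weighting == "binary":
            weights = {c: 1.0 for c in tf}
        elif weighting == "tfidf":
            weights = {
                c: v * compute_idf(stats, c) for c, v in tf.items() if c in stats.df
            }
        else:
            weights = tf
        vectors.append(FeatureVector(doc=doc, weights=weights))
    return vectors


def cosine_similarity(u: FeatureVector, v: FeatureVector) -> float:
    """Cosine of two non-negative concept vectors, in [0, 1]."""
    nu, nv = u.norm(), v.norm()
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for an all-zero vector")
    # normalize before the dot product so extreme weights cannot underflow
    dot = sum((w / nu) * (v.weights.get(c, 0.0) / nv) for c, w in u.weights.items())
    return min(1.0, dot)


def cosine_distance(u: FeatureVector, v: FeatureVector) -> float:
    return 1.0 - cosine_similarity(u, v)


def distance_matrix(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Symmetric cosine-distance matrix with document ids as labels."""
    docs = [v.doc for v in vectors]
    n = len(vectors)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = cosine_distance(vectors[i], vectors[j])
    return pd.DataFrame(m, index=docs, columns=docs)


@dataclass
class Dendrogram:
    """Binary merge tree; leaves are document ids, internal nodes carry
    the merge distance as their height."""

    height: float = 0.0
    leaf: Optional[str] = None
    children: List["Dendrogram"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.leaf]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def merge_heights(self) -> List[float]:
        """All internal-node heights, bottom-up (children before parents)."""
        if self.is_leaf:
            return []
        out: List[float] = []
        for c in self.children:
            out.extend(c.merge_heights())
        out.append(self.height)
        return out


DistInput = Union[Callable[[str, str], float], pd.DataFrame]


def _dist_fn(dist: DistInput) -> Callable[[str, str], float]:
    if callable(dist):
        return dist
    return lambda a, b: float(dist.loc[a, b])


def cluster_complete_linkage(docs: Sequence[str], dist: DistInput) -> Dendrogram:
    """Agglomerative clustering under the complete-linkage criterion.

    ``dist`` is a symmetric pairwise distance function or a labelled
    distance matrix.  At each step the pair of clusters with minimal
    maximum member distance is merged; exact ties go to the pair whose
    member ids sort lexicographically smallest.
    """
    if len(docs) < 2:
        raise ValueError("clustering requires at least 2 documents")
    if len(set(docs)) != len(docs):
        raise ValueError("document ids must be unique")
    d = _dist_fn(dist)

    active: List[Dendrogram] = [Dendrogram(leaf=doc) for doc in docs]
    members: Dict[int, List[str]] = {i: [doc] for i, doc in enumerate(docs)}

    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                link = max(d(a, b) for a in members[i] for b in members[j])
                key = (link, sorted(members[i] + members[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (link, _), i, j = best
        node = Dendrogram(height=link, children=[active[i], active[j]])
        merged = sorted(members[i] + members[j])
        new_active = [c for k, c in enumerate(active) if k not in (i, j)]
        new_members = {
            k: members[old_k]
            for k, old_k in enumerate(k for k in range(len(active)) if k not in (i, j))
        }
        new_active.append(node)
        new_members[len(new_active) - 1] = merged
        active, members = new_active, new_members
    return active[0]


def export_newick(tree: Dendrogram) -> str:
    """Newick string with ultrametric branch lengths.

    Every leaf sits at depth ``root.height / 2``, so the branch length
    into a child is ``(parent.height − child.height) / 2`` with leaves
    at height 0.
    """

    def fmt(node: Dendrogram) -> str:
        if node.is_leaf:
            return node.leaf
        inner = ",".join(
            f"{fmt(c)}:{(node.height - (0.0 if c.is_leaf else c.height)) / 2:g}"
            for c in node.children
        )
        return f"({inner})"

    return fmt(tree) + ";"


def export_heatmap(matrix: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a symmetric labelled distance matrix as delimited text."""
    matrix.to_csv(path, sep=sep)
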