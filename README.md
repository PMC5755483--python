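# litrdf

Linked-data RDFization, ontology-concept annotation and similarity
analysis for scholarly articles in JATS/XML (the PubMed Central
open-access dialect).

Most full-text biomedical literature is distributed as XML that is easy
to render and hard to query. `litrdf` turns each article into RDF graphs
built from the standard bibliographic and document-structure
vocabularies (BIBO, DoCO, DCTERMS, FOAF, PROV), recognizes biomedical
ontology concepts in the text with a dictionary engine, serializes those
annotations in either the Annotation Ontology (AO) or the W3C Open
Annotation Data Model (OADM), and supports corpus analysis over the
result: tf·idf concept vectors, cosine distance and complete-linkage
hierarchical clustering. A configurable mapping table additionally
rewrites any produced graph into a SIO-compliant form so the output can
join datasets modeled with the Semanticscience Integrated Ontology
(e.g., Bio2RDF).

## The model in brief

* **Publication parsing.** One JATS article yields two graphs. The
  *metadata + references* graph types the article `bibo:AcademicArticle`,
  carries ids (`bibo:pmid`, `bibo:doi`), an ordered `biotea:authorList`
  (`rdf:Seq`), `owl:sameAs` links to Bio2RDF / identifiers.org / the DOI
  resolver and `rdfs:seeAlso` links to the PubMed pages, and symmetric
  `bibo:cites` / `bibo:citedBy` reference edges. The *structure +
  content* graph represents sections as `doco:Section` nodes in an
  order-preserving `rdf:Seq`, nests them with `dcterms:hasPart`, and
  stores each paragraph's text as the `rdf:value` of a `doco:Paragraph`
  whose IRI encodes its position, e.g.
  `3879346_paragraph_Introduction_para_1`.
* **Semantic enrichment.** A lexicon (surface → concept IRI → ontology)
  drives exact, token-bounded, longest-match-wins concept recognition;
  the back-end is pluggable, so any producer of annotation records can
  substitute for the built-in engine. Each annotation carries its term
  frequency `tf` and inverse document frequency `idf = log10(N/df)`.
  Annotations are localized against RDFized paragraphs, never by
  character offsets, so a SPARQL query can ask for, say, two concepts
  co-occurring in one paragraph of the "Materials and Methods" section.
* **Similarity.** Per-document concept vectors (tf, tf·idf or binary
  weights; optionally restricted to one ontology) are compared with
  cosine similarity; corpora are clustered by hierarchical agglomeration
  under the complete-linkage criterion with dendrogram (Newick) and
  distance-matrix (CSV) exports.

## Worked example

```sh
# 1. synthesize a 3-article corpus with planted SNOMED CT terms
litrdf make-fixtures corpus --n-docs 3 --seed 7

# 2. metadata + content graphs per article
litrdf rdfize corpus out --fixed-time

# 3. annotate against the built-in SNOMED CT lexicon (OADM by default)
litrdf annotate corpus ann --lexicon corpus/lexicon.tsv --fixed-time

# 4. rewrite one graph into SIO form
litrdf map-sio out/1000001.rdf --out-dir sio

# 5. cluster the annotated corpus
litrdf cluster ann/*_annotations_oadm.rdf --out-newick tree.nwk --out-heatmap dist.csv
```

Step 5 prints `clustered 3 documents` and writes

```
(1000001:0.232739,(1000002:0.0527864,1000003:0.0527864):0.179952);
```

— documents 1000002 and 1000003 (which share only the ubiquitous planted
term) merge first at cosine distance ≈ 0.105, and document 1000001
(which additionally carries three occurrences of *Polymerase chain
reaction*) joins at ≈ 0.465; branch lengths are halved merge heights
(ultrametric convention). `dist.csv` is the symmetric cosine-distance
matrix behind the tree, and `ann/frequency.tsv` lists per-document
`tf`/`idf` for every recognized concept, e.g. `Carcinoma → snomedct
68453008` with `idf = 0` because it was planted in every document.

The same operations are available as a library:

```python
from litrdf import parse_jats, annotate_document, tables_lexicon

doc = parse_jats(open("corpus/1000001.xml", "rb").read())
for rec in annotate_document(doc, tables_lexicon()):
    print(rec.body_text, sorted(rec.topics), rec.tf, rec.targets)
```

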