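# Methods

## Scope and pipeline

`litrdf` implements a two-stage RDFization pipeline for JATS/XML
articles plus downstream similarity analysis. Stage one (publication
parsing) is deterministic and purely structural; stage two (semantic
enrichment) depends on a user-supplied lexicon and produces annotation
graphs and frequency statistics. All graphs are plain RDF
(subject–predicate–object statements with namespace bindings) carried
as `rdflib.Graph`, serialized as RDF/XML or JSON-LD; N-Triples is
available for canonical comparison in tests. Live annotation web
services are out of scope by design: the annotator interface accepts any
producer of annotation records, and the built-in engine is a dictionary
matcher.

## Document model and parsing

A parsed article is a `DocumentRecord`: identifiers (PMC id required;
PMID and DOI optional), title, a single abstract block (structured
abstracts are flattened — the model has one abstract per article),
keywords, journal info, an ordered author list, an ordered reference
list, and the body as a tree of sections holding paragraphs.

Parsing choices:

* Inline markup (`italic`, `xref`, `sup`, …) is flattened: paragraph
  text is the concatenated character data, because downstream the text
  is carried as a single `rdf:value` literal with no inline structure.
* Whitespace is canonicalized (runs collapsed, ends trimmed); the
  normalization is idempotent. Annotations are paragraph-relative, so a
  canonical text form is required.
* Paragraph ids are `"{pmcid}_paragraph_{Label}_para_{n}"` where
  `Label` is the nearest enclosing *titled* section title with spaces
  removed and non-alphanumerics dropped (`Materials and Methods` →
  `MaterialsandMethods`), and `n` is a 1-based counter per label.
  Untitled subsections inherit the nearest titled ancestor's label with
  the counter continuing, which keeps ids unique when two sections share
  a title. Sections with no titled ancestor get a positional
  `SectionN` label. Body-level paragraphs outside any section are
  wrapped in a synthetic `Body` section so every paragraph is
  addressable.
* Tables and figures are recorded as typed hook nodes
  (`doco:Table` / `doco:Figure`); their internal content is not
  decomposed.
* Unrecognized reference publication types fall back to a generic
  document type; the type map is a closed list (article, book, chapter,
  proceedings, other).

## URI policy

Article resources live under a configurable `doc_base` and every
derived resource (sections, paragraphs, lists, selectors, annotations,
minted value nodes) under `resource_base`. Blank nodes are avoided
throughout: minted IRIs keep serialization byte-stable under a fixed
timestamp and make the graphs joinable across files. Two published
naming schemes exist for this kind of data (a `linkingdata.io` document
space, and a `bio2rdf.org` CURIE-style space); the default is the
former and `bio2rdf_policy()` provides the latter, with slash-style
IRIs for list nodes.

## Annotation engine

Matching is exact and dictionary-based: no stemming, no lexical
variants, no word-sense disambiguation, no machine-learned NER. The
rules are:

* token boundaries are transitions between alphanumerics and
  non-alphanumerics (so `AJCC` never fires inside `subAJCC`, while
  hyphens and spaces inside multiword lexicon terms are matched
  literally);
* case-insensitive by default (configurable);
* longest match wins on overlaps, leftmost on equal length, and
  counting is non-overlapping. Implementation: a compiled alternation
  sorted longest-first with boundary lookarounds, which realizes
  exactly these semantics; tests cross-check it against an independent
  naive scanning oracle.

`tf` is document-scoped: one record per distinct surface per document,
with the total occurrence count over the annotated scope and the list
of target paragraphs in document order. The scope is either full text
(title + abstract + body) or title/abstract only; the latter is always
a subset of the former. `idf = log10(N / df)` with `N` the number of
processed documents (including unannotated ones) and `df` the number of
documents containing the concept; the base-10 logarithm is a fixed
package convention used consistently in emission and weighting, and
`idf = 0` exactly when a concept occurs in every document.

## Annotation serialization

AO output uses `aot:ExactQualifier` with `ao:body`, `ao:hasTopic`,
`ao:annotatesResource`, and one `biotea:ElementSelector` per target
paragraph via `ao:context` (`dcterms:references` the paragraph,
`ao:onResource` the document). OADM output (the default model) emits
`oa:Annotation` with two body forms — an `oa:TextualBody` carrying the
surface text as `rdf:value`, and direct `oa:hasBody` links to each
concept IRI — so both text-pattern and concept queries work.
`oa:hasTarget` links *directly* to the paragraph resource (keeping
one-join SPARQL over paragraphs), and `oa:hasSource` links the
annotation to the document. No character offsets into the source XML
appear anywhere: localization is entirely paragraph-relative.

Annotation and selector IRIs are minted with per-document counters in
record order; `idf` literals are written with 6 decimal places. Both
choices exist to make output graphs deterministic and comparable.

## SIO mapping

The rewrite engine is table-driven (key=value file; CURIE keys in
`class.`, `objprop.` and `dataprop.` sections). Type statements and
object-property statements are rewritten 1-to-1; a datatype statement
`(s, p, "v")` becomes three statements through its rule
`(objprop, class, prefix)`: `s --objprop--> b`, `b a class`,
`b sio:has-value "prefix+v"`, with `b` a deterministically minted node —
SIO has a single datatype property, so values must be encapsulated.
The 1-to-1 constraint is enforced at load time (a 2-to-1 file is a
configuration error naming both keys), making the known limitation of
mapping-table approaches explicit rather than silent. Unmapped
statements are dropped with a logged warning so the output can claim
SIO compliance; `passthrough=True` keeps them. The shipped profile
covers the bibliographic classes, citation properties and identifier
datatype rules; new target models are just new files.

## Vectors, cosine, clustering

Feature vectors sum `tf` per concept over a document's records,
optionally restricted to one ontology (the concept→ontology map comes
from the lexicon) and weighted as raw tf (the default for clustering,
exposed as a flag), tf·idf, or binary. Cosine similarity is computed on
norm-scaled vectors (underflow-safe for extreme weights) and clamped to
[0, 1]; distance is `1 − cosine`; a zero vector is an error rather than
a silent 0.

Clustering is hierarchical agglomeration under complete linkage
(inter-cluster distance = maximum pairwise member distance), implemented
directly as the O(n³) textbook procedure because the package fixes a
deterministic tie-break — among minimal-distance pairs, the merge whose
member ids sort lexicographically smallest wins — that off-the-shelf
implementations do not specify. scipy's `linkage` serves as an
independent cross-check on tie-free random instances in the test suite.
Complete linkage is monotone, so merge heights never decrease.

Newick export uses the ultrametric convention: every leaf sits at depth
`root height / 2`, so a two-leaf tree of height *h* serializes as
`(A:h/2,B:h/2);`. The distance matrix exports as symmetric labelled
CSV for heatmap rendering.

## Synthetic data

The fixture generator emulates PMC-OA JATS articles: front matter with
ids, journal metadata and authors; a body of titled sections with
paragraphs; back matter with mixed-type references. Filler text is
drawn from a fixed list of nonsense words disjoint from every lexicon
surface, so planted term frequencies are exact by construction:
`make_corpus` places each planted term token-bounded and
non-overlapping, exactly `tf` times per designated document, and
returns the ground-truth table.

What the generator does *not* emulate: real front-matter richness
(affiliations, funding groups), inline markup inside planted
paragraphs, lexical variation and real word statistics, and ambiguous
surfaces ("harbor" as verb vs. concept). Passing tests therefore
demonstrate the mechanics — parsing fidelity, graph shapes, exact-match
counting, clustering correctness — not recognition quality on real
prose, which for dictionary matching is bounded by the lexicon and the
exact-match assumption.

The built-in lexicon is a 13-term SNOMED CT table (cancer, patient,
sample and method terms from a published worked example), resolved
under the BioPortal SNOMED CT namespace; production lexicons are
user-supplied TSV files, since realistic annotation uses dozens of
ontologies with licensing that precludes bundling.

## Problem sizes and numerical choices

The test suite runs corpora of 1–3 articles with up to ~6 paragraphs,
random SIO fixtures up to 40 statements, and clustering instances up to
n = 50 documents — sizes at which the brute-force oracles used for
cross-checking remain exact and the full suite completes in seconds.
Timestamps are fixed in tests (`--fixed-time` in the CLI) because
provenance literals are the only nondeterministic output; with a fixed
timestamp, identical inputs produce byte-identical files.

## Known limitations

* Exact dictionary matching cannot disambiguate; stop-word lists are
  the only mitigation, as with any Mgrep-style matcher.
* The SIO rewrite drops what it cannot map; fidelity is bounded by the
  profile file.
* Keyword predicate choice (`dcterms:subject` by default) and the
  publisher-as-literal representation are configurable simplifications.
* No Turtle or HDT serialization; no SPARQL endpoint hosting; no
  federated querying. Queries run client-side over the generated
  graphs.
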