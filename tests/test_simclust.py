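"""Feature vectors, cosine similarity, complete-linkage clustering and
exports, cross-checked against scipy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from litrdf import (
    AnnotationRecord,
    CorpusStats,
    FeatureVector,
    build_vectors,
    cluster_complete_linkage,
    cosine_distance,
    cosine_similarity,
    distance_matrix,
    export_heatmap,
    export_newick,
)
from litrdf.simclust import concept_ontologies
from litrdf.fixtures import tables_lexicon


def rec(doc, concept, tf):
    return AnnotationRecord(
        doc=doc, body_text=concept, topics={f"http://x/{concept}"}, targets=["t"], tf=tf
    )


class TestBuildVectors:
    def test_tf_weighting_is_identity(self):
        vecs = build_vectors({"d": [rec("d", "c1", 2), rec("d", "c2", 1)]})
        assert vecs[0].weights == {"http://x/c1": 2.0, "http://x/c2": 1.0}

    def test_binary_weighting(self):
        vecs = build_vectors(
            {"d": [rec("d", "c1", 2), rec("d", "c2", 1)]}, weighting="binary"
        )
        assert vecs[0].weights == {"http://x/c1": 1.0, "http://x/c2": 1.0}

    def test_tfidf_drops_zero_idf_concepts(self):
        stats = CorpusStats(n_docs=10, df={"http://x/c1": 10, "http://x/c2": 1})
        vecs = build_vectors(
            {"d": [rec("d", "c1", 2), rec("d", "c2", 1)]},
            weighting="tfidf",
            stats=stats,
        )
        assert vecs[0].weights == {"http://x/c2": pytest.approx(1.0)}

    def test_tfidf_without_stats_is_error(self):
        with pytest.raises(ValueError):
            build_vectors({"d": []}, weighting="tfidf")

    def test_ontology_filter_restricts_concepts(self):
        lexicon = tables_lexicon()
        carcinoma = lexicon[0].concept_iri
        records = {
            "d": [
                AnnotationRecord(
                    doc="d", body_text="Carcinoma", topics={carcinoma}, targets=["t"], tf=1
                ),
                AnnotationRecord(
                    doc="d", body_text="x", topics={"http://x/other"}, targets=["t"], tf=5
                ),
            ]
        }
        vecs = build_vectors(
            records,
            ontology_filter={"SNOMEDCT"},
            concept_ontology=concept_ontologies(lexicon),
        )
        assert vecs[0].weights == {carcinoma: 1.0}


class TestCosine:
    def test_identical_vectors(self):
        v = FeatureVector("a", {"x": 3, "y": 4})
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_vectors_orthogonal(self):
        assert cosine_similarity(
            FeatureVector("a", {"x": 1}), FeatureVector("b", {"y": 1})
        ) == 0.0

    def test_hand_computed_example(self):
        u = FeatureVector("a", {"a": 1, "b": 2})
        v = FeatureVector("b", {"a": 2, "b": 1})
        assert cosine_similarity(u, v) == pytest.approx(0.8)

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError):
            cosine_similarity(FeatureVector("a", {}), FeatureVector("b", {"x": 1}))

    @settings(max_examples=60, derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from("abcdefg"),
            st.floats(min_value=0, max_value=50, allow_nan=False),
            min_size=1,
        ),
        st.dictionaries(
            st.sampled_from("abcdefg"),
            st.floats(min_value=0, max_value=50, allow_nan=False),
            min_size=1,
        ),
    )
    def test_symmetry_and_range(self, wu, wv):
        u, v = FeatureVector("u", wu), FeatureVector("v", wv)
        if not u.weights or not v.weights:
            return
        s1, s2 = cosine_similarity(u, v), cosine_similarity(v, u)
        assert s1 == pytest.approx(s2)
        assert 0.0 <= s1 <= 1.0


def cophenetic_from_tree(tree, docs):
    """Pairwise merge heights implied by a dendrogram."""
    n = len(docs)
    idx = {d: i for i, d in enumerate(docs)}
    m = np.zeros((n, n))

    def walk(node):
        if node.is_leaf:
            return [node.leaf]
        groups = [walk(c) for c in node.children]
        for i, gi in enumerate(groups):
            for gj in groups[i + 1 :]:
                for a in gi:
                    for b in gj:
                        m[idx[a], idx[b]] = m[idx[b], idx[a]] = node.height
        return [leaf for grp in groups for leaf in grp]

    walk(tree)
    return m


class TestClustering:
    def test_two_docs_single_merge_at_their_distance(self):
        d = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["A", "B"], columns=["A", "B"])
        tree = cluster_complete_linkage(["A", "B"], d)
        assert tree.height == pytest.approx(0.3)
        assert sorted(tree.leaves()) == ["A", "B"]

    def test_three_docs_hand_derived_merge_order(self):
        docs = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]], index=docs, columns=docs
        )
        tree = cluster_complete_linkage(docs, d)
        assert tree.merge_heights() == [pytest.approx(0.1), pytest.approx(0.9)]
        first_merge = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(first_merge.leaves()) == ["A", "B"]

    def test_fewer_than_two_docs_is_error(self):
        with pytest.raises(ValueError):
            cluster_complete_linkage(["A"], lambda a, b: 0.0)

    def test_monotone_merge_heights_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(3, 12))
            docs = [f"d{i}" for i in range(n)]
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = cluster_complete_linkage(docs, pd.DataFrame(m, index=docs, columns=docs))
            heights = tree.merge_heights()
            # children are visited before parents, and within the binary
            # tree every parent height bounds its subtree's heights
            def check(node):
                if node.is_leaf:
                    return 0.0
                child_max = max(check(c) for c in node.children)
                assert node.height >= child_max - 1e-12
                return node.height

            check(tree)

    @pytest.mark.parametrize("n", [4, 10, 25, 50])
    def test_agreement_with_scipy_reference(self, n):
        rng = np.random.default_rng(n)
        docs = [f"doc{i:02d}" for i in range(n)]
        # distinct random distances: tie-free, so tie-break policy is moot
        condensed = rng.permutation(np.linspace(0.1, 0.9, n * (n - 1) // 2))
        m = squareform(condensed)
        tree = cluster_complete_linkage(docs, pd.DataFrame(m, index=docs, columns=docs))
        ours = cophenetic_from_tree(tree, docs)
        Z = linkage(condensed, method="complete")
        theirs = squareform(cophenet(Z))
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_lexicographic_tie_break(self):
        docs = ["C", "B", "A"]
        d = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=docs, columns=docs)
        tree = cluster_complete_linkage(docs, d)
        first = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(first.leaves()) == ["A", "B"]


class TestExports:
    def test_two_leaf_newick_ultrametric(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        tree = cluster_complete_linkage(["A", "B"], d)
        assert export_newick(tree) == "(A:0.2,B:0.2);"

    def test_newick_parse_back_preserves_topology(self):
        import dendropy

        docs = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 0.1, 0.9], [0.1, 0, 0.8], [0.9, 0.8, 0]], index=docs, columns=docs
        )
        tree = cluster_complete_linkage(docs, d)
        parsed = dendropy.Tree.get(data=export_newick(tree), schema="newick")
        sibling_pairs = [
            sorted(leaf.taxon.label for leaf in node.leaf_iter())
            for node in parsed if not node.is_leaf()
        ]
        assert ["A", "B"] in sibling_pairs

    def test_heatmap_export_symmetric_with_headers(self, tmp_path):
        vectors = [
            FeatureVector("A", {"x": 1}),
            FeatureVector("B", {"x": 1, "y": 1}),
            FeatureVector("C", {"y": 1}),
        ]
        m = distance_matrix(vectors)
        out = tmp_path / "heat.csv"
        export_heatmap(m, out)
        back = pd.read_csv(out, index_col=0)
        assert list(back.columns) == ["A", "B", "C"]
        assert np.allclose(back.values, back.values.T)
        assert np.allclose(np.diag(back.values), 0)
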