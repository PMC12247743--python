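"""Weisfeiler-Lehman labeling, documents and embedding training."""

import random
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphtcr import (AMINO_ACIDS, FeatureConfig, build_documents,
                      embed_sequences, graph_document, initial_labels,
                      seq_to_graph, train_embeddings, wl_iterate)
from graphtcr.peptide_graph import MolecularGraph
from graphtcr.wl import infer_embedding

ELEM_ONLY = FeatureConfig(node_features={"atomic_number"},
                          edge_features=frozenset())
NON_ATTR = FeatureConfig(node_features=frozenset(), edge_features=frozenset(),
                         non_attributed=True)


def permute_graph(g: MolecularGraph, perm: list[int]) -> MolecularGraph:
    """Relabel node indices by ``perm`` (new index of old node i)."""
    import copy
    nodes = [None] * len(g.nodes)
    for old, new in enumerate(perm):
        n = copy.copy(g.nodes[old])
        n.index = new
        nodes[new] = n
    edges = []
    for e in g.edges:
        e2 = copy.copy(e)
        e2.endpoints = (perm[e.endpoints[0]], perm[e.endpoints[1]])
        edges.append(e2)
    return MolecularGraph(nodes=nodes, edges=edges,
                          source_sequence=g.source_sequence)


class TestLabels:
    def test_glycine_initial_element_labels(self):
        g = seq_to_graph("G")
        assert initial_labels(g, ELEM_ONLY).distinct(0) == 3  # N, C, O

    def test_glycine_initial_with_hydrogens(self):
        cfg = FeatureConfig(node_features={"atomic_number", "total_hydrogens"},
                            edge_features=frozenset())
        assert initial_labels(seq_to_graph("G"), cfg).distinct(0) == 5

    def test_non_attributed_single_label(self):
        for seq in ["G", "W", "CASSF"]:
            assert initial_labels(seq_to_graph(seq), NON_ATTR).distinct(0) == 1

    def test_glycine_one_iteration_no_edge_labels(self):
        g = seq_to_graph("G")
        lab = wl_iterate(g, initial_labels(g, ELEM_ONLY),
                         use_edge_labels=False, edge_config=ELEM_ONLY)
        # the two oxygens stay merged: both see neighbor multiset {C}
        assert lab.distinct(1) == 4

    def test_glycine_one_iteration_with_bond_type(self):
        g = seq_to_graph("G")
        cfg = FeatureConfig(node_features={"atomic_number"},
                            edge_features={"bond_type"})
        lab = wl_iterate(g, initial_labels(g, cfg),
                         use_edge_labels=True, edge_config=cfg)
        # carbonyl =O (double) separates from hydroxyl -O (single)
        assert lab.distinct(1) == 5

    def test_refinement_monotone(self):
        g = seq_to_graph("CASSF")
        lab = initial_labels(g, FeatureConfig())
        for _ in range(5):
            lab = wl_iterate(g, lab)
        counts = [lab.distinct(t) for t in range(lab.k + 1)]
        assert counts == sorted(counts)

    def test_hash_stable_across_runs(self):
        # frozen BLAKE2b-128 digest: must never change across processes
        g = seq_to_graph("G")
        lab = wl_iterate(g, initial_labels(g, ELEM_ONLY),
                         use_edge_labels=False, edge_config=ELEM_ONLY)
        assert lab.labels[1][0] == "530580d457704a301f4d68606402236a"


class TestDocuments:
    def test_document_size_law(self):
        for seq, k in [("G", 1), ("G", 0), ("CASSF", 5), ("WY", 3)]:
            g = seq_to_graph(seq)
            doc = graph_document(g, k)
            assert len(doc.tokens) == len(g.nodes) * (k + 1)

    def test_k0_tokens_are_initial_labels(self):
        g = seq_to_graph("AG")
        doc = graph_document(g, 0, ELEM_ONLY)
        assert Counter(doc.tokens) == Counter(initial_labels(g, ELEM_ONLY).labels[0])

    def test_glycine_k1_has_ten_tokens(self):
        assert len(graph_document(seq_to_graph("G"), 1).tokens) == 10

    def test_permutation_invariance(self):
        g = seq_to_graph("CAW")
        doc = Counter(graph_document(g, 3).tokens)
        rnd = random.Random(3)
        for _ in range(20):
            perm = list(range(len(g.nodes)))
            rnd.shuffle(perm)
            assert Counter(graph_document(permute_graph(g, perm), 3).tokens) == doc

    def test_non_attributed_sees_structure_only(self):
        # same connectivity, different elements -> identical documents
        g1 = seq_to_graph("A")
        g2 = seq_to_graph("A")
        for n in g2.nodes:
            n.element = 6
            n.total_hydrogens = 0
        d1 = graph_document(g1, 3, NON_ATTR, use_edge_labels=False)
        d2 = graph_document(g2, 3, NON_ATTR, use_edge_labels=False)
        assert Counter(d1.tokens) == Counter(d2.tokens)

    def test_provenance_residue_windows_grow_with_iteration(self):
        g = seq_to_graph("GGGG")
        doc = graph_document(g, 5)
        for occ in doc.provenance:
            assert occ.root_residue in occ.residues
            assert all(0 <= r < 4 for r in occ.residues)
        span0 = [occ for occ in doc.provenance if occ.iteration == 0]
        assert all(len(occ.residues) == 1 for occ in span0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            graph_document(seq_to_graph("G"), -1)


@settings(max_examples=20, deadline=None)
@given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=8),
       st.integers(min_value=0, max_value=4))
def test_document_size_law_property(seq, k):
    g = seq_to_graph(seq)
    assert len(graph_document(g, k).tokens) == len(g.nodes) * (k + 1)


class TestTraining:
    def test_shape_and_finiteness(self):
        docs = build_documents(["GG", "AC", "WY"], k=2)
        emb = train_embeddings(docs, dimensions=16, epochs=2, seed=5)
        assert emb.vectors.shape == (3, 16)
        assert np.isfinite(emb.vectors).all()

    def test_bitwise_determinism(self):
        docs = build_documents(["GG", "AC", "WY", "PP"], k=3)
        e1 = train_embeddings(docs, dimensions=8, epochs=3, seed=9)
        e2 = train_embeddings(docs, dimensions=8, epochs=3, seed=9)
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_isomorphic_block_more_similar(self):
        # 10 identical-document graphs vs 10 distinct ones: the identical
        # block must be more self-similar on average, over 10 seeds
        from conftest import random_peptides
        seqs = ["CASSGGGGF"] * 10 + random_peptides(10, min_len=8, max_len=12, seed=4)
        docs = build_documents(seqs, k=3)
        margins = []
        for seed in range(10):
            emb = train_embeddings(docs, dimensions=16, epochs=5, seed=seed)
            V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
            S = V @ V.T
            iu = np.triu_indices(20, 1)
            block = S[:10, :10][np.triu_indices(10, 1)].mean()
            cross = S[:10, 10:].mean()
            margins.append(block - cross)
        assert np.mean(margins) > 0

    def test_empty_corpus_and_bad_dims_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings([], dimensions=8)
        docs = build_documents(["GG"], k=1)
        with pytest.raises(ValueError):
            train_embeddings(docs, dimensions=0)

    def test_embed_sequences_convenience(self):
        emb = embed_sequences(["GG", "ACA", "GG", "WY", "PEP"], k=5,
                              dimensions=256, epochs=2, seed=0)
        assert emb.vectors.shape == (5, 256)
        assert emb.training_meta["wl_iterations"] == 5
        with pytest.raises(ValueError):
            embed_sequences([], k=1)

    def test_embed_sequences_deterministic(self):
        a = embed_sequences(["GG", "AC"], k=2, dimensions=8, epochs=2, seed=3)
        b = embed_sequences(["GG", "AC"], k=2, dimensions=8, epochs=2, seed=3)
        assert np.array_equal(a.vectors, b.vectors)

    def test_infer_embedding_frozen_tokens(self):
        docs = build_documents(["GGG", "ACA", "WYW", "PEP"], k=2)
        emb = train_embeddings(docs, dimensions=8, epochs=3, seed=1)
        new_doc = build_documents(["GGA"], k=2)[0]
        v1 = infer_embedding(new_doc, emb, epochs=3, seed=2)
        v2 = infer_embedding(new_doc, emb, epochs=3, seed=2)
        assert v1.shape == (8,)
        assert np.array_equal(v1, v2)
        assert np.array_equal(emb.vectors,
                              train_embeddings(docs, dimensions=8, epochs=3,
                                               seed=1).vectors)
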