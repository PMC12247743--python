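"""Weisfeiler-Lehman rooted-subgraph documents and Graph2Vec embeddings.

Each molecular graph is treated as a document whose words are WL subtree
tokens: iteration 0 serializes the enabled node attributes, and iteration
t+1 hashes a node's current label together with the sorted multiset of its
neighbors' labels (optionally prefixed by the serialized bond attributes).
The document of a graph with |V| nodes at subtree height k therefore holds
|V|·(k+1) tokens, and BoW(G) = Σ_{u∈V} φ(h(u)) over iterations 0..k.

Embeddings are learned with the doc2vec distributed-bag-of-words scheme:
each graph's vector is trained to predict its subgraph tokens, the softmax
over the token vocabulary approximated by negative sampling.  Training is
single-threaded and fully deterministic given (corpus order, seed).

Token hashes are keyless BLAKE2b-128 digests of the canonical label
serialization, so documents and TF-IDF vocabularies are stable across
processes and platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .peptide_graph import (FeatureConfig, MolecularGraph, PeptideSequence,
                            seq_to_graph)

_NODE_FEATURE_ORDER = ("atomic_number", "aromaticity", "formal_charge",
                       "hybridization", "degree", "total_hydrogens")
_EDGE_FEATURE_ORDER = ("bond_type", "aromaticity", "conjugation",
                       "stereochemistry", "ring_membership")

_CONSTANT_TOKEN = "*"


def _digest(text: str) -> str:
    return hashlib.blake2b(text.encode(), digest_size=16).hexdigest()


@dataclass
class WLLabeling:
    """Node labels per WL iteration; ``labels[t][u]`` is node u's label."""

    labels: list[list[str]]

    @property
    def k(self) -> int:
        return len(self.labels) - 1

    def distinct(self, t: int) -> int:
        return len(set(self.labels[t]))


@dataclass
class TokenOccurrence:
    """Provenance of one token: its root node and the residues it spans."""

    root: int
    root_residue: int
    residues: frozenset[int]
    iteration: int


@dataclass
class GraphDocument:
    graph_id: str
    tokens: list[str]
    provenance: list[TokenOccurrence]
    n_nodes: int
    sequence: str = ""


def _node_label(node, features: frozenset[str]) -> str:
    values = {
        "atomic_number": node.element,
        "aromaticity": int(node.aromatic),
        "formal_charge": node.formal_charge,
        "hybridization": node.hybridization,
        "degree": node.degree,
        "total_hydrogens": node.total_hydrogens,
    }
    parts = [f"{f}={values[f]}" for f in _NODE_FEATURE_ORDER if f in features]
    return "|".join(parts) if parts else _CONSTANT_TOKEN


def _edge_label(edge, features: frozenset[str]) -> str:
    values = {
        "bond_type": edge.bond_type,
        "aromaticity": int(edge.bond_type == "aromatic"),
        "conjugation": int(edge.conjugated),
        "stereochemistry": edge.stereo,
        "ring_membership": int(edge.in_ring),
    }
    parts = [f"{f}={values[f]}" for f in _EDGE_FEATURE_ORDER if f in features]
    return "|".join(parts)


def initial_labels(g: MolecularGraph, config: FeatureConfig) -> WLLabeling:
    """Iteration-0 labels: canonical serialization of enabled node features."""
    if config.non_attributed:
        return WLLabeling(labels=[[_CONSTANT_TOKEN] * len(g.nodes)])
    return WLLabeling(labels=[[_node_label(n, config.node_features)
                               for n in g.nodes]])


def wl_iterate(g: MolecularGraph, labeling: WLLabeling,
               use_edge_labels: bool = True,
               edge_config: FeatureConfig | None = None) -> WLLabeling:
    """Append one WL refinement round to ``labeling``."""
    if not labeling.labels:
        raise ValueError("labeling must hold at least the initial iteration")
    config = edge_config or FeatureConfig()
    edge_features = (frozenset() if config.non_attributed
                     else config.edge_features)
    current = labeling.labels[-1]
    adj = g.adjacency()
    nxt = []
    for u in range(len(g.nodes)):
        descriptors = []
        for v, ei in adj[u]:
            d = current[v]
            if use_edge_labels and edge_features:
                d = _edge_label(g.edges[ei], edge_features) + "~" + d
            descriptors.append(d)
        nxt.append(_digest(current[u] + "(" + ",".join(sorted(descriptors)) + ")"))
    return WLLabeling(labels=labeling.labels + [nxt])


def graph_document(g: MolecularGraph, k: int,
                   config: FeatureConfig | None = None,
                   use_edge_labels: bool = True,
                   graph_id: str = "") -> GraphDocument:
    """Collect all node labels from iterations 0..k as one token document."""
    if k < 0:
        raise ValueError("k must be >= 0")
    config = config or FeatureConfig()
    labeling = initial_labels(g, config)
    for _ in range(k):
        labeling = wl_iterate(g, labeling, use_edge_labels, config)
    n = len(g.nodes)
    residue_of = [node.residue_index for node in g.nodes]
    adj = g.adjacency()
    # residue span of the t-hop ball around each root, grown incrementally
    reach: list[frozenset[int]] = [frozenset((residue_of[u],)) for u in range(n)]
    tokens: list[str] = []
    prov: list[TokenOccurrence] = []
    for t, labels in enumerate(labeling.labels):
        if t > 0:
            reach = [frozenset().union(reach[u], *(reach[v] for v, _ in adj[u]))
                     for u in range(n)]
        for u in range(n):
            tokens.append(labels[u])
            prov.append(TokenOccurrence(root=u, root_residue=residue_of[u],
                                        residues=reach[u], iteration=t))
    return GraphDocument(graph_id=graph_id or g.source_sequence.id,
                         tokens=tokens, provenance=prov, n_nodes=n,
                         sequence=g.source_sequence.residues)


@dataclass
class EmbeddingMatrix:
    graph_ids: list[str]
    vectors: np.ndarray
    dimensions: int
    training_meta: dict = field(default_factory=dict)
    # retained for infer-only embedding of unseen graphs
    token_vectors: np.ndarray | None = None
    vocab: dict[str, int] | None = None

    def row(self, graph_id: str) -> np.ndarray:
        return self.vectors[self.graph_ids.index(graph_id)]


def train_embeddings(corpus: list[GraphDocument], dimensions: int = 256,
                     epochs: int = 10, seed: int = 0,
                     negative_samples: int = 5,
                     alpha: float = 0.025, min_alpha: float = 1e-4,
                     batch_size: int = 4096, min_count: int = 5,
                     down_sampling: float = 0.0) -> EmbeddingMatrix:
    """Learn one vector per document by PV-DBOW with negative sampling.

    Tokens with corpus count below ``min_count`` are pruned from the
    vocabulary (graphs at high WL height produce many one-off subgraph
    hashes that carry no shared signal).  Setting ``down_sampling`` > 0
    additionally discounts very frequent tokens with the word2vec keep
    probability min(1, (sqrt(f/t) + 1) · t/f) at threshold t; it is off by
    default because molecular-graph corpora are orders of magnitude
    smaller than the text corpora that heuristic assumes, and at text-scale
    thresholds it deletes the shared signal.  Gradient steps are applied
    in shuffled mini-batches with accumulated (`np.add.at`) updates; the
    noise distribution is the unigram token frequency raised to 3/4, the
    standard word2vec choice.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if dimensions < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)

    raw_counts: dict[str, int] = {}
    for doc in corpus:
        for t in doc.tokens:
            raw_counts[t] = raw_counts.get(t, 0) + 1
    vocab: dict[str, int] = {}
    doc_idx: list[int] = []
    tok_idx: list[int] = []
    for di, doc in enumerate(corpus):
        for t in doc.tokens:
            if raw_counts[t] < min_count:
                continue
            j = vocab.setdefault(t, len(vocab))
            doc_idx.append(di)
            tok_idx.append(j)
    if not vocab:
        # tiny corpora: fall back to the unpruned vocabulary
        for di, doc in enumerate(corpus):
            for t in doc.tokens:
                j = vocab.setdefault(t, len(vocab))
                doc_idx.append(di)
                tok_idx.append(j)
    docs = np.asarray(doc_idx, dtype=np.int64)
    toks = np.asarray(tok_idx, dtype=np.int64)
    n_docs, n_vocab = len(corpus), len(vocab)

    counts = np.bincount(toks, minlength=n_vocab).astype(np.float64)
    noise = counts ** 0.75
    noise /= noise.sum()
    if down_sampling > 0:
        freq = counts / counts.sum()
        keep_p = np.minimum(
            1.0, (np.sqrt(freq / down_sampling) + 1) * down_sampling / freq)
    else:
        keep_p = np.ones(n_vocab)

    D = ((rng.random((n_docs, dimensions), dtype=np.float32) - 0.5)
         / dimensions)
    W = np.zeros((n_vocab, dimensions), dtype=np.float32)

    n_pairs = len(docs)
    # keep >= ~16 accumulated-update batches per epoch so small corpora do
    # not degenerate into full-batch steps at the per-occurrence rate
    batch_size = max(16, min(batch_size, n_pairs // 16 + 1))
    total_batches = max(1, epochs * int(np.ceil(n_pairs / batch_size)))
    batch_no = 0
    for _ in range(epochs):
        if down_sampling > 0:
            kept = np.flatnonzero(rng.random(n_pairs) < keep_p[toks])
            order = kept[rng.permutation(len(kept))]
        else:
            order = rng.permutation(n_pairs)
        for start in range(0, len(order), batch_size):
            sel = order[start:start + batch_size]
            b = len(sel)
            d_ids = docs[sel]
            negs = rng.choice(n_vocab, size=(b, negative_samples), p=noise)
            t_ids = np.concatenate([toks[sel][:, None], negs], axis=1)
            labels = np.zeros((b, 1 + negative_samples), dtype=np.float32)
            labels[:, 0] = 1.0

            lr = alpha - (alpha - min_alpha) * batch_no / total_batches
            batch_no += 1

            dvec = D[d_ids]                      # (b, d)
            wvec = W[t_ids]                      # (b, K, d)
            scores = np.einsum("bd,bkd->bk", dvec, wvec)
            sig = expit(scores)
            g = (labels - sig) * lr              # (b, K)
            grad_d = np.einsum("bk,bkd->bd", g, wvec)
            grad_w = g[:, :, None] * dvec[:, None, :]
            np.add.at(D, d_ids, grad_d)
            np.add.at(W, t_ids.ravel(),
                      grad_w.reshape(-1, dimensions))

    meta = {"dimensions": dimensions, "epochs": epochs, "seed": seed,
            "negative_samples": negative_samples, "n_vocab": n_vocab,
            "alpha": alpha, "min_alpha": min_alpha,
            "min_count": min_count, "down_sampling": down_sampling}
    return EmbeddingMatrix(graph_ids=[d.graph_id for d in corpus],
                           vectors=D.astype(np.float64),
                           dimensions=dimensions, training_meta=meta,
                           token_vectors=W, vocab=vocab)


def build_documents(sequences: list[PeptideSequence | str], k: int = 5,
                    config: FeatureConfig | None = None,
                    use_edge_labels: bool = True) -> list[GraphDocument]:
    """Graphs + WL documents for a sequence list; duplicates share one graph."""
    config = config or FeatureConfig()
    cache: dict[str, GraphDocument] = {}
    out: list[GraphDocument] = []
    for i, s in enumerate(sequences):
        seq = PeptideSequence(s, id=f"seq{i}") if isinstance(s, str) else s
        base = cache.get(seq.residues)
        if base is None:
            g = seq_to_graph(seq)
            base = graph_document(g, k, config, use_edge_labels,
                                  graph_id=seq.id or f"seq{i}")
            cache[seq.residues] = base
        out.append(GraphDocument(graph_id=seq.id or f"seq{i}",
                                 tokens=base.tokens, provenance=base.provenance,
                                 n_nodes=base.n_nodes, sequence=seq.residues))
    return out


def embed_sequences(sequences: list[PeptideSequence | str], k: int = 5,
                    dimensions: int = 256, epochs: int = 10, seed: int = 0,
                    config: FeatureConfig | None = None,
                    use_edge_labels: bool = True,
                    negative_samples: int = 5) -> EmbeddingMatrix:
    """Pooled-corpus embedding of a sequence list (TCRs + epitopes together)."""
    if not sequences:
        raise ValueError("no sequences to embed")
    corpus = build_documents(sequences, k=k, config=config,
                             use_edge_labels=use_edge_labels)
    emb = train_embeddings(corpus, dimensions=dimensions, epochs=epochs,
                           seed=seed, negative_samples=negative_samples)
    emb.training_meta["wl_iterations"] = k
    return emb


def infer_embedding(doc: GraphDocument, trained: EmbeddingMatrix,
                    epochs: int = 10, seed: int = 0,
                    negative_samples: int = 5, alpha: float = 0.025,
                    min_alpha: float = 1e-4) -> np.ndarray:
    """Infer-only embedding of an unseen graph (leakage-free alternative).

    Token output vectors from a trained model stay frozen; gradient steps
    are taken on the new document's vector only.  Tokens outside the
    training vocabulary are dropped, mirroring doc2vec inference.  Unlike
    the default pooled training, test-set structure cannot influence the
    embedding space in this mode.
    """
    if trained.token_vectors is None or trained.vocab is None:
        raise ValueError("trained model does not retain token vectors")
    rng = np.random.default_rng(seed)
    W = trained.token_vectors
    d = trained.dimensions
    toks = np.asarray([trained.vocab[t] for t in doc.tokens
                       if t in trained.vocab], dtype=np.int64)
    vec = (rng.random(d, dtype=np.float32) - 0.5) / d
    if len(toks) == 0:
        return vec.astype(np.float64)
    n_vocab = W.shape[0]
    total = max(1, epochs * len(toks))
    step = 0
    for _ in range(epochs):
        for j in rng.permutation(len(toks)):
            lr = alpha - (alpha - min_alpha) * step / total
            step += 1
            t_ids = np.concatenate(([toks[j]],
                                    rng.integers(0, n_vocab,
                                                 size=negative_samples)))
            labels = np.zeros(1 + negative_samples, dtype=np.float32)
            labels[0] = 1.0
            wvec = W[t_ids]
            sig = expit(wvec @ vec)
            vec = vec + lr * ((labels - sig) @ wvec)
    return vec.astype(np.float64)
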