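"""TF-IDF mining of cluster-discriminative WL subgraph tokens and their
back-mapping to 5-residue sequence motifs.

Documents are, by default, cluster-level: all member graphs' WL tokens are
pooled per cluster, so TF-IDF highlights subgraph features frequent inside
one cluster but rare across clusters.  High-scoring tokens are traced back
through their provenance (the WL root atom's residue) to 5-residue windows
centered on the root residue; windows are then filtered by support counts
and cross-cluster exclusivity and summarized as position-probability
matrices for logo rendering.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import NOISE, ClusterResult
from .peptide_graph import AMINO_ACIDS
from .wl import GraphDocument

PAD = "-"
WINDOW = 5


@dataclass
class TFIDFTable:
    entries: dict[tuple[str, str], tuple[float, float, float]]  # (t, g) -> tf, idf, tfidf
    corpus_size: int
    min_df: int

    def tfidf(self, token: str, doc: str) -> float:
        return self.entries.get((token, doc), (0.0, 0.0, 0.0))[2]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"token": t, "doc": g, "tf": v[0], "idf": v[1], "tfidf": v[2]}
                for (t, g), v in self.entries.items()]
        return pd.DataFrame(rows)


@dataclass
class Motif:
    window: str
    cluster_id: int
    support_tcrs: int          # distinct member TCRs containing the window
    total_occurrences: int     # distinct TCRs corpus-wide containing it
    tfidf_score: float
    exclusive: bool = True


@dataclass
class PositionProbabilityMatrix:
    matrix: np.ndarray  # WINDOW x 20
    alphabet: str = AMINO_ACIDS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.alphabet),
                            index=[f"pos_{i - WINDOW // 2}" for i in range(WINDOW)])


def tfidf(corpus: dict[str, Counter | list], min_df: int = 1,
          log_base: float = math.e) -> TFIDFTable:
    """TF-IDF over a token corpus.

    TF(t, g) = count(t in g) / |g|;  IDF(t, C) = log(|C| / df(t)).
    Tokens appearing in fewer than ``min_df`` documents are dropped.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if min_df > len(corpus):
        raise ValueError("min_df exceeds the corpus size")
    counts = {g: (toks if isinstance(toks, Counter) else Counter(toks))
              for g, toks in corpus.items()}
    df: Counter = Counter()
    for c in counts.values():
        df.update(c.keys())
    n = len(counts)
    entries = {}
    for g, c in counts.items():
        total = sum(c.values())
        for t, k in c.items():
            if df[t] < min_df:
                continue
            tf = k / total
            idf = math.log(n / df[t], log_base)
            entries[(t, g)] = (tf, idf, tf * idf)
    return TFIDFTable(entries=entries, corpus_size=n, min_df=min_df)


def cluster_documents(documents: list[GraphDocument],
                      assignments: ClusterResult | np.ndarray
                      ) -> dict[int, Counter]:
    """Pool member documents' tokens per cluster; noise contributes nothing."""
    labels = (assignments.assignments
              if isinstance(assignments, ClusterResult) else
              np.asarray(assignments))
    if len(labels) != len(documents):
        raise ValueError("one assignment per document required")
    pooled: dict[int, Counter] = {}
    for doc, c in zip(documents, labels):
        if c == NOISE:
            continue
        pooled.setdefault(int(c), Counter()).update(doc.tokens)
    if not pooled:
        raise ValueError("no non-noise clusters")
    return pooled


def token_windows(token: str, documents: list[GraphDocument]
                  ) -> list[tuple[str, str]]:
    """(document id, 5-residue window) for every occurrence of ``token``.

    The window is centered on the occurrence's WL root residue — the most
    informative position, position 0 — and padded with '-' at sequence
    ends."""
    out = []
    for doc in documents:
        if not doc.provenance:
            raise ValueError(f"document {doc.graph_id} lacks provenance")
        seq = doc.sequence
        for tok, occ in zip(doc.tokens, doc.provenance):
            if tok != token:
                continue
            c = occ.root_residue
            chars = [seq[i] if 0 <= i < len(seq) else PAD
                     for i in range(c - WINDOW // 2, c + WINDOW // 2 + 1)]
            out.append((doc.graph_id, "".join(chars)))
    return out


AMBIGUOUS = "%"


def consensus_window(windows: list[str], threshold: float = 0.5) -> str:
    """Majority consensus of aligned 5-residue windows.

    A position shows its modal residue when that residue covers at least
    ``threshold`` of the non-padded occurrences, and '%' (an ambiguous,
    unconserved position) otherwise; positions that are padding in most
    occurrences stay '-'.
    """
    out = []
    for i in range(WINDOW):
        col = Counter(w[i] for w in windows)
        pad = col.pop(PAD, 0)
        if pad > sum(col.values()):
            out.append(PAD)
            continue
        if not col:
            out.append(AMBIGUOUS)
            continue
        res, cnt = col.most_common(1)[0]
        out.append(res if cnt >= threshold * sum(col.values()) else AMBIGUOUS)
    return "".join(out)


def select_motifs(documents: list[GraphDocument],
                  assignments: ClusterResult | np.ndarray,
                  min_tcrs_within: int = 5, min_total_occurrences: int = 20,
                  exclusive: bool = True, min_df: int = 1,
                  top_tokens: int = 50, max_motifs_per_cluster: int = 10,
                  consensus_threshold: float = 0.5) -> list[Motif]:
    """Cluster-discriminative 5-residue motifs.

    Per cluster, subgraph tokens are ranked by TF-IDF over the pooled
    cluster documents.  A token survives if it occurs in at least
    ``min_tcrs_within`` distinct TCRs of its cluster and at least
    ``min_total_occurrences`` distinct TCRs overall; its motif is the
    consensus of the 5-residue windows centered on its occurrence roots
    (unconserved positions shown as '%', the logo-plot ambiguity mark).
    Motifs whose consensus window is selected by more than one cluster
    are removed from all of them when ``exclusive``.
    """
    labels = (assignments.assignments
              if isinstance(assignments, ClusterResult) else
              np.asarray(assignments))
    pooled = cluster_documents(documents, labels)
    table = tfidf({str(c): toks for c, toks in pooled.items()}, min_df=min_df)
    token_sets = [set(d.tokens) for d in documents]
    members: dict[int, list[GraphDocument]] = {}
    for doc, c in zip(documents, labels):
        if c != NOISE:
            members.setdefault(int(c), []).append(doc)

    # distinct sequences containing each token, corpus-wide (computed lazily)
    total_cache: dict[str, int] = {}
    seq_of = [d.sequence for d in documents]

    def total_support(tok: str) -> int:
        if tok not in total_cache:
            total_cache[tok] = len({s for s, ts in zip(seq_of, token_sets)
                                    if tok in ts})
        return total_cache[tok]

    candidates: dict[int, list[Motif]] = {}
    for c in sorted(pooled):
        ranked = sorted(
            ((tok, v[2]) for (tok, g), v in table.entries.items()
             if g == str(c)), key=lambda kv: (-kv[1], kv[0]))[:top_tokens]
        member_docs = members[c]
        motifs: list[Motif] = []
        seen_windows: set[str] = set()
        for tok, score in ranked:
            if score <= 0 or len(motifs) >= max_motifs_per_cluster:
                break
            within = len({d.sequence for d in member_docs
                          if tok in set(d.tokens)})
            if within < min_tcrs_within:
                continue
            total = total_support(tok)
            if total < min_total_occurrences:
                continue
            windows = [w for _, w in token_windows(tok, member_docs)]
            window = consensus_window(windows, threshold=consensus_threshold)
            if window in seen_windows or window.strip(PAD + AMBIGUOUS) == "":
                continue
            seen_windows.add(window)
            motifs.append(Motif(window=window, cluster_id=c,
                                support_tcrs=within,
                                total_occurrences=total,
                                tfidf_score=score))
        candidates[c] = motifs

    if exclusive:
        owner: Counter = Counter()
        for motifs in candidates.values():
            owner.update({m.window for m in motifs})
        for c in candidates:
            for m in candidates[c]:
                m.exclusive = owner[m.window] == 1
            candidates[c] = [m for m in candidates[c] if m.exclusive]
    return [m for c in sorted(candidates) for m in candidates[c]]


def ppm(windows: list[str]) -> PositionProbabilityMatrix:
    """Per-position residue probabilities; '-' padding is excluded from the
    denominator of its position."""
    if not windows:
        raise ValueError("no windows")
    rank = {a: i for i, a in enumerate(AMINO_ACIDS)}
    mat = np.zeros((WINDOW, 20))
    for w in windows:
        if len(w) != WINDOW:
            raise ValueError(f"window {w!r} is not length {WINDOW}")
        for i, ch in enumerate(w):
            if ch == PAD:
                continue
            mat[i, rank[ch]] += 1
    sums = mat.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return PositionProbabilityMatrix(matrix=mat / sums)


def motifs_to_frame(motifs: list[Motif]) -> pd.DataFrame:
    return pd.DataFrame([{"cluster": m.cluster_id, "window": m.window,
                          "support_tcrs": m.support_tcrs,
                          "total_occurrences": m.total_occurrences,
                          "tfidf": m.tfidf_score, "exclusive": m.exclusive}
                         for m in motifs])
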