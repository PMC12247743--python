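"""Binding-pair construction, leakage-controlled splitting and RF classification.

Positive TCR–epitope pairs come from observation (or simulation); negatives
are generated by shuffling TCRs across non-cognate epitopes or by swapping
TCRs between antigen groups.  The 80/20 train/test split is similarity
guided: within each epitope group, random seed CDR3s and their exact
nearest neighbors (L2 on one-hot encodings) are assigned to the test side
together, so that near-duplicate sequences never straddle the split.
A random forest on concatenated TCR+epitope graph embeddings scores
binding, evaluated by the rank-statistic auROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .peptide_graph import AMINO_ACIDS, FeatureConfig
from .wl import EmbeddingMatrix, build_documents, train_embeddings

_AA_RANK = {a: i for i, a in enumerate(AMINO_ACIDS)}  # alphabetical already


@dataclass(frozen=True)
class BindingPair:
    tcr: str
    epitope: str
    label: int  # 1 positive, 0 negative
    origin: str = "observed"  # observed | shuffled | swapped
    pair_id: int = -1


@dataclass
class SplitAssignment:
    train_ids: set[int]
    test_ids: set[int]
    test_fraction: float
    seed: int
    unsplittable_epitopes: list[str] = field(default_factory=list)


@dataclass
class ClassifierConfig:
    n_trees: int = 500
    max_depth: int | None = None  # None = unlimited
    seed: int = 0


@dataclass
class RocResult:
    auroc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


def pairs_from_dataframe(df: pd.DataFrame) -> list[BindingPair]:
    """Rows with cdr3/epitope columns (optional label, default positive)."""
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        label = int(getattr(row, "label", 1))
        out.append(BindingPair(tcr=row.cdr3, epitope=row.epitope, label=label,
                               origin="observed" if label else "shuffled",
                               pair_id=i))
    return out


def filter_epitopes(pairs: list[BindingPair], min_tcrs: int = 1000
                    ) -> list[BindingPair]:
    """Drop pairs whose epitope has fewer than ``min_tcrs`` distinct
    positively-associated TCRs."""
    if min_tcrs < 1:
        raise ValueError("min_tcrs must be >= 1")
    counts: dict[str, set[str]] = {}
    for p in pairs:
        if p.label == 1:
            counts.setdefault(p.epitope, set()).add(p.tcr)
    keep = {e for e, s in counts.items() if len(s) >= min_tcrs}
    return [p for p in pairs if p.epitope in keep]


def one_hot_encode(seq: str, max_len: int) -> np.ndarray:
    """Position-wise 20-letter one-hot, zero-padded to ``max_len``."""
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than max_len={max_len}: {seq!r}")
    v = np.zeros(20 * max_len)
    for p, a in enumerate(seq):
        v[20 * p + _AA_RANK[a]] = 1.0
    return v


def similarity_split(pairs: list[BindingPair], test_fraction: float = 0.2,
                     seed: int = 0, group_size: int = 10) -> SplitAssignment:
    """Nearest-neighbor-guided 80/20 split, independent per epitope group.

    Splitting operates on distinct CDR3 strings so that duplicated
    sequences always land on the same side.  Per epitope, random seed
    sequences pull their ``group_size - 1`` exact nearest neighbors (L2 on
    one-hot vectors) into the test set until the quota
    ``round(test_fraction * n_distinct)`` is reached.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_epitope: dict[str, list[BindingPair]] = {}
    for p in pairs:
        by_epitope.setdefault(p.epitope, []).append(p)

    train_ids: set[int] = set()
    test_ids: set[int] = set()
    unsplittable: list[str] = []
    for epitope in sorted(by_epitope):
        group = by_epitope[epitope]
        tcrs = sorted({p.tcr for p in group})
        if len(tcrs) < 2:
            unsplittable.append(epitope)
            train_ids.update(p.pair_id for p in group)
            continue
        max_len = max(len(t) for t in tcrs)
        X = np.stack([one_hot_encode(t, max_len) for t in tcrs])
        quota = int(round(test_fraction * len(tcrs)))
        remaining = list(range(len(tcrs)))
        test_idx: set[int] = set()
        while len(test_idx) < quota and remaining:
            seed_pos = rng.integers(len(remaining))
            seed_i = remaining[seed_pos]
            rem = np.asarray(remaining)
            d2 = ((X[rem] - X[seed_i]) ** 2).sum(axis=1)
            take = min(group_size, quota - len(test_idx), len(remaining))
            order = np.lexsort((rem, d2))  # distance, then index, for determinism
            chosen = rem[order[:take]]
            test_idx.update(int(c) for c in chosen)
            chosen_set = set(int(c) for c in chosen)
            remaining = [r for r in remaining if r not in chosen_set]
        test_tcrs = {tcrs[i] for i in test_idx}
        for p in group:
            (test_ids if p.tcr in test_tcrs else train_ids).add(p.pair_id)
    return SplitAssignment(train_ids=train_ids, test_ids=test_ids,
                           test_fraction=test_fraction, seed=seed,
                           unsplittable_epitopes=unsplittable)


def generate_negatives(positives: list[BindingPair],
                       strategy: str = "shuffle", ratio: float = 1.0,
                       seed: int = 0,
                       groups: dict[str, str] | None = None,
                       start_id: int | None = None) -> list[BindingPair]:
    """Negative pairs by shuffling across non-cognate epitopes or swapping
    between antigen groups; never duplicates, never an observed positive."""
    if strategy not in ("shuffle", "swap_groups"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    positive_set = {(p.tcr, p.epitope) for p in positives}
    cognate: dict[str, set[str]] = {}
    for p in positives:
        cognate.setdefault(p.tcr, set()).add(p.epitope)
    epitopes = sorted({p.epitope for p in positives})
    if strategy == "shuffle" and len(epitopes) < 2:
        raise ValueError("shuffle strategy needs >= 2 distinct epitopes")
    if strategy == "swap_groups":
        if groups is None:
            raise ValueError("swap_groups strategy needs an epitope->group map")
        if len(set(groups.values())) < 2:
            raise ValueError("swap_groups strategy needs >= 2 antigen groups")
    tcrs = sorted(cognate)
    target = int(round(ratio * len(positives)))
    origin = "shuffled" if strategy == "shuffle" else "swapped"
    made: set[tuple[str, str]] = set()
    out: list[BindingPair] = []
    next_id = (max((p.pair_id for p in positives), default=-1) + 1
               if start_id is None else start_id)
    attempts = 0
    max_attempts = 50 * max(1, target)
    while len(out) < target and attempts < max_attempts:
        attempts += 1
        tcr = tcrs[rng.integers(len(tcrs))]
        if strategy == "shuffle":
            candidates = [e for e in epitopes if e not in cognate[tcr]]
        else:
            own_groups = {groups[e] for e in cognate[tcr] if e in groups}
            candidates = [e for e in epitopes
                          if groups.get(e) not in own_groups]
        if not candidates:
            continue  # TCR cognate to every candidate epitope: skip
        epi = candidates[rng.integers(len(candidates))]
        key = (tcr, epi)
        if key in made or key in positive_set:
            continue
        made.add(key)
        out.append(BindingPair(tcr=tcr, epitope=epi, label=0, origin=origin,
                               pair_id=next_id))
        next_id += 1
    return out


def pair_features(tcr_vec: np.ndarray, epi_vec: np.ndarray) -> np.ndarray:
    """Concatenated [TCR | epitope] embedding, TCR first."""
    if tcr_vec.shape != epi_vec.shape:
        raise ValueError("embedding dimensionality mismatch")
    return np.concatenate([tcr_vec, epi_vec])


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     config: ClassifierConfig | None = None
                     ) -> RandomForestClassifier:
    config = config or ClassifierConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(n_estimators=config.n_trees,
                                 max_depth=config.max_depth,
                                 random_state=config.seed, n_jobs=1)
    clf.fit(features, labels)
    return clf


def evaluate_auroc(scores, labels) -> RocResult:
    """Rank-statistic auROC (Mann-Whitney, ties counted 1/2) with curve."""
    from scipy.stats import rankdata
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(auroc=float(auroc), fpr=fpr, tpr=tpr,
                     n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Composed experiments
# ---------------------------------------------------------------------------

def _embed_pairs(pairs: list[BindingPair], k: int, dimensions: int,
                 epochs: int, seed: int,
                 config: FeatureConfig | None = None) -> EmbeddingMatrix:
    """Pooled embedding of every distinct sequence appearing in ``pairs``."""
    seqs = sorted({p.tcr for p in pairs} | {p.epitope for p in pairs})
    docs = build_documents(seqs, k=k, config=config)
    for d, s in zip(docs, seqs):
        d.graph_id = s
    emb = train_embeddings(docs, dimensions=dimensions, epochs=epochs,
                           seed=seed)
    emb.training_meta["wl_iterations"] = k
    return emb


def _feature_matrix(pairs: list[BindingPair], emb: EmbeddingMatrix):
    index = {g: i for i, g in enumerate(emb.graph_ids)}
    X = np.stack([pair_features(emb.vectors[index[p.tcr]],
                                emb.vectors[index[p.epitope]])
                  for p in pairs])
    y = np.asarray([p.label for p in pairs])
    return X, y


def run_classification(positives: list[BindingPair], *, wl_iterations: int = 5,
                       dimensions: int = 256, epochs: int = 10,
                       test_fraction: float = 0.2,
                       negative_strategy: str = "shuffle",
                       negative_ratio: float = 1.0, seed: int = 0,
                       groups: dict[str, str] | None = None,
                       min_tcrs: int = 1,
                       classifier: ClassifierConfig | None = None,
                       feature_config: FeatureConfig | None = None) -> dict:
    """Full supervised pipeline: filter, split, negatives, embed, RF, auROC.

    Negatives are generated after the split, independently on each side, so
    no negative pair can leak across it.
    """
    positives = filter_epitopes(positives, min_tcrs=min_tcrs)
    if not positives:
        raise ValueError("no epitopes pass filter")
    split = similarity_split(positives, test_fraction=test_fraction, seed=seed)
    train_pos = [p for p in positives if p.pair_id in split.train_ids]
    test_pos = [p for p in positives if p.pair_id in split.test_ids]
    if not train_pos or not test_pos:
        raise ValueError("split produced an empty side")
    train_neg = generate_negatives(train_pos, strategy=negative_strategy,
                                   ratio=negative_ratio, seed=seed + 1,
                                   groups=groups)
    test_neg = generate_negatives(test_pos, strategy=negative_strategy,
                                  ratio=negative_ratio, seed=seed + 2,
                                  groups=groups,
                                  start_id=max(p.pair_id for p in train_neg) + 1)
    all_pairs = positives + train_neg + test_neg
    emb = _embed_pairs(all_pairs, k=wl_iterations, dimensions=dimensions,
                       epochs=epochs, seed=seed, config=feature_config)
    train = train_pos + train_neg
    test = test_pos + test_neg
    X_train, y_train = _feature_matrix(train, emb)
    X_test, y_test = _feature_matrix(test, emb)
    cfg = classifier or ClassifierConfig(seed=seed)
    clf = train_classifier(X_train, y_train, cfg)
    scores = clf.predict_proba(X_test)[:, 1]
    roc = evaluate_auroc(scores, y_test)
    return {"auroc": roc.auroc, "roc": roc, "split": split,
            "embedding": emb, "classifier": clf,
            "train_pairs": train, "test_pairs": test,
            "test_scores": scores}


def cross_validate(positives: list[BindingPair], *, k_folds: int = 5,
                   grid: list[tuple[int, int]] | None = None,
                   epochs: int = 10, seed: int = 0,
                   negative_strategy: str = "shuffle",
                   negative_ratio: float = 1.0,
                   groups: dict[str, str] | None = None,
                   classifier: ClassifierConfig | None = None) -> pd.DataFrame:
    """Mean validation auROC per (wl_iterations, dimensions) grid cell.

    Folds are epitope-stratified over pairs; embeddings are trained once
    per grid cell on the pooled corpus (the pooled-training mode) and the
    classifier is refit per fold.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    grid = grid or [(5, 256)]
    rng = np.random.default_rng(seed)
    negatives = generate_negatives(positives, strategy=negative_strategy,
                                   ratio=negative_ratio, seed=seed + 1,
                                   groups=groups)
    pairs = positives + negatives
    if len(pairs) < k_folds:
        raise ValueError("too few pairs for the requested number of folds")
    # epitope-stratified fold assignment
    fold_of = np.empty(len(pairs), dtype=int)
    by_epitope: dict[str, list[int]] = {}
    for i, p in enumerate(pairs):
        by_epitope.setdefault(p.epitope, []).append(i)
    for epitope in sorted(by_epitope):
        idx = np.asarray(by_epitope[epitope])
        perm = rng.permutation(len(idx))
        fold_of[idx[perm]] = np.arange(len(idx)) % k_folds
    rows = []
    for k, d in grid:
        emb = _embed_pairs(pairs, k=k, dimensions=d, epochs=epochs, seed=seed)
        X, y = _feature_matrix(pairs, emb)
        aurocs = []
        for f in range(k_folds):
            val = fold_of == f
            if len(np.unique(y[~val])) < 2 or len(np.unique(y[val])) < 2:
                continue
            cfg = classifier or ClassifierConfig(seed=seed)
            clf = train_classifier(X[~val], y[~val], cfg)
            s = clf.predict_proba(X[val])[:, 1]
            aurocs.append(evaluate_auroc(s, y[val]).auroc)
        rows.append({"wl_iterations": k, "dimensions": d,
                     "mean_auroc": float(np.mean(aurocs)),
                     "n_folds": len(aurocs)})
    return pd.DataFrame(rows)


def downsample_experiment(positives: list[BindingPair], ratios: list[float],
                          seed: int = 0, **pipeline_kwargs) -> pd.DataFrame:
    """auROC as a function of data depth.

    Train and test sides are down-sampled at the same ratio after the
    split, then embedding and classification are re-run from scratch on
    the reduced data.
    """
    wl_iterations = pipeline_kwargs.get("wl_iterations", 5)
    dimensions = pipeline_kwargs.get("dimensions", 256)
    epochs = pipeline_kwargs.get("epochs", 10)
    strategy = pipeline_kwargs.get("negative_strategy", "shuffle")
    ratio_neg = pipeline_kwargs.get("negative_ratio", 1.0)
    groups = pipeline_kwargs.get("groups")
    classifier = pipeline_kwargs.get("classifier")
    feature_config = pipeline_kwargs.get("feature_config")

    rng = np.random.default_rng(seed)
    split = similarity_split(
        positives, test_fraction=pipeline_kwargs.get("test_fraction", 0.2),
        seed=seed)
    train_all = [p for p in positives if p.pair_id in split.train_ids]
    test_all = [p for p in positives if p.pair_id in split.test_ids]
    rows = []
    for ratio in ratios:
        if not 0 < ratio <= 1:
            raise ValueError("ratios must lie in (0, 1]")
        sub_seed = int(rng.integers(2 ** 31))
        sub_rng = np.random.default_rng(sub_seed)

        def _sample(side):
            n = max(1, int(round(ratio * len(side))))
            idx = sub_rng.choice(len(side), size=n, replace=False)
            return [side[i] for i in sorted(idx)]

        train_pos, test_pos = _sample(train_all), _sample(test_all)
        train_neg = generate_negatives(train_pos, strategy=strategy,
                                       ratio=ratio_neg, seed=sub_seed + 1,
                                       groups=groups)
        test_neg = generate_negatives(
            test_pos, strategy=strategy, ratio=ratio_neg, seed=sub_seed + 2,
            groups=groups,
            start_id=max((p.pair_id for p in train_neg), default=0) + 1)
        all_pairs = train_pos + test_pos + train_neg + test_neg
        emb = _embed_pairs(all_pairs, k=wl_iterations, dimensions=dimensions,
                           epochs=epochs, seed=sub_seed, config=feature_config)
        X_train, y_train = _feature_matrix(train_pos + train_neg, emb)
        X_test, y_test = _feature_matrix(test_pos + test_neg, emb)
        cfg = classifier or ClassifierConfig(seed=sub_seed)
        clf = train_classifier(X_train, y_train, cfg)
        scores = clf.predict_proba(X_test)[:, 1]
        rows.append({"ratio": ratio,
                     "auroc": evaluate_auroc(scores, y_test).auroc,
                     "n_train": len(train_pos), "n_test": len(test_pos)})
    return pd.DataFrame(rows)
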