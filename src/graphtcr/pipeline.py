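"""End-to-end pipeline: filter → split → negatives → embed → classify,
cluster and mine motifs, writing every artifact to a run directory."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import cluster as cc
from . import motifs as mm
from .io import PairsTable, RunConfig, write_embeddings, write_json, write_pairs
from .wl import build_documents

logger = logging.getLogger("graphtcr")


def _stage(name):
    logger.info("stage %s starting", name)
    return time.time()


def run_pipeline(config: RunConfig, pairs: PairsTable,
                 out_dir: str | Path) -> dict:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Returns the metrics dictionary that is also written to metrics.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())

    positives = [p for p in pairs.to_pairs() if p.label == 1]
    groups = pairs.groups()
    t0 = _stage("filter")
    positives = cl.filter_epitopes(positives, min_tcrs=config.min_tcrs)
    if not positives:
        raise ValueError("no epitopes pass filter")
    logger.info("filter kept %d pairs (%.1fs)", len(positives), time.time() - t0)

    feature_config = None
    if config.non_attributed:
        from .peptide_graph import FeatureConfig
        feature_config = FeatureConfig(node_features=frozenset(),
                                       edge_features=frozenset(),
                                       non_attributed=True)

    t0 = _stage("classification")
    res = cl.run_classification(
        positives, wl_iterations=config.wl_iterations,
        dimensions=config.dimensions, epochs=config.epochs,
        test_fraction=config.test_fraction,
        negative_strategy=config.negative_strategy,
        negative_ratio=config.negative_ratio, seed=config.seed,
        groups=groups, min_tcrs=1,
        classifier=cl.ClassifierConfig(n_trees=config.n_trees,
                                       max_depth=config.max_depth,
                                       seed=config.seed),
        feature_config=feature_config)
    logger.info("classification auROC %.4f (%.1fs)", res["auroc"], time.time() - t0)

    emb = res["embedding"]
    write_embeddings(emb, out / "embeddings.tsv")
    split_rows = [{"id": p.pair_id, "cdr3": p.tcr, "epitope": p.epitope,
                   "label": p.label, "side": side}
                  for side, plist in (("train", res["train_pairs"]),
                                      ("test", res["test_pairs"]))
                  for p in plist]
    pd.DataFrame(split_rows).to_csv(out / "split.tsv", sep="\t", index=False)
    write_pairs(res["train_pairs"] + res["test_pairs"], out / "pairs_labeled.tsv")
    roc = res["roc"]
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
        out / "roc_curve.tsv", sep="\t", index=False)

    # clustering: TCR embeddings only, against their (first) cognate epitope
    t0 = _stage("clustering")
    tcr_epitope: dict[str, str] = {}
    for p in positives:
        tcr_epitope.setdefault(p.tcr, p.epitope)
    index = {g: i for i, g in enumerate(emb.graph_ids)}
    tcrs = sorted(tcr_epitope)
    X = emb.vectors[[index[t] for t in tcrs]]
    truth = np.asarray([tcr_epitope[t] for t in tcrs])
    sweep = cc.epsilon_sweep(
        X, truth,
        eps_values=np.geomspace(config.eps_min, config.eps_max,
                                config.eps_points),
        config=cc.ClusterConfig(min_points=config.min_points,
                                metric=config.cluster_metric,
                                reduction="pca",
                                reduced_dims=config.reduced_dims))
    sweep.to_csv(out / "epsilon_sweep.tsv", sep="\t", index=False)
    best = sweep.loc[sweep["c_csi"].idxmax()]
    logger.info("best c-CSI %.4f at eps %.3f (%.1fs)",
                best["c_csi"], best["epsilon"], time.time() - t0)

    # motif mining on epitope pools (the annotated TCR groups); the best-ε
    # DBSCAN assignment is written alongside for unsupervised re-analysis
    t0 = _stage("motifs")
    Xr = cc.reduce_pca(X, min(config.reduced_dims, min(X.shape)))
    assign = cc.dbscan(Xr, cc.ClusterConfig(
        epsilon=float(best["epsilon"]), min_points=config.min_points,
        metric=config.cluster_metric, reduction="none")).assignments
    pd.DataFrame({"cdr3": tcrs, "cluster": assign}).to_csv(
        out / "cluster_assignments.tsv", sep="\t", index=False)
    epitopes = sorted(set(truth))
    pool_of = {e: i for i, e in enumerate(epitopes)}
    pool_assign = np.asarray([pool_of[e] for e in truth])
    docs = build_documents(tcrs, k=config.wl_iterations,
                           config=feature_config)
    for d, t in zip(docs, tcrs):
        d.graph_id = t
    motif_list = mm.select_motifs(
        docs, pool_assign, min_tcrs_within=config.motif_min_tcrs,
        min_total_occurrences=config.motif_min_occurrences)
    frame = mm.motifs_to_frame(motif_list)
    if len(frame):
        frame["epitope"] = [epitopes[c] for c in frame["cluster"]]
    frame.to_csv(out / "motifs.tsv", sep="\t", index=False)
    logger.info("%d motifs selected (%.1fs)", len(motif_list), time.time() - t0)

    metrics = {
        "auroc": round(float(res["auroc"]), 10),
        "n_pos_test": roc.n_pos, "n_neg_test": roc.n_neg,
        "best_epsilon": round(float(best["epsilon"]), 10),
        "best_c_csi": round(float(best["c_csi"]), 10),
        "best_mean_precision": round(float(best["mean_precision"]), 10),
        "n_clusters_at_best": int(best["n_clusters"]),
        "n_motifs": len(motif_list),
        "seed": config.seed,
        "wl_iterations": config.wl_iterations,
        "dimensions": config.dimensions,
    }
    write_json(metrics, out / "metrics.json")
    return metrics
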