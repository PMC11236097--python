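"""Per-TF scoring, cross-validation orchestration, robustness and ablation
harnesses, and candidate ranking.

The primary unit of evaluation is the transcription factor: AUROC and AUPRC
are computed over the test pairs of each TF separately and summarised by
their median (and mean) across TFs; pooled scores over all test pairs are
also reported. TFs whose test pairs end up single-class are excluded from
the per-TF summary with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from ._random import derive_seed, rng_for
from .graph import CellGraph, SFNGraph, fuse_graphs, spatial_adjacency
from .io import EdgeList, ExpressionMatrix, SpatialCoordinates, normalize_expression
from .model import ModelParams, TrainConfig, predict, train
from .pairs import (
    PairDataset,
    build_causality_pairs,
    build_interaction_pairs,
    shuffle_labels_within_tf,
    split_by_tf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TFEvaluation",
    "roc_pr_scores",
    "evaluate_per_tf",
    "cross_validate",
    "downsample_run",
    "ablation_run",
    "rank_candidates",
    "per_tf_top",
]


@dataclass
class TFEvaluation:
    """Per-TF and pooled AUROC/AUPRC with median/mean summaries."""

    per_tf: dict[str, tuple[float, float, int]]
    pooled: tuple[float, float]
    n_excluded: int = 0
    detail: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def summary(self) -> dict[str, float]:
        aurocs = [v[0] for v in self.per_tf.values()]
        auprcs = [v[1] for v in self.per_tf.values()]
        return {
            "median_auroc": float(np.median(aurocs)) if aurocs else float("nan"),
            "median_auprc": float(np.median(auprcs)) if auprcs else float("nan"),
            "mean_auroc": float(np.mean(aurocs)) if aurocs else float("nan"),
            "mean_auprc": float(np.mean(auprcs)) if auprcs else float("nan"),
            "pooled_auroc": self.pooled[0],
            "pooled_auprc": self.pooled[1],
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tf": tf, "auroc": a, "auprc": p, "n_pairs": n}
            for tf, (a, p, n) in self.per_tf.items()
        ]
        return pd.DataFrame(rows, columns=["tf", "auroc", "auprc", "n_pairs"])


def roc_pr_scores(scores, labels) -> tuple[float, float]:
    """AUROC (tie-corrected Mann-Whitney) and AUPRC (step-wise PR integral).

    Requires both classes present; a single-class input is undefined and
    raises.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both labels must be present to compute AUROC/AUPRC")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def roc_pr_points(scores, labels) -> pd.DataFrame:
    """Threshold-sweep curve points (for plotting dumps)."""
    from sklearn.metrics import precision_recall_curve, roc_curve

    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    roc = pd.DataFrame({"curve": "roc", "x": fpr, "y": tpr})
    pr = pd.DataFrame({"curve": "pr", "x": rec, "y": prec})
    return pd.concat([roc, pr], ignore_index=True)


def evaluate_per_tf(scores, labels, tf_groups) -> TFEvaluation:
    """Split scores by anchor TF and compute per-TF + pooled metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    tf_groups = np.asarray(tf_groups, dtype=object)
    per_tf: dict[str, tuple[float, float, int]] = {}
    n_excluded = 0
    for tf in pd.unique(tf_groups):
        mask = tf_groups == tf
        if len(np.unique(labels[mask])) < 2:
            n_excluded += 1
            continue
        auroc, auprc = roc_pr_scores(scores[mask], labels[mask])
        per_tf[str(tf)] = (auroc, auprc, int(mask.sum()))
    if n_excluded:
        logger.warning("excluded %d single-class TF(s) from per-TF metrics", n_excluded)
    pooled = roc_pr_scores(scores, labels)
    detail = pd.DataFrame(
        {"tf": tf_groups, "label": labels, "score": scores}
    )
    return TFEvaluation(per_tf=per_tf, pooled=pooled, n_excluded=n_excluded, detail=detail)


def _build_graph(
    X: ExpressionMatrix,
    coords: SpatialCoordinates | None,
    graph_cfg: dict,
) -> CellGraph:
    builder = SFNGraph(
        strategy=graph_cfg.get("strategy", "sfn"),
        variance_target=graph_cfg.get("variance_target", 0.90),
        k=graph_cfg.get("k", 10),
        threshold=graph_cfg.get("threshold", 0.5),
        normalize_by_k=graph_cfg.get("normalize_by_k", True),
        dominant_on_abs=graph_cfg.get("dominant_on_abs", False),
    )
    graph = builder.fit(X).graph_
    if coords is not None and graph_cfg.get("use_spatial", True):
        spatial = spatial_adjacency(
            coords,
            threshold=graph_cfg.get("threshold", 0.5),
            scale=graph_cfg.get("spatial_scale", "median_knn"),
        )
        graph = fuse_graphs(graph, spatial)
    return graph


def _build_pairs(
    truth: EdgeList,
    task: str,
    gene_universe: list[str],
    tf_list: list[str] | None,
    seed: int,
) -> PairDataset:
    if task == "interaction":
        return build_interaction_pairs(
            truth, gene_universe, tf_list=tf_list, seed=derive_seed(seed, "negatives")
        )
    if task == "causality":
        return build_causality_pairs(truth.restrict_to(gene_universe), tf_list=tf_list)
    raise ValueError(f"unknown task {task!r}")


def cross_validate(
    X: ExpressionMatrix,
    truth: EdgeList,
    task: str = "interaction",
    coords: SpatialCoordinates | None = None,
    graph_cfg: dict | None = None,
    train_cfg: TrainConfig | None = None,
    n_folds: int = 3,
    seed: int = 0,
    tf_list: list[str] | None = None,
    normalize: str | None = None,
    shuffle_labels: bool = False,
) -> TFEvaluation:
    """TF-disjoint k-fold cross-validation of the full pipeline.

    Builds the cell graph once from the full expression matrix (the graph
    uses no pair labels, so it cannot leak), constructs the task's pair
    dataset, deals TFs into folds, trains one model per fold on the other
    folds' pairs and scores the held-out fold. A leakage assertion — empty
    intersection between train and test TF sets — runs on every fold.

    ``shuffle_labels`` trains on a within-TF label permutation, the null
    control whose median AUROC should sit near 0.5.
    """
    graph_cfg = dict(graph_cfg or {})
    train_cfg = train_cfg or TrainConfig()
    if normalize is not None and not X.normalized:
        X = normalize_expression(X, mode=normalize)
    graph = _build_graph(X, coords, graph_cfg)
    ds = _build_pairs(truth, task, list(X.gene_ids), tf_list, seed)
    ds.check_balance()
    ds = split_by_tf(ds, n_folds=n_folds, seed=derive_seed(seed, "folds"))
    if shuffle_labels:
        ds = shuffle_labels_within_tf(ds, seed=derive_seed(seed, "shuffle_labels"))
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    all_tfs: list[np.ndarray] = []
    fold_rows: list[dict] = []
    for fold in range(n_folds):
        test_ds = ds.subset_folds({fold})
        train_ds = ds.subset_folds(set(range(n_folds)) - {fold})
        train_tfs = set(train_ds.tf_groups)
        test_tfs = set(test_ds.tf_groups)
        assert not (train_tfs & test_tfs), "TF leakage between train and test folds"
        fold_cfg = replace(train_cfg, seed=derive_seed(seed, f"train_fold{fold}"))
        params = train(train_ds, X, graph, fold_cfg)
        scores = predict(params, test_ds, X, graph)
        all_scores.append(scores)
        all_labels.append(test_ds.labels())
        all_tfs.append(test_ds.groups())
        fold_rows.append(
            {"fold": fold, "n_train": len(train_ds), "n_test": len(test_ds)}
        )
    evaluation = evaluate_per_tf(
        np.concatenate(all_scores), np.concatenate(all_labels), np.concatenate(all_tfs)
    )
    evaluation.detail = evaluation.detail.assign(task=task)
    return evaluation


def downsample_run(
    X: ExpressionMatrix,
    truth: EdgeList,
    task: str = "interaction",
    coords: SpatialCoordinates | None = None,
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    seed: int = 0,
    graph_cfg: dict | None = None,
    train_cfg: TrainConfig | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Robustness to cell count: rerun the whole pipeline on random cell subsets.

    Cells are sampled uniformly without replacement per fraction and kept in
    their original order, so ``fraction=1.0`` reproduces the full-data run
    bit-exactly under the same seed. The graph is rebuilt for every subset.
    """
    graph_cfg = dict(graph_cfg or {})
    k = graph_cfg.get("k", 10)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fraction {frac} outside (0, 1]")
        n_sub = int(round(frac * X.n_cells))
        if n_sub < k + 1:
            raise ValueError(
                f"fraction {frac} leaves {n_sub} cells, fewer than K+1={k + 1}"
            )
        rng = rng_for(seed, f"downsample_{frac}")
        idx = np.sort(rng.choice(X.n_cells, size=n_sub, replace=False))
        X_sub = X.subset_cells(idx)
        coords_sub = coords.subset_cells(idx) if coords is not None else None
        ev = cross_validate(
            X_sub,
            truth,
            task=task,
            coords=coords_sub,
            graph_cfg=graph_cfg,
            train_cfg=train_cfg,
            seed=seed,
            **cv_kwargs,
        )
        rows.append({"fraction": frac, "n_cells": n_sub, **ev.summary})
    return pd.DataFrame(rows)


_VARIANTS = ("full", "gcn_only", "expression_graph_only", "spatial+expression")


def ablation_run(
    X: ExpressionMatrix,
    truth: EdgeList,
    task: str = "interaction",
    coords: SpatialCoordinates | None = None,
    variants: tuple[str, ...] = ("full", "gcn_only"),
    seed: int = 0,
    graph_cfg: dict | None = None,
    train_cfg: TrainConfig | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Component ablations, one cross-validation per variant.

    ``gcn_only`` disables the dense branch and nothing else;
    ``expression_graph_only`` skips spatial fusion; ``spatial+expression``
    (and ``full`` when coordinates are given) fuses both graphs.
    """
    graph_cfg = dict(graph_cfg or {})
    train_cfg = train_cfg or TrainConfig()
    normalize = cv_kwargs.pop("normalize", None)
    if normalize is not None and not X.normalized:
        X = normalize_expression(X, mode=normalize)
    rows = []
    for variant in variants:
        if variant not in _VARIANTS:
            raise ValueError(f"unknown ablation variant {variant!r}")
        v_train = replace(train_cfg)
        v_coords = coords
        if variant == "gcn_only":
            v_train = replace(train_cfg, use_nn_branch=False)
        elif variant == "expression_graph_only":
            v_coords = None
        elif variant == "spatial+expression":
            if coords is None:
                raise ValueError("spatial+expression variant requires coordinates")
        graph = _build_graph(X, v_coords, graph_cfg)
        ev = cross_validate(
            X,
            truth,
            task=task,
            coords=v_coords,
            graph_cfg=graph_cfg,
            train_cfg=v_train,
            seed=seed,
            **cv_kwargs,
        )
        rows.append(
            {
                "variant": variant,
                "graph_source": graph.source,
                "n_edges": graph.n_edges,
                **ev.summary,
            }
        )
    return pd.DataFrame(rows)


def rank_candidates(
    params: ModelParams,
    tf_list: list[str],
    gene_universe: list[str],
    X: ExpressionMatrix,
    G: CellGraph,
    top_n: int = 100,
) -> pd.DataFrame:
    """Score all TF x gene candidate pairs with a trained model.

    The candidate TFs must be disjoint from the model's training TFs
    (leakage guard, enforced). Self-pairs are excluded. Returns the top
    ``top_n`` pairs by probability, with a dense overall rank; per-TF
    sub-rankings come from :func:`per_tf_top`.
    """
    training = {t.casefold() for t in params.meta.get("training_tfs", [])}
    overlap = [t for t in tf_list if t.casefold() in training]
    if overlap:
        raise ValueError(
            f"candidate TFs overlap the training TFs: {', '.join(overlap)}"
        )
    pairs = [
        (tf, g)
        for tf in tf_list
        for g in gene_universe
        if tf.casefold() != g.casefold()
    ]
    arr = np.array(pairs, dtype=object)
    scores = predict(params, arr, X, G)
    frame = pd.DataFrame(
        {"regulator": arr[:, 0], "target": arr[:, 1], "score": scores}
    ).sort_values("score", ascending=False, kind="mergesort")
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.head(min(top_n, len(frame))).reset_index(drop=True)


def per_tf_top(ranked: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Top-``n`` candidate targets per TF from a ranked candidate table."""
    return (
        ranked.sort_values("score", ascending=False, kind="mergesort")
        .groupby("regulator", sort=False)
        .head(n)
        .reset_index(drop=True)
    )
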