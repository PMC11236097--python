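"""Integrated graph-convolutional + fully-connected gene-pair classifier.

The per-pair input is a (n_cells x 2) block holding the regulator's and the
target's expression across all cells, in the cell graph's order. Two parallel
branches embed it:

* an NN branch — two dense ReLU layers of 32 units applied per cell row;
* a GCN branch — two graph-convolution layers
  ``X^(l+1) = ELU(N X^(l) W^(l) + b^(l))`` with N the symmetric degree-
  normalised adjacency ``D̂^{-1/2}(A + I)D̂^{-1/2}`` (self-loops added so
  isolated cells keep a well-defined degree).

The branch outputs are concatenated along the feature axis, flattened into a
single vector, and mapped through one dense unit with a sigmoid to the
probability that the pair is a true (or correctly-directed) regulation.
Training minimises binary cross-entropy with Adam.

All forward and backward passes are explicit NumPy in float64, which keeps
the model light, exactly reproducible on CPU, and directly verifiable by
finite-difference gradient checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._random import rng_for
from .graph import CellGraph
from .io import ExpressionMatrix
from .pairs import PairDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ModelParams",
    "normalize_adjacency",
    "build_pair_tensors",
    "nn_branch",
    "gcn_branch",
    "classify",
    "bce_loss",
    "train",
    "predict",
    "save_model",
    "load_model",
    "SFINNClassifier",
]

_EPS = 1e-7


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the shallow-network design."""

    gcn_units: int = 32
    nn_units: int = 32
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    use_nn_branch: bool = True
    patience: int = 10
    val_fraction: float = 0.1
    compat_literal_normalizer: bool = False


@dataclass
class ModelParams:
    """All trainable weights plus the architecture they assume."""

    weights: dict[str, np.ndarray]
    n_cells: int
    gcn_units: int
    nn_units: int
    use_nn_branch: bool
    compat_literal_normalizer: bool = False
    meta: dict = field(default_factory=dict)

    def copy(self) -> "ModelParams":
        return ModelParams(
            weights={k: v.copy() for k, v in self.weights.items()},
            n_cells=self.n_cells,
            gcn_units=self.gcn_units,
            nn_units=self.nn_units,
            use_nn_branch=self.use_nn_branch,
            compat_literal_normalizer=self.compat_literal_normalizer,
            meta=dict(self.meta),
        )

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights.values()))


# ---------------------------------------------------------------------------
# adjacency normalisation


def normalize_adjacency(G: CellGraph, compat_literal: bool = False) -> np.ndarray:
    """Degree-normalised propagation matrix for the graph convolution.

    Default: the symmetric ``D̂^{-1/2} (A + I) D̂^{-1/2}`` with ``D̂`` the
    degree matrix of the self-loop-augmented adjacency. An edgeless graph
    therefore normalises to the identity and every row/column of an isolated
    cell reduces to its self-loop value 1.

    ``compat_literal`` switches to the one-sided form ``D^{-1/2} A D^{1/2}``
    on the raw adjacency (degree-0 rows mapped to zero), retained only for
    fidelity experiments.
    """
    a = G.a.astype(float)
    if compat_literal:
        d = a.sum(axis=1)
        with np.errstate(divide="ignore"):
            d_m = np.where(d > 0, d**-0.5, 0.0)
            d_p = np.where(d > 0, d**0.5, 0.0)
        return (d_m[:, None] * a) * d_p[None, :]
    a_hat = a + np.eye(G.n_cells)
    d_inv_sqrt = a_hat.sum(axis=1) ** -0.5
    return (d_inv_sqrt[:, None] * a_hat) * d_inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# activations


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# parameter initialisation


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    n_cells: int,
    rng: np.random.Generator,
    gcn_units: int = 32,
    nn_units: int = 32,
    use_nn_branch: bool = True,
    compat_literal_normalizer: bool = False,
) -> ModelParams:
    """Glorot-uniform initialisation of all layers under ``rng``."""
    w: dict[str, np.ndarray] = {}
    w["gcn_w0"] = _glorot(rng, 2, gcn_units, (2, gcn_units))
    w["gcn_b0"] = np.zeros(gcn_units)
    w["gcn_w1"] = _glorot(rng, gcn_units, gcn_units, (gcn_units, gcn_units))
    w["gcn_b1"] = np.zeros(gcn_units)
    feat = gcn_units
    if use_nn_branch:
        w["nn_w0"] = _glorot(rng, 2, nn_units, (2, nn_units))
        w["nn_b0"] = np.zeros(nn_units)
        w["nn_w1"] = _glorot(rng, nn_units, nn_units, (nn_units, nn_units))
        w["nn_b1"] = np.zeros(nn_units)
        feat += nn_units
    flat = n_cells * feat
    w["head_w"] = _glorot(rng, flat, 1, (flat,))
    w["head_b"] = np.zeros(1)
    return ModelParams(
        weights=w,
        n_cells=n_cells,
        gcn_units=gcn_units,
        nn_units=nn_units,
        use_nn_branch=use_nn_branch,
        compat_literal_normalizer=compat_literal_normalizer,
    )


# ---------------------------------------------------------------------------
# forward passes (public branch functions operate on single blocks or batches)


def _as_batch(x0: np.ndarray) -> tuple[np.ndarray, bool]:
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim == 2:
        return x0[None], True
    if x0.ndim == 3:
        return x0, False
    raise ValueError("pair tensor must have shape (n_cells, 2) or (batch, n_cells, 2)")


def nn_branch(x0: np.ndarray, params: ModelParams) -> np.ndarray:
    """Dense ReLU branch applied per cell row: (.., n_cells, 2) -> (.., n_cells, units)."""
    xb, squeeze = _as_batch(x0)
    if not np.all(np.isfinite(xb)):
        raise ValueError("non-finite values in pair tensor")
    w = params.weights
    a1 = _relu(xb @ w["nn_w0"] + w["nn_b0"])
    out = _relu(a1 @ w["nn_w1"] + w["nn_b1"])
    return out[0] if squeeze else out


def gcn_branch(
    x0: np.ndarray, G: CellGraph | np.ndarray, params: ModelParams
) -> np.ndarray:
    """Two-layer graph convolution with ELU activations."""
    xb, squeeze = _as_batch(x0)
    N = normalize_adjacency(G, params.compat_literal_normalizer) if isinstance(
        G, CellGraph
    ) else np.asarray(G, float)
    if xb.shape[1] != N.shape[0]:
        raise ValueError(
            f"pair tensor has {xb.shape[1]} cells but the graph has {N.shape[0]}"
        )
    w = params.weights
    m0 = np.einsum("ij,bjf->bif", N, xb)
    e1 = _elu(m0 @ w["gcn_w0"] + w["gcn_b0"])
    m1 = np.einsum("ij,bjf->bif", N, e1)
    out = _elu(m1 @ w["gcn_w1"] + w["gcn_b1"])
    return out[0] if squeeze else out


def classify(
    theta1: np.ndarray, theta2: np.ndarray | None, params: ModelParams
) -> np.ndarray:
    """Concatenate -> flatten -> dense -> sigmoid; returns probabilities."""
    t1, squeeze = _as_batch(theta1)
    if params.use_nn_branch:
        if theta2 is None:
            raise ValueError("theta2 required when the NN branch is enabled")
        t2, _ = _as_batch(theta2)
        if t1.shape[:2] != t2.shape[:2]:
            raise ValueError("branch outputs are not row-aligned")
        cat = np.concatenate([t1, t2], axis=-1)
    else:
        cat = t1
    flat = cat.reshape(cat.shape[0], -1)
    w = params.weights
    if flat.shape[1] != w["head_w"].shape[0]:
        raise ValueError(
            f"flattened features ({flat.shape[1]}) do not match head weights "
            f"({w['head_w'].shape[0]}); the model is tied to its training graph"
        )
    logit = flat @ w["head_w"] + w["head_b"][0]
    p = _sigmoid(logit)
    return p[0] if squeeze else p


def bce_loss(
    preds: np.ndarray, labels: np.ndarray, reduction: str = "sum", eps: float = _EPS
) -> float:
    """Binary cross-entropy over T pairs (sum convention; mean optional)."""
    preds = np.clip(np.asarray(preds, dtype=float), eps, 1.0 - eps)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    labels = labels.astype(float)
    terms = labels * np.log(preds) + (1.0 - labels) * np.log(1.0 - preds)
    if reduction == "sum":
        return float(-np.sum(terms))
    if reduction == "mean":
        return float(-np.mean(terms))
    raise ValueError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# fused forward/backward for training


def _forward(params: ModelParams, xb: np.ndarray, N: np.ndarray) -> dict:
    w = params.weights
    cache: dict[str, np.ndarray] = {"xb": xb}
    cache["m0"] = np.einsum("ij,bjf->bif", N, xb)
    cache["g1"] = cache["m0"] @ w["gcn_w0"] + w["gcn_b0"]
    cache["e1"] = _elu(cache["g1"])
    cache["m1"] = np.einsum("ij,bjf->bif", N, cache["e1"])
    cache["g2"] = cache["m1"] @ w["gcn_w1"] + w["gcn_b1"]
    theta1 = _elu(cache["g2"])
    if params.use_nn_branch:
        cache["z1"] = xb @ w["nn_w0"] + w["nn_b0"]
        cache["a1"] = _relu(cache["z1"])
        cache["z2"] = cache["a1"] @ w["nn_w1"] + w["nn_b1"]
        theta2 = _relu(cache["z2"])
        cat = np.concatenate([theta1, theta2], axis=-1)
    else:
        cat = theta1
    cache["theta1"] = theta1
    flat = cat.reshape(cat.shape[0], -1)
    cache["flat"] = flat
    cache["logit"] = flat @ w["head_w"] + w["head_b"][0]
    cache["p"] = _sigmoid(cache["logit"])
    return cache


def loss_and_grads(
    params: ModelParams, xb: np.ndarray, N: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean binary cross-entropy over the batch and its analytic gradients."""
    w = params.weights
    cache = _forward(params, xb, N)
    p, y = cache["p"], np.asarray(y, dtype=float)
    loss = bce_loss(p, y, reduction="mean")
    B = xb.shape[0]
    n = params.n_cells
    # clipped-BCE + sigmoid gradient: zero where the prediction is saturated
    inside = (p > _EPS) & (p < 1.0 - _EPS)
    dlogit = np.where(inside, p - y, 0.0) / B
    grads: dict[str, np.ndarray] = {}
    grads["head_w"] = cache["flat"].T @ dlogit
    grads["head_b"] = np.array([dlogit.sum()])
    dflat = dlogit[:, None] * w["head_w"][None, :]
    feat = params.gcn_units + (params.nn_units if params.use_nn_branch else 0)
    dcat = dflat.reshape(B, n, feat)
    dtheta1 = dcat[..., : params.gcn_units]
    dg2 = dtheta1 * _elu_grad(cache["g2"])
    grads["gcn_w1"] = np.einsum("bni,bnj->ij", cache["m1"], dg2)
    grads["gcn_b1"] = dg2.sum(axis=(0, 1))
    dm1 = dg2 @ w["gcn_w1"].T
    de1 = np.einsum("ji,bjf->bif", N, dm1)  # N^T propagation
    dg1 = de1 * _elu_grad(cache["g1"])
    grads["gcn_w0"] = np.einsum("bni,bnj->ij", cache["m0"], dg1)
    grads["gcn_b0"] = dg1.sum(axis=(0, 1))
    if params.use_nn_branch:
        dtheta2 = dcat[..., params.gcn_units :]
        dz2 = dtheta2 * (cache["z2"] > 0)
        grads["nn_w1"] = np.einsum("bni,bnj->ij", cache["a1"], dz2)
        grads["nn_b1"] = dz2.sum(axis=(0, 1))
        da1 = dz2 @ w["nn_w1"].T
        dz1 = da1 * (cache["z1"] > 0)
        grads["nn_w0"] = np.einsum("bni,bnj->ij", xb, dz1)
        grads["nn_b0"] = dz1.sum(axis=(0, 1))
    return loss, grads


class _Adam:
    def __init__(self, weights: dict[str, np.ndarray], lr: float = 1e-3):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            weights[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


# ---------------------------------------------------------------------------
# pair-tensor assembly


def build_pair_tensors(pairs: np.ndarray, X: ExpressionMatrix) -> np.ndarray:
    """Stack per-pair (n_cells x 2) blocks: column 0 regulator, column 1 target.

    Cells follow the expression matrix's row order, which must match the
    graph the model was (or will be) trained with.
    """
    pairs = np.asarray(pairs, dtype=object)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n_pairs, 2) array of gene names")
    missing = sorted(
        {str(g) for g in pairs.ravel() if not X.has_gene(str(g))},
        key=str.casefold,
    )
    if missing:
        raise KeyError(f"genes absent from expression matrix: {', '.join(missing)}")
    cols = np.array(
        [[X.gene_index(str(r)), X.gene_index(str(t))] for r, t in pairs]
    )
    return np.stack(
        [np.column_stack([X.values[:, i], X.values[:, j]]) for i, j in cols]
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator


class SFINNClassifier(BaseEstimator, ClassifierMixin):
    """Gene-pair classifier over a fixed expression matrix and cell graph.

    The estimator follows the scikit-learn protocol: samples passed to
    ``fit``/``predict_proba`` are (n_pairs, 2) arrays of gene names; the
    dataset-level context (the expression matrix and the cell graph, which
    play the role of a precomputed kernel) is given at construction. This
    makes the classifier compose with ``GroupKFold(groups=tf_group)`` for
    leakage-free TF-wise model selection.

    Parameters
    ----------
    expression, graph
        The cells x genes matrix and the cell-cell adjacency; cell order must
        agree.
    gcn_units, nn_units
        Widths of the graph-convolution and dense branches.
    use_nn_branch
        Disable to train the graph-convolution-only ablation.
    epochs, batch_size, learning_rate, patience, val_fraction
        Optimisation settings; early stopping monitors mean BCE on an
        internal ``val_fraction`` slice of the training pairs and restores
        the best weights.
    seed
        Controls initialisation, the validation split and shuffling; a fixed
        seed gives bit-identical training on CPU.

    Attributes
    ----------
    params_ : ModelParams
        Trained weights and architecture.
    classes_ : ndarray
        ``[0, 1]``.
    history_ : dict
        Per-epoch train/validation loss curves.
    """

    def __init__(
        self,
        expression: ExpressionMatrix | None = None,
        graph: CellGraph | None = None,
        gcn_units: int = 32,
        nn_units: int = 32,
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        use_nn_branch: bool = True,
        patience: int = 10,
        val_fraction: float = 0.1,
        compat_literal_normalizer: bool = False,
        seed: int = 0,
    ):
        self.expression = expression
        self.graph = graph
        self.gcn_units = gcn_units
        self.nn_units = nn_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.use_nn_branch = use_nn_branch
        self.patience = patience
        self.val_fraction = val_fraction
        self.compat_literal_normalizer = compat_literal_normalizer
        self.seed = seed

    # -- internal -----------------------------------------------------------

    def _context(self) -> tuple[ExpressionMatrix, CellGraph]:
        if self.expression is None or self.graph is None:
            raise ValueError("expression and graph must be set before fitting")
        if self.expression.n_cells != self.graph.n_cells:
            raise ValueError(
                f"expression has {self.expression.n_cells} cells, graph has "
                f"{self.graph.n_cells}"
            )
        return self.expression, self.graph

    def fit(self, P: np.ndarray, y: np.ndarray) -> "SFINNClassifier":
        X, G = self._context()
        P = np.asarray(P, dtype=object)
        y = np.asarray(y, dtype=int)
        if len(P) != len(y):
            raise ValueError("P and y length mismatch")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        xb = build_pair_tensors(P, X)
        N = normalize_adjacency(G, self.compat_literal_normalizer)
        params = init_params(
            X.n_cells,
            rng_for(self.seed, "init"),
            gcn_units=self.gcn_units,
            nn_units=self.nn_units,
            use_nn_branch=self.use_nn_branch,
            compat_literal_normalizer=self.compat_literal_normalizer,
        )
        n_pairs = len(P)
        n_val = int(round(self.val_fraction * n_pairs))
        n_val = min(max(n_val, 1), n_pairs - 1) if n_pairs > 1 else 0
        perm = rng_for(self.seed, "val_split").permutation(n_pairs)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        shuffle_rng = rng_for(self.seed, "shuffle")
        opt = _Adam(params.weights, lr=self.learning_rate)
        best = params.copy()
        best_val = np.inf
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        stall = 0
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(tr_idx)
            epoch_losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                loss, grads = loss_and_grads(params, xb[batch], N, y[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        "training diverged (loss is not finite); "
                        "reduce the learning rate"
                    )
                opt.step(params.weights, grads)
                epoch_losses.append(loss)
            history["train_loss"].append(float(np.mean(epoch_losses)))
            if n_val:
                val_p = _forward(params, xb[val_idx], N)["p"]
                val_loss = bce_loss(val_p, y[val_idx], reduction="mean")
            else:
                val_loss = history["train_loss"][-1]
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best = params.copy()
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        best.meta = {
            "training_tfs": [],
            "seed": self.seed,
            "epochs_run": len(history["train_loss"]),
            "best_val_loss": float(best_val),
        }
        self.params_ = best
        self.classes_ = np.array([0, 1])
        self.history_ = history
        self.n_features_in_ = 2
        return self

    def predict_proba(self, P: np.ndarray) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise ValueError("classifier is not fitted")
        X, G = self._context()
        xb = build_pair_tensors(np.asarray(P, dtype=object), X)
        N = normalize_adjacency(G, self.params_.compat_literal_normalizer)
        p = _forward(self.params_, xb, N)["p"]
        return np.column_stack([1.0 - p, p])

    def predict(self, P: np.ndarray) -> np.ndarray:
        return (self.predict_proba(P)[:, 1] > 0.5).astype(int)

    def decision_function(self, P: np.ndarray) -> np.ndarray:
        return self.predict_proba(P)[:, 1]


# ---------------------------------------------------------------------------
# functional wrappers


def train(
    train_pairs: PairDataset,
    X: ExpressionMatrix,
    G: CellGraph,
    cfg: TrainConfig | None = None,
) -> ModelParams:
    """Train a classifier on a pair dataset; returns the best weights."""
    cfg = cfg or TrainConfig()
    clf = SFINNClassifier(
        expression=X,
        graph=G,
        gcn_units=cfg.gcn_units,
        nn_units=cfg.nn_units,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        use_nn_branch=cfg.use_nn_branch,
        patience=cfg.patience,
        val_fraction=cfg.val_fraction,
        compat_literal_normalizer=cfg.compat_literal_normalizer,
        seed=cfg.seed,
    )
    clf.fit(train_pairs.pair_array(), train_pairs.labels())
    params = clf.params_
    params.meta["training_tfs"] = sorted(train_pairs.tf_groups)
    params.meta["config"] = asdict(cfg)
    return params


def predict(
    params: ModelParams,
    pairs: PairDataset | np.ndarray,
    X: ExpressionMatrix,
    G: CellGraph,
) -> np.ndarray:
    """Per-pair probabilities from trained weights; never mutates ``params``."""
    arr = pairs.pair_array() if isinstance(pairs, PairDataset) else np.asarray(
        pairs, dtype=object
    )
    if X.n_cells != params.n_cells:
        raise ValueError(
            f"model was trained on {params.n_cells} cells but the expression "
            f"matrix has {X.n_cells}; a trained model is tied to its graph"
        )
    xb = build_pair_tensors(arr, X)
    N = normalize_adjacency(G, params.compat_literal_normalizer)
    return _forward(params, xb, N)["p"]


def save_model(params: ModelParams, path: str | Path) -> None:
    """Checkpoint weights + architecture + metadata to an ``.npz`` archive."""
    arch = {
        "n_cells": params.n_cells,
        "gcn_units": params.gcn_units,
        "nn_units": params.nn_units,
        "use_nn_branch": params.use_nn_branch,
        "compat_literal_normalizer": params.compat_literal_normalizer,
        "meta": params.meta,
    }
    np.savez(
        path,
        __arch__=np.frombuffer(json.dumps(arch).encode(), dtype=np.uint8),
        **params.weights,
    )


def load_model(path: str | Path) -> ModelParams:
    with np.load(path) as archive:
        arch = json.loads(bytes(archive["__arch__"]).decode())
        weights = {k: archive[k].copy() for k in archive.files if k != "__arch__"}
    return ModelParams(
        weights=weights,
        n_cells=int(arch["n_cells"]),
        gcn_units=int(arch["gcn_units"]),
        nn_units=int(arch["nn_units"]),
        use_nn_branch=bool(arch["use_nn_branch"]),
        compat_literal_normalizer=bool(arch["compat_literal_normalizer"]),
        meta=arch.get("meta", {}),
    )
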