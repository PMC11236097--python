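"""Cell-cell adjacency construction: shared factor neighborhood, spatial
similarity and logical-OR fusion.

The shared-factor-neighborhood (SFN) strategy summarises every cell by the
histogram of the *dominant PCA factors* of its K nearest neighbours in the
reduced expression space, and links two cells when those histograms are close
under a Manhattan distance mapped through the similarity transform

    S[i, j] = 1 / (1 + E[i, j])

with an edge admitted whenever S exceeds a threshold (0.5 by default, i.e.
E < 1). Spatial graphs apply the same transform to rescaled Euclidean
distances between cell positions, and the two graphs are fused by an
elementwise logical OR.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .io import ExpressionMatrix, SpatialCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "FactorEmbedding",
    "FactorNeighborhood",
    "CellGraph",
    "compute_factor_embedding",
    "shared_factor_neighborhood",
    "manhattan_distance",
    "similarity_from_distance",
    "threshold_adjacency",
    "spatial_adjacency",
    "fuse_graphs",
    "alternative_graph",
    "sfn_graph",
    "SFNGraph",
    "write_graph",
    "read_graph",
]


@dataclass
class FactorEmbedding:
    """PCA scores retaining the leading factors up to a variance target."""

    H: np.ndarray  # (n_cells, n_factors)
    explained_fraction: np.ndarray  # per-factor variance fractions, descending

    @property
    def n_factors(self) -> int:
        return self.H.shape[1]


@dataclass
class FactorNeighborhood:
    """K-nearest-neighbour structure and dominant-factor histograms."""

    k: int
    neighbors: np.ndarray  # (n_cells, k) int indices, self excluded
    dominant: np.ndarray  # (n_cells,) dominant factor index per cell
    fn: np.ndarray  # (n_cells, n_factors) histogram counts, rows sum to k


@dataclass
class CellGraph:
    """Symmetric binary cell-cell adjacency with zero diagonal."""

    a: np.ndarray
    source: str  # "expression" | "spatial" | "fused"

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.a = a.astype(np.int8)

    @property
    def n_cells(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def degree_matrix(self) -> np.ndarray:
        """Degree matrix of the self-loop-augmented adjacency A + I."""
        return np.diag(self.a.sum(axis=1) + 1.0)


def compute_factor_embedding(
    X: ExpressionMatrix | np.ndarray, variance_target: float = 0.90
) -> FactorEmbedding:
    """PCA of the cells x genes matrix, keeping the smallest number of
    components whose cumulative explained variance reaches ``variance_target``.

    Scores are column-centred; each factor's sign is fixed so that its
    largest-magnitude gene loading is positive, making runs reproducible
    across linear-algebra backends.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if values.shape[0] < 2:
        raise ValueError("PCA needs at least two cells")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    centered = values - values.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("expression matrix has zero variance; PCA undefined")
    pca = PCA(n_components=min(values.shape), svd_solver="full")
    scores = pca.fit_transform(values)
    evr = pca.explained_variance_ratio_
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
    cum = np.cumsum(evr)
    reached = np.flatnonzero(cum >= variance_target - 1e-9)
    k = int(reached[0]) + 1 if reached.size else rank
    k = max(1, min(k, rank))
    components = pca.components_[:k]
    scores = scores[:, :k].copy()
    for j in range(k):
        lead = np.argmax(np.abs(components[j]))
        if components[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return FactorEmbedding(H=scores, explained_fraction=evr[:k].copy())


def shared_factor_neighborhood(
    H: FactorEmbedding | np.ndarray, k: int = 10, dominant_on_abs: bool = False
) -> FactorNeighborhood:
    """K nearest neighbours (Euclidean, self excluded, distance ties broken by
    lower cell index) and the histogram of the neighbours' dominant factors.

    The dominant factor of a cell is the argmax of its signed factor scores
    (first index on ties); set ``dominant_on_abs`` to take the argmax of the
    absolute scores instead.
    """
    h = H.H if isinstance(H, FactorEmbedding) else np.asarray(H, float)
    n_cells, n_factors = h.shape
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")
    if k < 1:
        raise ValueError("k must be positive")
    dist = cdist(h, h)
    np.fill_diagonal(dist, np.inf)  # exclude self even under duplicate rows
    # stable sort => ties resolved toward the lower cell index
    order = np.argsort(dist, axis=1, kind="stable")
    neighbors = order[:, :k]
    scores = np.abs(h) if dominant_on_abs else h
    dominant = np.argmax(scores, axis=1)
    fn = np.zeros((n_cells, n_factors), dtype=int)
    for i in range(n_cells):
        fn[i] = np.bincount(dominant[neighbors[i]], minlength=n_factors)
    return FactorNeighborhood(k=k, neighbors=neighbors, dominant=dominant, fn=fn)


def manhattan_distance(
    fn: np.ndarray, k: int | None = None, normalize_by_k: bool = True
) -> np.ndarray:
    """Pairwise Manhattan distance between dominant-factor histograms.

    With ``normalize_by_k`` (default) the histograms are divided by K first,
    putting distances in [0, 2] so the default similarity threshold of 0.5
    (edge iff distance < 1) is meaningful; raw integer counts are kept when
    the flag is off.
    """
    fn = np.asarray(fn, dtype=float)
    if normalize_by_k:
        if k is None:
            row_sums = fn.sum(axis=1)
            if not np.allclose(row_sums, row_sums[0]):
                raise ValueError("cannot infer K: histogram rows sum differently")
            k = int(round(row_sums[0]))
        fn = fn / k
    return cdist(fn, fn, metric="cityblock")


def similarity_from_distance(E: np.ndarray) -> np.ndarray:
    """Map a non-negative distance matrix to similarities 1 / (1 + E)."""
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("distances must be non-negative")
    return 1.0 / (1.0 + E)


def threshold_adjacency(
    S: np.ndarray, threshold: float = 0.5, source: str = "expression"
) -> CellGraph:
    """Binary adjacency: edge iff similarity strictly exceeds ``threshold``."""
    S = np.asarray(S, dtype=float)
    a = (S > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    a = np.maximum(a, a.T)  # defensive; S is symmetric in all pipeline paths
    graph = CellGraph(a=a, source=source)
    if graph.n_edges == 0:
        logger.warning("thresholded graph has zero edges (threshold=%g)", threshold)
    return graph


def spatial_adjacency(
    coords: SpatialCoordinates | np.ndarray,
    threshold: float = 0.5,
    scale: str = "median_knn",
) -> CellGraph:
    """Adjacency from 2-D positions via rescaled Euclidean distances.

    With ``scale="median_knn"`` distances are divided by the median
    nearest-neighbour spacing, so a unit distance means "one typical neighbour
    gap" regardless of the coordinate units; ``scale="none"`` uses raw
    distances.
    """
    xy = coords.xy if isinstance(coords, SpatialCoordinates) else np.asarray(coords, float)
    if xy.shape[0] < 2:
        raise ValueError("spatial graph needs at least two cells")
    dist = cdist(xy, xy)
    if scale == "median_knn":
        off = dist + np.diag(np.full(len(dist), np.inf))
        nn = off.min(axis=1)
        s = float(np.median(nn))
        if s == 0:
            positive = nn[nn > 0]
            s = float(positive.min()) if positive.size else 1.0
        dist = dist / s
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    return threshold_adjacency(similarity_from_distance(dist), threshold, source="spatial")


def fuse_graphs(a_expr: CellGraph, a_spatial: CellGraph) -> CellGraph:
    """Logical-OR fusion of two cell graphs over the same cell set."""
    if a_expr.a.shape != a_spatial.a.shape:
        raise ValueError(
            f"cannot fuse graphs of sizes {a_expr.n_cells} and {a_spatial.n_cells}"
        )
    return CellGraph(a=np.maximum(a_expr.a, a_spatial.a), source="fused")


def alternative_graph(
    X: ExpressionMatrix | np.ndarray,
    strategy: str,
    threshold: float = 0.5,
    variance_target: float = 0.90,
) -> CellGraph:
    """Cell graph from a conventional cell-cell distance on the PCA embedding.

    Supported strategies: ``pcc`` (1 - Pearson correlation), ``euclidean``,
    ``manhattan`` and ``cosine``. Used by the graph-strategy ablation harness;
    the main pipeline uses :func:`sfn_graph`.
    """
    emb = compute_factor_embedding(X, variance_target=variance_target)
    h = emb.H
    if strategy == "pcc":
        if h.shape[1] < 2:
            raise ValueError("pcc strategy needs at least two factors")
        E = 1.0 - np.corrcoef(h)
        E = np.clip(E, 0.0, None)
    elif strategy == "euclidean":
        E = cdist(h, h)
    elif strategy == "manhattan":
        E = cdist(h, h, metric="cityblock")
    elif strategy == "cosine":
        E = np.clip(cdist(h, h, metric="cosine"), 0.0, None)
    else:
        raise ValueError(f"unknown graph strategy {strategy!r}")
    np.fill_diagonal(E, 0.0)
    return threshold_adjacency(similarity_from_distance(E), threshold)


def sfn_graph(
    X: ExpressionMatrix | np.ndarray,
    k: int = 10,
    threshold: float = 0.5,
    variance_target: float = 0.90,
    normalize_by_k: bool = True,
    dominant_on_abs: bool = False,
) -> tuple[CellGraph, FactorEmbedding, FactorNeighborhood]:
    """The full shared-factor-neighborhood pipeline:
    PCA -> KNN -> dominant factors -> histograms -> Manhattan -> similarity
    -> threshold.
    """
    emb = compute_factor_embedding(X, variance_target=variance_target)
    nb = shared_factor_neighborhood(emb, k=k, dominant_on_abs=dominant_on_abs)
    E = manhattan_distance(nb.fn, k=k, normalize_by_k=normalize_by_k)
    S = similarity_from_distance(E)
    return threshold_adjacency(S, threshold), emb, nb


class SFNGraph(BaseEstimator):
    """Cell-graph builder with a scikit-learn estimator surface.

    ``fit(X)`` accepts an :class:`~sfngrn.io.ExpressionMatrix` or a raw
    cells x genes array and exposes the built graph as ``graph_`` together
    with the intermediate embedding and neighbourhood structures.

    Parameters
    ----------
    strategy
        ``"sfn"`` (default) or one of the conventional distances
        ``{"pcc", "euclidean", "manhattan", "cosine"}``.
    variance_target
        Cumulative explained-variance fraction retained by the PCA step.
    k
        Neighbourhood size of the SFN strategy.
    threshold
        Similarity threshold above which an edge is admitted (strict).
    normalize_by_k
        Divide dominant-factor histograms by K before the Manhattan distance.
    dominant_on_abs
        Take the dominant factor as argmax of |score| instead of the signed
        score.
    """

    def __init__(
        self,
        strategy: str = "sfn",
        variance_target: float = 0.90,
        k: int = 10,
        threshold: float = 0.5,
        normalize_by_k: bool = True,
        dominant_on_abs: bool = False,
    ):
        self.strategy = strategy
        self.variance_target = variance_target
        self.k = k
        self.threshold = threshold
        self.normalize_by_k = normalize_by_k
        self.dominant_on_abs = dominant_on_abs

    def fit(self, X: ExpressionMatrix | np.ndarray, y=None) -> "SFNGraph":
        if self.strategy == "sfn":
            graph, emb, nb = sfn_graph(
                X,
                k=self.k,
                threshold=self.threshold,
                variance_target=self.variance_target,
                normalize_by_k=self.normalize_by_k,
                dominant_on_abs=self.dominant_on_abs,
            )
            self.embedding_ = emb
            self.neighborhood_ = nb
        else:
            graph = alternative_graph(
                X,
                strategy=self.strategy,
                threshold=self.threshold,
                variance_target=self.variance_target,
            )
            self.embedding_ = None
            self.neighborhood_ = None
        self.graph_ = graph
        self.n_cells_ = graph.n_cells
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the binary adjacency matrix."""
        return self.fit(X).graph_.a


def _provenance_hash(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a, dtype=np.int8).tobytes()).hexdigest()


def write_graph(graph: CellGraph, path: str | Path, params: dict | None = None) -> None:
    """Write adjacency as MatrixMarket pattern + a JSON provenance sidecar."""
    path = Path(path)
    sparse = scipy.sparse.coo_matrix(graph.a)
    scipy.io.mmwrite(str(path), sparse, field="pattern", symmetry="symmetric")
    meta = {
        "source": graph.source,
        "n_cells": graph.n_cells,
        "n_edges": graph.n_edges,
        "adjacency_sha256": _provenance_hash(graph.a),
    }
    if params:
        meta.update(params)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_graph(path: str | Path) -> CellGraph:
    path = Path(path)
    a = np.asarray(scipy.io.mmread(str(path)).toarray() != 0, dtype=np.int8)
    source = "expression"
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        source = meta.get("source", source)
    return CellGraph(a=a, source=source)
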