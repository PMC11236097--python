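"""Synthetic single-cell and spatial datasets with planted regulation.

The generator emulates the statistical structure the pipeline assumes:
cells fall into discrete populations; every gene has a cluster-specific
baseline log-mean; each planted target gene is a noisy monotone function of
its transcription factor's log-expression; counts are Poisson draws on the
exponentiated log-expression with Bernoulli dropout; and, in spatial mode,
cluster membership also determines position on the unit square — so
expression neighbourhoods and spatial neighbourhoods coincide, the regime
in which graph fusion is informative.

Generation model, per cell c in cluster z(c) and gene g:

    mu[z, g]   ~  Normal(1.0, 0.5)                      cluster baseline
    tf:   L    =  mu[z, tf] + Normal(0, noise_sd)
    tgt:  L    =  mu[z, tgt] + beta * L_tf + Normal(0, noise_sd)
    other: L   =  mu[z, g] + Normal(0, noise_sd)
    count      =  Poisson(exp(L)) * Bernoulli(1 - dropout_rate)

``beta`` (the effect size) is the only coupling between a TF and its
targets; non-target genes are independent given the cluster.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._random import rng_for
from .io import EdgeList, ExpressionMatrix, SpatialCoordinates

__all__ = ["SimConfig", "simulate", "fixture_suite", "write_bundle"]

_LOG_EXPR_CAP = 12.0  # keeps Poisson means representable


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_cells: int = 200
    n_genes: int = 60
    n_tfs: int = 6
    targets_per_tf: int = 5
    n_clusters: int = 3
    effect_size: float = 1.5  # beta, in log-expression units
    noise_sd: float = 0.5
    dropout_rate: float = 0.1
    spatial: bool = False
    spatial_cluster_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs * (1 + self.targets_per_tf) > self.n_genes:
            raise ValueError(
                f"{self.n_tfs} TFs x (1 + {self.targets_per_tf}) targets need more "
                f"genes than n_genes={self.n_genes}"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.spatial_cluster_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if min(self.n_cells, self.n_genes, self.n_tfs, self.n_clusters) < 1:
            raise ValueError("counts must be positive")
        if self.targets_per_tf < 1:
            raise ValueError("targets_per_tf must be positive")


def _gene_names(cfg: SimConfig) -> tuple[list[str], list[str], dict[str, list[str]]]:
    tfs = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]
    targets_of = {
        tf: [f"TG{i + 1:02d}_{j + 1}" for j in range(cfg.targets_per_tf)]
        for i, tf in enumerate(tfs)
    }
    n_bg = cfg.n_genes - cfg.n_tfs * (1 + cfg.targets_per_tf)
    background = [f"BG{i + 1:03d}" for i in range(n_bg)]
    genes = tfs + [t for tf in tfs for t in targets_of[tf]] + background
    return genes, tfs, targets_of


def simulate(
    cfg: SimConfig,
) -> tuple[ExpressionMatrix, SpatialCoordinates | None, EdgeList]:
    """Draw one dataset under ``cfg``; all randomness flows from ``cfg.seed``."""
    genes, tfs, targets_of = _gene_names(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = rng_for(cfg.seed, "simulate")
    clusters = rng.integers(0, cfg.n_clusters, size=cfg.n_cells)
    baseline = rng.normal(1.0, 0.5, size=(cfg.n_clusters, len(genes)))
    log_expr = baseline[clusters] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_cells, len(genes))
    )
    # planted dependency: target log-expression rides on its TF's
    for tf in tfs:
        tf_col = log_expr[:, gene_pos[tf]]
        for tgt in targets_of[tf]:
            j = gene_pos[tgt]
            log_expr[:, j] = (
                baseline[clusters, j]
                + cfg.effect_size * tf_col
                + rng.normal(0.0, cfg.noise_sd, size=cfg.n_cells)
            )
    counts = rng.poisson(np.exp(np.minimum(log_expr, _LOG_EXPR_CAP))).astype(float)
    if cfg.dropout_rate > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate
        counts *= keep
    cell_ids = [f"cell{i + 1:04d}" for i in range(cfg.n_cells)]
    X = ExpressionMatrix(counts, cell_ids, genes)
    coords = None
    if cfg.spatial:
        centers = rng.uniform(0.0, 1.0, size=(cfg.n_clusters, 2))
        xy = centers[clusters] + rng.normal(
            0.0, cfg.spatial_cluster_sd, size=(cfg.n_cells, 2)
        )
        coords = SpatialCoordinates(cell_ids, xy)
    truth = EdgeList(
        [(tf, tgt) for tf in tfs for tgt in targets_of[tf]], directed=True
    )
    return X, coords, truth


_FIXTURES = {
    # oracle-scale: enough cells for K=5 neighbourhoods, trivially fast
    "tiny": SimConfig(
        n_cells=20, n_genes=12, n_tfs=2, targets_per_tf=2, n_clusters=2, seed=101
    ),
    # end-to-end scale: the conditions the acceptance checks run under
    "small": SimConfig(seed=202),
    "small-spatial": SimConfig(spatial=True, seed=303),
}


def fixture_suite() -> dict[str, tuple[ExpressionMatrix, SpatialCoordinates | None, EdgeList]]:
    """Deterministic named bundles: ``tiny`` (20 cells), ``small``
    (200 cells, 60 genes, 6 TFs x 5 targets) and ``small-spatial`` (same,
    plus coordinates). Fixed seeds make every bundle bit-reproducible.
    """
    return {name: simulate(cfg) for name, cfg in _FIXTURES.items()}


def fixture_config(name: str) -> SimConfig:
    return _FIXTURES[name]


def write_bundle(
    cfg: SimConfig,
    out_dir: str | Path,
) -> dict[str, str]:
    """Simulate under ``cfg`` and write the interchange files to ``out_dir``."""
    from .io import write_coordinates, write_edge_list, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, coords, truth = simulate(cfg)
    files = {"expression": str(out / "expression.tsv"), "truth": str(out / "truth.tsv")}
    write_expression(X, out / "expression.tsv")
    write_edge_list(truth, out / "truth.tsv")
    if coords is not None:
        write_coordinates(coords, out / "coords.csv")
        files["coords"] = str(out / "coords.csv")
    meta = {"config": asdict(cfg), "n_cells": X.n_cells, "n_genes": X.n_genes}
    (out / "sim-metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    files["metadata"] = str(out / "sim-metadata.json")
    return files
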