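"""Readers, writers and normalisation for the pipeline's interchange formats.

Expression matrices travel as dense TSV/CSV (cells x genes, header = gene
names, first column = cell ids) or MatrixMarket ``.mtx`` with companion
``.rows``/``.cols`` name files. Coordinates are a ``cell_id,x,y`` CSV and
ground-truth networks a two-column ``regulator<TAB>target`` TSV.

Gene-name matching is case-insensitive throughout (mouse and human symbol
conventions differ across data sources) while the case of the first
occurrence is preserved on output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SpatialCoordinates",
    "EdgeList",
    "read_expression",
    "write_expression",
    "normalize_expression",
    "read_coordinates",
    "write_coordinates",
    "read_edge_list",
    "write_edge_list",
    "align",
]


def _check_unique_casefold(names: list[str], what: str) -> None:
    seen: dict[str, str] = {}
    for n in names:
        key = n.casefold()
        if key in seen:
            raise ValueError(
                f"duplicate {what} after case normalization: {seen[key]!r} vs {n!r}"
            )
        seen[key] = n


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of non-negative expression values.

    Parameters
    ----------
    values
        Array of shape ``(n_cells, n_genes)``; finite and non-negative.
    cell_ids, gene_ids
        Row and column identifiers, duplicate-free after case folding.
    normalized
        Whether a normalisation step has already been applied.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        _check_unique_casefold(self.cell_ids, "cell id")
        _check_unique_casefold(self.gene_ids, "gene id")
        self._gene_lookup = {g.casefold(): i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, name: str) -> int:
        """Column index of ``name``, matched case-insensitively."""
        try:
            return self._gene_lookup[name.casefold()]
        except KeyError:
            raise KeyError(f"gene {name!r} not present in expression matrix") from None

    def has_gene(self, name: str) -> bool:
        return name.casefold() in self._gene_lookup

    def gene_column(self, name: str) -> np.ndarray:
        return self.values[:, self.gene_index(name)]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """New matrix restricted to the given cell positions (order kept)."""
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index],
            [self.cell_ids[i] for i in index],
            list(self.gene_ids),
            normalized=self.normalized,
        )


@dataclass
class SpatialCoordinates:
    """2-D spatial positions, one row per cell, paired with an expression matrix."""

    cell_ids: list[str]
    xy: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must have shape (n_cells, 2)")
        if len(self.cell_ids) != self.xy.shape[0]:
            raise ValueError("one coordinate row required per cell id")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        _check_unique_casefold(self.cell_ids, "cell id")

    @property
    def n_cells(self) -> int:
        return self.xy.shape[0]

    def subset_cells(self, index: np.ndarray) -> "SpatialCoordinates":
        index = np.asarray(index)
        return SpatialCoordinates([self.cell_ids[i] for i in index], self.xy[index])


@dataclass
class EdgeList:
    """Directed or undirected (regulator, target) gene pairs, deduplicated."""

    edges: list[tuple[str, str]] = field(default_factory=list)
    directed: bool = True

    def __post_init__(self) -> None:
        cleaned: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        n_self = 0
        for a, b in self.edges:
            a, b = str(a), str(b)
            if a.casefold() == b.casefold():
                n_self += 1
                continue
            key = (a.casefold(), b.casefold())
            if key in seen:
                continue
            seen.add(key)
            cleaned.append((a, b))
        if n_self:
            logger.warning("removed %d self-pair(s) from edge list", n_self)
        self.edges = cleaned

    def __len__(self) -> int:
        return len(self.edges)

    def regulators(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for a, _ in self.edges:
            if a.casefold() not in seen:
                seen.add(a.casefold())
                out.append(a)
        return out

    def targets_of(self, regulator: str) -> list[str]:
        key = regulator.casefold()
        return [b for a, b in self.edges if a.casefold() == key]

    def restrict_to(self, gene_universe: list[str]) -> "EdgeList":
        """Drop edges whose genes are absent from ``gene_universe`` (logged)."""
        universe = {g.casefold() for g in gene_universe}
        kept = [
            (a, b)
            for a, b in self.edges
            if a.casefold() in universe and b.casefold() in universe
        ]
        dropped = len(self.edges) - len(kept)
        if dropped:
            logger.warning(
                "dropped %d edge(s) with genes outside the supplied universe", dropped
            )
        return EdgeList(kept, directed=self.directed)


def read_expression(
    path: str | Path,
    format: str | None = None,
    genes_as_rows: bool | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV or MatrixMarket.

    For ``mtx`` the companion name files ``<stem>.rows`` and ``<stem>.cols``
    must sit next to the matrix; on-disk orientation defaults to genes-as-rows
    for MatrixMarket (the common sparse convention) and cells-as-rows for
    delimited text. Pass ``genes_as_rows`` to override.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        if genes_as_rows is None:
            genes_as_rows = True
        rows_path = path.with_suffix(".rows")
        cols_path = path.with_suffix(".cols")
        for p in (path, rows_path, cols_path):
            if not p.exists():
                raise FileNotFoundError(f"required file not found: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        row_names = rows_path.read_text().split()
        col_names = cols_path.read_text().split()
        if genes_as_rows:
            values, gene_ids, cell_ids = mat.T, row_names, col_names
        else:
            values, cell_ids, gene_ids = mat, row_names, col_names
        for g in np.flatnonzero(values.sum(axis=0) == 0):
            logger.warning("gene %s has all-zero expression", gene_ids[g])
    else:
        sep = "\t" if format == "tsv" else ","
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"malformed expression file {path}: {exc}") from exc
        if genes_as_rows:
            frame = frame.T
        values = frame.to_numpy(dtype=float)
        cell_ids = [str(c) for c in frame.index]
        gene_ids = [str(g) for g in frame.columns]
    return ExpressionMatrix(values, cell_ids, gene_ids)


def write_expression(
    X: ExpressionMatrix, path: str | Path, format: str | None = None, decimals: int = 6
) -> None:
    """Write an expression matrix; TSV/CSV values use ``decimals`` fixed places."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(X.values.T)  # genes as rows on disk
        scipy.io.mmwrite(str(path), sparse)
        path.with_suffix(".rows").write_text("\n".join(X.gene_ids) + "\n")
        path.with_suffix(".cols").write_text("\n".join(X.cell_ids) + "\n")
    else:
        sep = "\t" if format == "tsv" else ","
        frame = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
        frame.to_csv(path, sep=sep, float_format=f"%.{decimals}f")


def normalize_expression(X: ExpressionMatrix, mode: str = "none") -> ExpressionMatrix:
    """Normalise an expression matrix.

    ``library_log1p`` rescales each cell's counts so every library totals the
    median library size, then applies ``log(1 + x)``; ``none`` only marks the
    matrix as normalised.
    """
    if X.normalized:
        raise ValueError("expression matrix is already normalized")
    if mode == "none":
        return replace(X, values=X.values.copy(), normalized=True)
    if mode == "library_log1p":
        totals = X.values.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            names = ", ".join(X.cell_ids[i] for i in zero[:10])
            raise ValueError(f"cells with zero total count cannot be scaled: {names}")
        median = float(np.median(totals))
        scaled = X.values * (median / totals)[:, None]
        return replace(X, values=np.log1p(scaled), normalized=True)
    raise ValueError(f"unknown normalization mode {mode!r}")


def read_coordinates(path: str | Path) -> SpatialCoordinates:
    """Read a ``cell_id,x,y`` CSV of 2-D cell positions."""
    frame = pd.read_csv(path)
    required = {"cell_id", "x", "y"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"coordinate file must have columns cell_id,x,y; found {list(frame.columns)}"
        )
    return SpatialCoordinates(
        [str(c) for c in frame["cell_id"]], frame[["x", "y"]].to_numpy(dtype=float)
    )


def write_coordinates(coords: SpatialCoordinates, path: str | Path) -> None:
    pd.DataFrame(
        {"cell_id": coords.cell_ids, "x": coords.xy[:, 0], "y": coords.xy[:, 1]}
    ).to_csv(path, index=False)


def read_edge_list(
    path: str | Path,
    directed: bool = True,
    gene_universe: list[str] | None = None,
) -> EdgeList:
    """Read a two-column regulator/target TSV; optionally restrict to a universe."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"edge list {path} must have two tab-separated columns")
    edges = [(str(a), str(b)) for a, b in zip(frame.iloc[:, 0], frame.iloc[:, 1])]
    out = EdgeList(edges, directed=directed)
    if gene_universe is not None:
        out = out.restrict_to(gene_universe)
    return out


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges.edges:
            fh.write(f"{a}\t{b}\n")


def align(
    X: ExpressionMatrix, coords: SpatialCoordinates
) -> tuple[ExpressionMatrix, SpatialCoordinates]:
    """Restrict matrix and coordinates to shared cells, in the matrix's order."""
    coord_pos = {c.casefold(): i for i, c in enumerate(coords.cell_ids)}
    keep_x: list[int] = []
    keep_c: list[int] = []
    for i, c in enumerate(X.cell_ids):
        j = coord_pos.get(c.casefold())
        if j is not None:
            keep_x.append(i)
            keep_c.append(j)
    if not keep_x:
        raise ValueError("expression matrix and coordinates share no cell ids")
    dropped = max(X.n_cells, coords.n_cells) - len(keep_x)
    if dropped:
        logger.warning("align dropped %d unmatched cell(s)", dropped)
    return X.subset_cells(np.array(keep_x)), coords.subset_cells(np.array(keep_c))
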