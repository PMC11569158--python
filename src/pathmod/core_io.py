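"""Containers and I/O for expression matrices, metadata and pathway collections.

The in-memory model follows the single-cell convention: cells are rows,
genes are columns, indices are 0-based.  Expression values must be
nonnegative (raw counts or log-normalized counts); no normalisation is
performed here.  Pathway collections are plain ``name -> gene list``
mappings, read and written in the GMT dialect used by MSigDB/BioPlanet.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class PathwayOverlapWarning(UserWarning):
    """Raised when overlap filtering drops every pathway."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} are not unique")


@dataclass
class ExpressionMatrix:
    """A cells x genes nonnegative expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, shape ``(n_cells, n_genes)``.
    cell_ids, gene_ids
        Ordered unique string identifiers for rows and columns.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.cell_ids, "cell_ids")
        _check_unique(self.gene_ids, "gene_ids")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell_ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene_ids"
            )
        mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
        if mn < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Map gene symbols to column indices; unknown genes raise KeyError."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lut[g] for g in genes], dtype=np.int64)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=np.float64)
        return np.asarray(self.values, dtype=np.float64)


@dataclass
class CellMetadata:
    """Per-cell annotations: sample of origin, cell type, optional batch.

    ``table`` is indexed by cell id and must contain columns ``sample_id``
    and ``cell_type``; ``batch`` is optional and only required by the
    multi-group pseudobulk aggregation.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample_id", "cell_type"):
            if col not in self.table.columns:
                raise ValueError(f"cell metadata is missing column {col!r}")
            if self.table[col].isna().any():
                raise ValueError(f"cell metadata column {col!r} has missing values")
        _check_unique(list(self.table.index.astype(str)), "cell metadata index ids")

    @property
    def has_batch(self) -> bool:
        return "batch" in self.table.columns

    def aligned_to(self, cell_ids: Sequence[str]) -> pd.DataFrame:
        missing = set(cell_ids) - set(self.table.index.astype(str))
        if missing:
            raise ValueError(
                f"cell metadata does not cover {len(missing)} cells "
                f"(e.g. {sorted(missing)[:3]})"
            )
        return self.table.loc[list(cell_ids)]


@dataclass
class SampleMetadata:
    """Per-sample clinical table: categorical conditions and numeric traits."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.table.index.astype(str)), "sample ids")

    def condition(self, column: str) -> pd.Series:
        if column not in self.table.columns:
            raise KeyError(f"no sample metadata column {column!r}")
        return self.table[column]


@dataclass
class PathwayCollection:
    """Mapping of pathway name to gene-symbol list.

    Gene symbols are matched by exact, case-sensitive string equality.
    Within each pathway, duplicate genes are removed preserving first
    occurrence; names must be unique and lists non-empty.
    """

    pathways: dict[str, list[str]]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene list")
            cleaned[name] = list(dict.fromkeys(str(g) for g in genes))
        self.pathways = cleaned

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, name: str) -> list[str]:
        return self.pathways[name]

    def items(self):
        return self.pathways.items()

    def names(self) -> list[str]:
        return list(self.pathways)


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Read a GMT file (tab-separated: name, description, genes...).

    The description field is discarded; duplicate genes within a line are
    deduplicated preserving first occurrence.  Malformed lines (fewer than
    three fields) and duplicate pathway names raise ``ValueError`` naming
    the offending line.
    """
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in pathways:
                raise ValueError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
            genes = [g for g in fields[2:] if g]
            pathways[name] = list(dict.fromkeys(genes))
    return PathwayCollection(pathways, provenance=str(path))


def write_gmt(collection: PathwayCollection, path: str | os.PathLike) -> None:
    """Write a collection as GMT; the description field is set to 'na'."""
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def generate_pathway_input(
    pathways: PathwayCollection,
    genes: Sequence[str],
    min_overlap: int = 6,
) -> tuple[PathwayCollection, pd.DataFrame]:
    """Filter and reformat a pathway collection against a gene universe.

    Each retained pathway's gene list is replaced by its intersection with
    ``genes`` (order preserved); pathways whose overlap has fewer than
    ``min_overlap`` genes are dropped.  Returns the filtered collection and
    a per-pathway report with columns ``original_size``, ``overlap_size``
    and ``kept``.

    The inclusive reading (keep overlap >= ``min_overlap``) is the default;
    the threshold is exposed so the strict reading is one parameter away.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(genes) == 0:
        raise ValueError("gene universe is empty")
    universe = set(genes)
    kept: dict[str, list[str]] = {}
    rows = []
    for name, gene_list in pathways.items():
        overlap = [g for g in gene_list if g in universe]
        keep = len(overlap) >= min_overlap
        rows.append(
            {
                "pathway": name,
                "original_size": len(gene_list),
                "overlap_size": len(overlap),
                "kept": keep,
            }
        )
        if keep:
            kept[name] = overlap
    report = pd.DataFrame(rows).set_index("pathway")
    if not kept:
        warnings.warn(
            "all pathways dropped by the overlap filter", PathwayOverlapWarning
        )
        filtered = PathwayCollection.__new__(PathwayCollection)
        filtered.pathways = {}
        filtered.provenance = pathways.provenance + " [overlap-filtered]"
        return filtered, report
    return (
        PathwayCollection(kept, provenance=pathways.provenance + " [overlap-filtered]"),
        report,
    )


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    path: str | os.PathLike,
    fmt: str = "mtx_dir",
    genes_as_rows: bool = False,
) -> tuple[ExpressionMatrix, CellMetadata | None]:
    """Load an expression matrix from disk.

    Formats
    -------
    ``mtx_dir``
        A directory with ``matrix.mtx`` (MatrixMarket triplet),
        ``cells.txt`` and ``genes.txt`` (one id per line), and optionally
        ``cell_metadata.csv``.  ``genes_as_rows=True`` transposes a
        genes x cells matrix on load.
    ``h5ad``
        An AnnData HDF5 container (read-only); cell metadata columns
        ``sample_id``/``cell_type``/``batch`` are picked up from ``.obs``
        when present.
    ``dense_tsv``
        A TSV with cell ids as the index column and gene ids as header.
    """
    if fmt == "mtx_dir":
        mat = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
        mat = sp.csr_matrix(mat)
        if genes_as_rows:
            mat = sp.csr_matrix(mat.T)
        cell_ids = _read_ids(os.path.join(path, "cells.txt"))
        gene_ids = _read_ids(os.path.join(path, "genes.txt"))
        meta = None
        meta_path = os.path.join(path, "cell_metadata.csv")
        if os.path.exists(meta_path):
            meta = CellMetadata(pd.read_csv(meta_path, index_col=0))
        return ExpressionMatrix(mat, cell_ids, gene_ids), meta
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        values = adata.X
        if sp.issparse(values):
            values = sp.csr_matrix(values)
        else:
            values = np.asarray(values)
        em = ExpressionMatrix(
            values, list(adata.obs_names), list(adata.var_names)
        )
        meta = None
        if {"sample_id", "cell_type"} <= set(adata.obs.columns):
            cols = ["sample_id", "cell_type"]
            if "batch" in adata.obs.columns:
                cols.append("batch")
            meta = CellMetadata(adata.obs[cols].astype(str))
        return em, meta
    if fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if genes_as_rows:
            df = df.T
        return (
            ExpressionMatrix(
                df.to_numpy(dtype=np.float64),
                list(df.index.astype(str)),
                list(df.columns.astype(str)),
            ),
            None,
        )
    raise ValueError(f"unknown expression format {fmt!r}")


def write_expression_mtx(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    cell_metadata: CellMetadata | None = None,
) -> None:
    """Write an ExpressionMatrix as a MatrixMarket directory bundle."""
    os.makedirs(path, exist_ok=True)
    values = matrix.values
    if not sp.issparse(values):
        values = sp.csr_matrix(values)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp.coo_matrix(values))
    with open(os.path.join(path, "cells.txt"), "w") as fh:
        fh.write("\n".join(matrix.cell_ids) + "\n")
    with open(os.path.join(path, "genes.txt"), "w") as fh:
        fh.write("\n".join(matrix.gene_ids) + "\n")
    if cell_metadata is not None:
        cell_metadata.table.to_csv(os.path.join(path, "cell_metadata.csv"))
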