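"""Truncated-rank Mann-Whitney pathway activity scoring.

Each cell's genes are ranked in descending expression order (average ranks
for ties).  Ranks beyond ``r_max`` are uninformative in sparse single-cell
data and are truncated: stored as 0 in the rank matrix and reconstituted as
``r_max + 1`` inside the score formula.  For a pathway ``S`` of ``n`` genes
the per-cell score is

    PAS_j = 1 - U_j / (n * r_max),   U_j = sum(ranks of S in cell j) - n(n+1)/2

which lies in [0, 1]; cells where every pathway gene is truncated (the C0
set, rank-sum V = 0 in the stored matrix) are set to exactly 0.

Ranks are always computed over ALL genes of the matrix; the pathway-union
submatrix is extracted only afterwards, so scores are independent of which
other pathways are scored alongside.  Scoring is chunked over cells and the
pathway set may be partitioned across workers; both are pure execution
details and the result is bit-identical for every configuration.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .core_io import ExpressionMatrix, PathwayCollection

DEFAULT_R_MAX = 1500
DEFAULT_CHUNK_CELLS = 100_000


@dataclass
class TruncatedRankMatrix:
    """Cells x genes matrix of within-cell descending ranks, 0 = truncated."""

    values: sp.csr_matrix
    r_max: int

    def __post_init__(self) -> None:
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")


@dataclass
class PASMatrix:
    """Cells x pathways activity scores with provenance parameters."""

    values: np.ndarray
    cell_ids: list[str]
    pathway_names: list[str]
    scorer: str
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.cell_ids, columns=self.pathway_names
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path)


def rank_genes(X: ExpressionMatrix | np.ndarray | sp.spmatrix, r_max: int = DEFAULT_R_MAX) -> TruncatedRankMatrix:
    """Rank every cell's genes in descending expression order, truncated.

    Ties receive average ranks, so fractional values occur; any rank
    exceeding ``r_max`` is stored as the sparse sentinel 0.  Because the
    matrix is nonnegative, all zero-expression genes of a cell form one
    bottom tie group whose average rank is ``nnz + (n_zero + 1)/2``; it is
    assigned directly, and only the nonzero entries are passed through the
    ranking routine.  Ranking one cell never depends on any other cell.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    values = X.values if isinstance(X, ExpressionMatrix) else X
    Xs = sp.csr_matrix(values, dtype=np.float64)
    if Xs.nnz and Xs.data.min() < 0:
        raise ValueError("expression values must be nonnegative")
    n_cells, n_genes = Xs.shape
    indptr = Xs.indptr
    out_data = np.zeros(Xs.nnz, dtype=np.float64)
    rows_extra: list[np.ndarray] = []  # zero-gene entries that stay <= r_max
    cols_extra: list[np.ndarray] = []
    vals_extra: list[float] = []
    for i in range(n_cells):
        lo, hi = indptr[i], indptr[i + 1]
        nnz = hi - lo
        if nnz:
            # descending ranks among nonzeros == full-matrix ranks, since
            # every zero is strictly smaller than every nonzero
            r = rankdata(-Xs.data[lo:hi], method="average")
            r[r > r_max] = 0.0
            out_data[lo:hi] = r
        n_zero = n_genes - nnz
        if n_zero:
            zero_rank = nnz + (n_zero + 1) / 2.0
            if zero_rank <= r_max:
                cols = np.setdiff1d(
                    np.arange(n_genes), Xs.indices[lo:hi], assume_unique=True
                )
                rows_extra.append(np.full(cols.size, i, dtype=np.int64))
                cols_extra.append(cols)
                vals_extra.append(zero_rank)
    R = sp.csr_matrix(
        (out_data, Xs.indices.copy(), indptr.copy()), shape=(n_cells, n_genes)
    )
    R.eliminate_zeros()
    if rows_extra:
        rows = np.concatenate(rows_extra)
        cols = np.concatenate(cols_extra)
        data = np.concatenate(
            [np.full(c.size, v) for c, v in zip(cols_extra, vals_extra)]
        )
        R = sp.csr_matrix(
            R + sp.csr_matrix((data, (rows, cols)), shape=(n_cells, n_genes))
        )
    return TruncatedRankMatrix(R, r_max=r_max)


def ucell_pathway_scores(
    R: TruncatedRankMatrix, gene_idx: np.ndarray, r_max: int | None = None
) -> np.ndarray:
    """Score one pathway (given by column indices) for every cell.

    Implements the sparse reconstruction: V = per-cell sum of stored ranks
    over the pathway columns, z = per-cell count of truncated (stored-zero)
    pathway genes; cells with V = 0 score exactly 0, the rest score
    ``1 - (V + (r_max+1) z - n(n+1)/2) / (n r_max)``.
    """
    r_max = R.r_max if r_max is None else r_max
    gene_idx = np.asarray(gene_idx, dtype=np.int64)
    n = gene_idx.size
    if n == 0:
        raise ValueError("pathway has no genes after filtering")
    if n > R.values.shape[1]:
        raise ValueError("pathway larger than the gene universe")
    if n > r_max:
        # the score is only bounded in [0, 1] while r_max covers the pathway
        raise ValueError(f"pathway size n={n} exceeds r_max={r_max}")
    Rs = R.values[:, gene_idx]
    V = np.asarray(Rs.sum(axis=1)).ravel()
    nz_per_cell = np.diff(sp.csr_matrix(Rs).indptr)
    z = n - nz_per_cell
    scores = 1.0 - (V + (r_max + 1.0) * z - n * (n + 1) / 2.0) / (n * r_max)
    scores[V == 0] = 0.0
    return scores


def _score_pathway_block(
    R: TruncatedRankMatrix,
    items: list[tuple[int, np.ndarray]],
    out: np.ndarray,
    row0: int,
) -> None:
    for col, idx in items:
        out[row0 : row0 + R.values.shape[0], col] = ucell_pathway_scores(R, idx)


def fast_ucell(
    X: ExpressionMatrix,
    pathways: PathwayCollection,
    r_max: int = DEFAULT_R_MAX,
    chunk_cells: int = DEFAULT_CHUNK_CELLS,
    workers: int = 1,
) -> PASMatrix:
    """Chunked, parallel truncated-rank Mann-Whitney scoring.

    ``pathways`` must already be overlap-filtered against ``X``'s genes
    (a pathway gene absent from the matrix is a contract violation and
    raises).  Cells are processed in chunks of ``chunk_cells``; within a
    chunk only the union-of-pathway-genes submatrix is scored, after
    ranking all genes.  The pathway set is partitioned across ``workers``;
    every (chunk_cells, workers) configuration yields a bit-identical
    result.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway collection")
    if chunk_cells < 1 or workers < 1:
        raise ValueError("chunk_cells and workers must be >= 1")
    gene_lut = {g: i for i, g in enumerate(X.gene_ids)}
    path_idx: list[tuple[int, np.ndarray]] = []
    union: set[int] = set()
    for col, (name, genes) in enumerate(pathways.items()):
        missing = [g for g in genes if g not in gene_lut]
        if missing:
            raise ValueError(
                f"pathway {name!r} contains genes absent from the matrix "
                f"(e.g. {missing[:3]}); run generate_pathway_input first"
            )
        idx = np.array([gene_lut[g] for g in genes], dtype=np.int64)
        union.update(idx.tolist())
        path_idx.append((col, idx))
    union_idx = np.array(sorted(union), dtype=np.int64)
    remap = {g: i for i, g in enumerate(union_idx.tolist())}
    path_sub = [
        (col, np.array([remap[g] for g in idx.tolist()], dtype=np.int64))
        for col, idx in path_idx
    ]

    Xs = sp.csr_matrix(X.values)
    n_cells = X.n_cells
    out = np.empty((n_cells, len(pathways)), dtype=np.float64)
    for start in range(0, n_cells, chunk_cells):
        stop = min(start + chunk_cells, n_cells)
        # rank over ALL genes of the chunk, then extract the pathway union
        R_full = rank_genes(Xs[start:stop], r_max=r_max)
        R_sub = TruncatedRankMatrix(
            sp.csr_matrix(R_full.values[:, union_idx]), r_max=r_max
        )
        if workers == 1:
            _score_pathway_block(R_sub, path_sub, out, start)
        else:
            blocks = [path_sub[w::workers] for w in range(workers)]
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futures = [
                    pool.submit(_score_pathway_block, R_sub, blk, out, start)
                    for blk in blocks
                    if blk
                ]
                for f in futures:
                    f.result()
    return PASMatrix(
        out,
        cell_ids=list(X.cell_ids),
        pathway_names=pathways.names(),
        scorer="ucell",
        params={"r_max": r_max},
    )
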