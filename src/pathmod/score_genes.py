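"""Bin-matched control-gene module scoring.

The score of a signature ``S`` in cell ``j`` is the mean expression of the
signature genes minus the mean expression of a control set ``S_ref`` drawn
from the same dataset-wide mean-expression bins:

    PAS_j = mean_{g in S} X_{j,g} - mean_{g in S_ref} X_{j,g}

Bins are computed ONCE on the full dataset and one control set per pathway
is fixed BEFORE any cell chunking, so results are bit-identical across
chunk sizes and worker counts for a fixed seed.  Unlike the rank scorer,
these scores depend on dataset composition: adding cells moves the gene
means and therefore the bins and control pools.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .core_io import ExpressionMatrix, PathwayCollection
from .ucell import DEFAULT_CHUNK_CELLS, PASMatrix

DEFAULT_N_BINS = 25
DEFAULT_CTRL_SIZE = 50


@dataclass
class BinAssignment:
    """Per-gene expression bin, from average-ranked dataset-wide means."""

    bin_index: np.ndarray  # int in [0, n_bins)
    n_bins: int
    gene_means: np.ndarray


@dataclass
class ControlSet:
    pathway: str
    control_idx: np.ndarray
    seed: int

    @property
    def n_ref(self) -> int:
        return self.control_idx.size


def compute_bins(
    X: ExpressionMatrix | np.ndarray | sp.spmatrix, n_bins: int = DEFAULT_N_BINS
) -> BinAssignment:
    """Assign every gene to one of ``n_bins`` mean-expression bins.

    Genes are ranked by dataset-wide mean expression (average ranks for
    ties) and the rank scale is cut into ``n_bins`` equal-width intervals,
    so tied means always land in the same bin.  Must be called on the full
    dataset before any chunking.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else X
    n_genes = values.shape[1]
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds the number of genes ({n_genes})")
    if sp.issparse(values):
        means = np.asarray(values.mean(axis=0)).ravel()
    else:
        means = np.asarray(values, dtype=np.float64).mean(axis=0)
    ranks = rankdata(means, method="average")
    # equal-width cut of the rank scale [1, n_genes]
    bins = np.floor((ranks - 1.0) * n_bins / n_genes).astype(np.int64)
    bins = np.clip(bins, 0, n_bins - 1)
    return BinAssignment(bin_index=bins, n_bins=n_bins, gene_means=means)


def sample_control_set(
    signature_idx: np.ndarray,
    bins: BinAssignment,
    ctrl_size: int = DEFAULT_CTRL_SIZE,
    seed: int = 0,
    pathway: str = "",
    allow_signature_in_ctrl: bool = False,
) -> ControlSet:
    """Draw the bin-matched control set for one signature.

    For each signature gene, up to ``ctrl_size`` genes are drawn uniformly
    without replacement from its bin's eligible pool (bin members minus the
    signature itself unless ``allow_signature_in_ctrl``); per-gene draws are
    unioned and deduplicated.  Identical inputs give identical output.
    """
    signature_idx = np.asarray(signature_idx, dtype=np.int64)
    if signature_idx.size == 0:
        raise ValueError("signature is empty")
    rng = np.random.default_rng(seed)
    sig_set = set(signature_idx.tolist())
    chosen: set[int] = set()
    for g in sorted(sig_set):
        pool = np.flatnonzero(bins.bin_index == bins.bin_index[g])
        if not allow_signature_in_ctrl:
            pool = pool[~np.isin(pool, signature_idx)]
        if pool.size == 0:
            continue  # this gene contributes no controls
        take = min(ctrl_size, pool.size)
        chosen.update(rng.choice(pool, size=take, replace=False).tolist())
    if not chosen:
        raise ValueError(
            f"control set for pathway {pathway!r} is empty (no eligible pool)"
        )
    return ControlSet(
        pathway=pathway,
        control_idx=np.array(sorted(chosen), dtype=np.int64),
        seed=seed,
    )


def _pathway_child_seed(master_seed: int, pathway_pos: int) -> int:
    # derived from (master seed, position in sorted name order): stable
    # regardless of worker scheduling
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(pathway_pos,))
    return int(ss.generate_state(1)[0])


def _mean_over(X: sp.csr_matrix | np.ndarray, idx: np.ndarray) -> np.ndarray:
    # strict left-to-right accumulation over genes: the rounding of each
    # cell's sum is then independent of how many cells share the chunk
    sub = X[:, idx]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    acc = np.zeros(sub.shape[0], dtype=np.float64)
    for k in range(sub.shape[1]):
        acc += sub[:, k]
    return acc / idx.size


def fast_score_genes(
    X: ExpressionMatrix,
    pathways: PathwayCollection,
    n_bins: int = DEFAULT_N_BINS,
    ctrl_size: int = DEFAULT_CTRL_SIZE,
    seed: int = 0,
    chunk_cells: int = DEFAULT_CHUNK_CELLS,
    workers: int = 1,
    allow_signature_in_ctrl: bool = False,
) -> PASMatrix:
    """Score all pathways with bin-matched control subtraction.

    Per-pathway child seeds are derived deterministically from the master
    ``seed`` and the pathway's position in sorted-name order, and all
    control sets are sampled globally before the chunk loop.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway collection")
    if chunk_cells < 1 or workers < 1:
        raise ValueError("chunk_cells and workers must be >= 1")
    bins = compute_bins(X, n_bins=n_bins)
    gene_lut = {g: i for i, g in enumerate(X.gene_ids)}
    names = pathways.names()
    order = {n: p for p, n in enumerate(sorted(names))}
    sig_idx: dict[str, np.ndarray] = {}
    controls: dict[str, ControlSet] = {}
    for name, genes in pathways.items():
        missing = [g for g in genes if g not in gene_lut]
        if missing:
            raise ValueError(
                f"pathway {name!r} contains genes absent from the matrix "
                f"(e.g. {missing[:3]}); run generate_pathway_input first"
            )
        # canonical sorted index order so summation order is deterministic
        idx = np.sort(np.array([gene_lut[g] for g in genes], dtype=np.int64))
        sig_idx[name] = idx
        controls[name] = sample_control_set(
            idx,
            bins,
            ctrl_size=ctrl_size,
            seed=_pathway_child_seed(seed, order[name]),
            pathway=name,
            allow_signature_in_ctrl=allow_signature_in_ctrl,
        )

    Xv = X.values if not sp.issparse(X.values) else sp.csr_matrix(X.values)
    n_cells = X.n_cells
    out = np.empty((n_cells, len(names)), dtype=np.float64)

    def score_block(cols: list[int], chunk, row0: int) -> None:
        for col in cols:
            name = names[col]
            sig_mean = _mean_over(chunk, sig_idx[name])
            ctrl_mean = _mean_over(chunk, controls[name].control_idx)
            out[row0 : row0 + sig_mean.size, col] = sig_mean - ctrl_mean

    all_cols = list(range(len(names)))
    for start in range(0, n_cells, chunk_cells):
        stop = min(start + chunk_cells, n_cells)
        chunk = Xv[start:stop]
        if workers == 1:
            score_block(all_cols, chunk, start)
        else:
            blocks = [all_cols[w::workers] for w in range(workers)]
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futs = [
                    pool.submit(score_block, blk, chunk, start)
                    for blk in blocks
                    if blk
                ]
                for f in futs:
                    f.result()
    return PASMatrix(
        out,
        cell_ids=list(X.cell_ids),
        pathway_names=names,
        scorer="score_genes",
        params={
            "n_bins": n_bins,
            "ctrl_size": ctrl_size,
            "seed": seed,
            "control_sizes": {n: controls[n].n_ref for n in names},
        },
    )
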