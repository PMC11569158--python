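"""Shared fixtures and independent reference implementations.

The reference (oracle) functions here deliberately use the slow, literal
form of each computation — dense full ranking, per-cell loops, explicit
step-by-step control sampling — and never call the package's fast paths.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import rankdata

from pathmod import ExpressionMatrix, PathwayCollection


def naive_ucell_scores(
    X: np.ndarray, pathway_cols: dict[str, list[int]], r_max: int
) -> np.ndarray:
    """Per-cell, per-pathway truncated-rank Mann-Whitney scores, the slow way.

    Dense full ranking per cell (descending, average ties), truncated ranks
    set to r_max + 1, U = sum(ranks) - n(n+1)/2, score = 1 - U/(n*r_max);
    cells whose pathway genes are all truncated score exactly 0.
    """
    n_cells = X.shape[0]
    out = np.zeros((n_cells, len(pathway_cols)))
    for j in range(n_cells):
        full = rankdata(-X[j], method="average")
        trunc = np.where(full > r_max, r_max + 1.0, full)
        for col, idx in enumerate(pathway_cols.values()):
            n = len(idx)
            if np.all(full[idx] > r_max):
                out[j, col] = 0.0
            else:
                U = trunc[idx].sum() - n * (n + 1) / 2.0
                out[j, col] = 1.0 - U / (n * r_max)
    return out


def random_instance(seed: int, r_max=1500, max_cells=200, max_genes=500, max_pathways=20):
    """A random counts matrix plus overlap-consistent random pathways.

    Pathway sizes are capped at ``r_max``: the rank score is only defined
    while the informative-rank cap covers the whole pathway.
    """
    rng = np.random.default_rng(seed)
    n_cells = int(rng.integers(5, max_cells + 1))
    n_genes = int(rng.integers(20, max_genes + 1))
    X = rng.poisson(rng.uniform(0.2, 2.0), size=(n_cells, n_genes)).astype(float)
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    n_pw = int(rng.integers(2, max_pathways + 1))
    pathways = {}
    cols = {}
    for k in range(n_pw):
        size = int(rng.integers(3, min(25, n_genes, r_max + 1)))
        idx = sorted(rng.choice(n_genes, size=size, replace=False).tolist())
        pathways[f"P{k}"] = [genes[i] for i in idx]
        cols[f"P{k}"] = idx
    em = ExpressionMatrix(sp.csr_matrix(X), cells, genes)
    return X, em, PathwayCollection(pathways), cols


@pytest.fixture
def small_matrix():
    """10 cells x 50 genes of Poisson counts with 4 pathways."""
    rng = np.random.default_rng(42)
    X = rng.poisson(1.0, size=(10, 50)).astype(float)
    genes = [f"G{i}" for i in range(50)]
    em = ExpressionMatrix(sp.csr_matrix(X), [f"c{i}" for i in range(10)], genes)
    pw = PathwayCollection(
        {
            "PA": genes[0:8],
            "PB": genes[10:16],
            "PC": genes[20:30],
            "PD": genes[5:12],
        }
    )
    return X, em, pw
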