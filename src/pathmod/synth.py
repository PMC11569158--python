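"""Synthetic single-cell fixtures with planted multicellular condition effects.

Two generators cover the two halves of the pipeline:

``make_synthetic_dataset`` draws per-gene negative-binomial counts (the
count sparsity exercises the rank scorer's zero-tie truncation path) for a
case/control cohort of samples, each observed across several cell types.
For case samples, the genes of the planted pathways are multiplied by the
module's effect size within the planted cell types only, so both the
rank-based and the mean-based scorer can detect them; batches add a
batch-specific per-gene multiplicative offset.  A dense Gaussian mode
exists for shift/scale property tests of the control-gene scorer.

``make_planted_pseudobulk`` skips the cell level and emits a low-rank
pseudobulk long table directly: K_true sample-score vectors times per-view
feature loadings plus Gaussian noise, with one designated condition factor
whose sample scores differ by a fixed offset between case and control and
whose loadings are concentrated on the planted (pathway, cell type) pairs.

Everything is reproducible from the seed; these generators are the only
source of randomness in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    CellMetadata,
    ExpressionMatrix,
    PathwayCollection,
    SampleMetadata,
)
from .pseudobulk import LONG_COLUMNS, PseudobulkLongTable


@dataclass
class SyntheticTruth:
    """Ground truth of a planted fixture."""

    planted_pairs: list[tuple[str, str]]  # (pathway, cell type) pairs
    effect_size: float
    condition: pd.Series  # sample -> 'case' / 'control'
    batches: pd.Series  # sample -> batch label
    seed: int
    extras: dict = field(default_factory=dict)


def make_synthetic_dataset(
    n_samples: int = 12,
    n_celltypes: int = 3,
    cells_per_sample_celltype: int = 20,
    n_genes: int = 300,
    n_pathways: int = 8,
    pathway_size: int = 10,
    planted_modules: list[tuple[int, int]] | None = None,
    effect_size: float = 3.0,
    n_batches: int = 1,
    nb_mean: float = 2.0,
    nb_dispersion: float = 0.5,
    gaussian: bool = False,
    seed: int = 0,
) -> tuple[ExpressionMatrix, CellMetadata, SampleMetadata, PathwayCollection, SyntheticTruth]:
    """Generate a full synthetic cohort with planted condition effects.

    ``planted_modules`` lists (pathway index, cell type index) pairs whose
    pathway genes are amplified by ``effect_size`` in case samples within
    that cell type; defaults to ``[(0, 0)]``.  Pathway gene sets are drawn
    disjoint, so planted effects never leak across pathways.  Half the
    samples (rounded up) are cases; batches are assigned round-robin.
    """
    if min(n_samples, n_celltypes, cells_per_sample_celltype, n_genes, n_pathways) < 1:
        raise ValueError("all counts must be >= 1")
    if n_pathways * pathway_size > n_genes:
        raise ValueError("pathway gene sets exceed the gene pool")
    if planted_modules is None:
        planted_modules = [(0, 0)]
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    celltypes = [f"CT{j}" for j in range(n_celltypes)]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    condition = pd.Series(
        ["case" if i < (n_samples + 1) // 2 else "control" for i in range(n_samples)],
        index=samples,
        name="condition",
    )
    batches = pd.Series(
        [f"B{i % n_batches}" for i in range(n_samples)], index=samples, name="batch"
    )

    # disjoint pathway gene sets from a random permutation of the pool
    perm = rng.permutation(n_genes)
    pw = {
        f"PW{p}": [genes[k] for k in perm[p * pathway_size : (p + 1) * pathway_size]]
        for p in range(n_pathways)
    }
    pathways = PathwayCollection(pw, provenance="synthetic")
    planted_pairs = [(f"PW{p}", celltypes[c]) for p, c in planted_modules]

    base_mean = nb_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    batch_offset = {
        b: rng.lognormal(mean=0.0, sigma=0.1 if n_batches > 1 else 0.0, size=n_genes)
        for b in sorted(batches.unique())
    }

    rows, cell_ids, meta_rows = [], [], []
    for s in samples:
        for ct_i, ct in enumerate(celltypes):
            mean = base_mean * batch_offset[batches[s]]
            boost = np.ones(n_genes)
            if condition[s] == "case":
                for p, c in planted_modules:
                    if c == ct_i:
                        idx = perm[p * pathway_size : (p + 1) * pathway_size]
                        boost[idx] = effect_size
            mu = mean * boost
            n_c = cells_per_sample_celltype
            if gaussian:
                block = rng.normal(loc=mu, scale=1.0, size=(n_c, n_genes))
                block = np.abs(block)
            else:
                # NB via gamma-Poisson; dispersion r = 1/nb_dispersion
                r = 1.0 / nb_dispersion
                lam = rng.gamma(shape=r, scale=mu / r, size=(n_c, n_genes))
                block = rng.poisson(lam).astype(np.float64)
            rows.append(block)
            for j in range(n_c):
                cid = f"{s}_{ct}_{j:03d}"
                cell_ids.append(cid)
                meta_rows.append(
                    {"cell_id": cid, "sample_id": s, "cell_type": ct, "batch": batches[s]}
                )
    values = np.vstack(rows)
    X = ExpressionMatrix(sp.csr_matrix(values), cell_ids, genes)
    cell_meta = CellMetadata(pd.DataFrame(meta_rows).set_index("cell_id"))
    sample_meta = SampleMetadata(
        pd.DataFrame({"condition": condition, "batch": batches})
    )
    truth = SyntheticTruth(
        planted_pairs=planted_pairs,
        effect_size=effect_size,
        condition=condition,
        batches=batches,
        seed=seed,
    )
    return X, cell_meta, sample_meta, pathways, truth


def make_planted_pseudobulk(
    n_samples: int = 60,
    n_views: int = 4,
    n_features: int = 20,
    K_true: int = 3,
    condition_factor_index: int = 0,
    condition_offset: float = 2.0,
    noise_sd: float = 0.5,
    n_planted_pairs: int = 6,
    n_groups: int = 1,
    group_shift: float = 0.0,
    seed: int = 0,
) -> tuple[PseudobulkLongTable, SyntheticTruth]:
    """Emit a low-rank pseudobulk long table with one condition factor.

    The condition factor's sample scores are standard normal plus
    ``condition_offset`` for case samples; its loadings are ~1 in magnitude
    on ``n_planted_pairs`` designated (feature, view) pairs and exactly 0
    elsewhere, so top-weight interpretation has an unambiguous target.
    The remaining factors model weaker background covariation: standard
    normal scores with N(0, 0.15) loadings everywhere.  Group labels shift feature baselines by
    ``group_shift`` (removed again by per-group centering downstream).
    """
    if K_true < 1 or not (0 <= condition_factor_index < K_true):
        raise ValueError("need K_true >= 1 and a valid condition factor index")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    views = [f"CT{j}" for j in range(n_views)]
    features = [f"PW{p}" for p in range(n_features)]
    condition = pd.Series(
        ["case" if i % 2 == 0 else "control" for i in range(n_samples)],
        index=samples,
        name="condition",
    )
    groups = pd.Series(
        [f"B{i % n_groups}" for i in range(n_samples)], index=samples, name="batch"
    )

    Z = rng.normal(size=(n_samples, K_true))
    Z[:, condition_factor_index] += np.where(
        condition.to_numpy() == "case", condition_offset, 0.0
    )

    # a multicellular module spans cell types: plant pairs round-robin so
    # every view carries at least one (when n_planted_pairs >= n_views)
    per_view = [n_planted_pairs // n_views + (1 if i < n_planted_pairs % n_views else 0)
                for i in range(n_views)]
    planted = []
    for v, cnt in zip(views, per_view):
        feats = rng.choice(n_features, size=cnt, replace=False)
        planted.extend((features[fi], v) for fi in sorted(feats))
    W = {v: rng.normal(scale=0.15, size=(n_features, K_true)) for v in views}
    for v in views:
        W[v][:, condition_factor_index] = 0.0
    for f, v in planted:
        fi = features.index(f)
        W[v][fi, condition_factor_index] = rng.choice([-1.0, 1.0]) * rng.uniform(
            0.8, 1.2
        )

    rows = []
    for v in views:
        Y = Z @ W[v].T + rng.normal(scale=noise_sd, size=(n_samples, n_features))
        if group_shift:
            gshift = {g: rng.normal(scale=group_shift, size=n_features)
                      for g in sorted(groups.unique())}
            Y = Y + np.vstack([gshift[groups[s]] for s in samples])
        for si, s in enumerate(samples):
            for fi, f in enumerate(features):
                rows.append((s, groups[s], f, v, Y[si, fi]))
    table = PseudobulkLongTable(
        pd.DataFrame(rows, columns=LONG_COLUMNS),
        params={"synthetic": True, "seed": seed},
    )
    truth = SyntheticTruth(
        planted_pairs=planted,
        effect_size=condition_offset,
        condition=condition,
        batches=groups,
        seed=seed,
        extras={"Z": Z, "condition_factor_index": condition_factor_index,
                "noise_sd": noise_sd},
    )
    return table, truth


def sample_metadata_from_truth(truth: SyntheticTruth) -> SampleMetadata:
    """Sample-level metadata table (condition + batch) for a fixture."""
    return SampleMetadata(
        pd.DataFrame({"condition": truth.condition, "batch": truth.batches})
    )
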