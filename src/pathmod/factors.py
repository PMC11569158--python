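"""Multi-group, multi-view factor model over pseudobulk pathway activity.

The pseudobulk long table is reshaped into one samples x features block per
(group, view); features are centered per group per view, and a K-factor
linear model ``Y_gv ~ F_g W_v^T`` is fitted.  Two backends exist:

``builtin_svd``
    Assembles the centered blocks into one samples x (view, feature)
    matrix across groups (missing entries zero-filled after centering) and
    takes the top-K singular triplets; factors are left singular vectors
    scaled by the singular values, weights are the right singular vectors.
``external_mofa``
    Delegates to a MOFA-compatible variational trainer through a narrow
    data-only adapter (matrices in, matrices out); requires ``mofapy2``.

Downstream, factors explaining too little variance are dropped, and the
per-group factor matrices / per-view weight matrices are scaled (division
by the per-column max absolute value, keeping sign) and concatenated into
a single factor matrix (rows = pseudobulk samples) and a single weight
matrix (rows = pathway-cell type pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pseudobulk import PseudobulkLongTable


@dataclass
class FactorModelResult:
    factors: dict[str, pd.DataFrame]  # group -> samples x K
    weights: dict[str, pd.DataFrame]  # view -> features x K
    varexp: pd.DataFrame | None  # columns: factor, group, view, varexp_pct
    K: int
    centering: dict[tuple[str, str], pd.Series]  # (group, view) -> per-feature mean
    backend: str
    factor_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ks = {df.shape[1] for df in self.factors.values()}
        if len(ks) != 1:
            raise ValueError("factor column count differs across groups")
        kw = {df.shape[1] for df in self.weights.values()}
        if kw != ks:
            raise ValueError("weight column count differs from factor column count")
        if not self.factor_labels:
            self.factor_labels = list(next(iter(self.factors.values())).columns)

    @property
    def groups(self) -> list[str]:
        return list(self.factors)

    @property
    def views(self) -> list[str]:
        return list(self.weights)


@dataclass
class FactorMatrix:
    """Concatenated per-group factor matrix, scaled per factor per group."""

    table: pd.DataFrame  # index: sample; columns: factor labels; plus .group
    group: pd.Series

    def factor_columns(self) -> list[str]:
        return list(self.table.columns)


@dataclass
class WeightMatrix:
    """Concatenated per-view weight matrix; rows are (pathway, view) pairs."""

    table: pd.DataFrame  # MultiIndex (feature, view) x factor labels

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate (pathway, view) row identifiers")


def _blocks_from_table(
    table: PseudobulkLongTable,
) -> tuple[dict[tuple[str, str], pd.DataFrame], list[str], list[str], dict[str, list[str]]]:
    df = table.table
    groups = sorted(df["group"].astype(str).unique())
    views = sorted(df["view"].astype(str).unique())
    blocks: dict[tuple[str, str], pd.DataFrame] = {}
    group_samples: dict[str, list[str]] = {}
    for g in groups:
        sub = df[df["group"].astype(str) == g]
        group_samples[g] = sorted(sub["sample"].astype(str).unique())
        for v in views:
            sv = sub[sub["view"].astype(str) == v]
            if sv.empty:
                raise ValueError(
                    f"view {v!r} entirely missing in group {g!r}; "
                    "pseudobulk QC contract violated"
                )
            blocks[(g, v)] = sv.pivot(index="sample", columns="feature", values="value")
    return blocks, groups, views, group_samples


def train_factor_model(
    table: PseudobulkLongTable,
    K: int = 10,
    backend: str = "builtin_svd",
) -> FactorModelResult:
    """Fit the multi-group/multi-view factor model.

    Features are centered per group per view (missing entries excluded from
    the means) before fitting.  ``K`` must not exceed the feasible rank of
    the assembled matrix.
    """
    blocks, groups, views, group_samples = _blocks_from_table(table)
    features_per_view = {
        v: sorted(
            set().union(*(blocks[(g, v)].columns for g in groups))
        )
        for v in views
    }
    n_samples = sum(len(s) for s in group_samples.values())
    n_featpairs = sum(len(f) for f in features_per_view.values())
    if K < 1 or K > min(n_samples - 1, n_featpairs):
        raise ValueError(
            f"K={K} infeasible for {n_samples} samples x {n_featpairs} feature pairs"
        )

    centering: dict[tuple[str, str], pd.Series] = {}
    centered: dict[tuple[str, str], pd.DataFrame] = {}
    for (g, v), blk in blocks.items():
        blk = blk.reindex(index=group_samples[g], columns=features_per_view[v])
        mu = blk.mean(axis=0, skipna=True)
        centering[(g, v)] = mu
        centered[(g, v)] = blk - mu

    if backend == "builtin_svd":
        factors, weights = _fit_builtin_svd(
            centered, groups, views, group_samples, features_per_view, K
        )
    elif backend == "external_mofa":
        factors, weights = _fit_external_mofa(
            centered, groups, views, group_samples, features_per_view, K
        )
    else:
        raise ValueError(f"unknown backend {backend!r}")

    labels = [f"factor_{k + 1}" for k in range(K)]
    result = FactorModelResult(
        factors={
            g: pd.DataFrame(factors[g], index=group_samples[g], columns=labels)
            for g in groups
        },
        weights={
            v: pd.DataFrame(weights[v], index=features_per_view[v], columns=labels)
            for v in views
        },
        varexp=None,
        K=K,
        centering=centering,
        backend=backend,
        factor_labels=labels,
    )
    result.varexp = variance_explained(result, table)
    return result


def _fit_builtin_svd(centered, groups, views, group_samples, features_per_view, K):
    rows = []
    for g in groups:
        row_blocks = [centered[(g, v)].to_numpy() for v in views]
        rows.append(np.hstack(row_blocks))
    Y = np.vstack(rows)
    Y = np.nan_to_num(Y, nan=0.0)  # missing entries: zero after centering
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    F = U * s
    factors = {}
    r0 = 0
    for g in groups:
        n = len(group_samples[g])
        factors[g] = F[r0 : r0 + n]
        r0 += n
    weights = {}
    c0 = 0
    for v in views:
        p = len(features_per_view[v])
        weights[v] = Vt[:, c0 : c0 + p].T
        c0 += p
    return factors, weights


def _fit_external_mofa(centered, groups, views, group_samples, features_per_view, K):
    """Adapter to a MOFA-compatible variational trainer (pure data contract)."""
    try:
        from mofapy2.run.entry_point import entry_point
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "backend 'external_mofa' requires the mofapy2 package; "
            "use backend='builtin_svd' otherwise"
        ) from exc
    data = [
        [centered[(g, v)].to_numpy() for v in views] for g in groups
    ]
    ep = entry_point()
    ep.set_data_options(scale_groups=False, scale_views=False)
    ep.set_data_matrix(
        data,
        groups_names=list(groups),
        views_names=list(views),
        samples_names=[group_samples[g] for g in groups],
        features_names=[features_per_view[v] for v in views],
    )
    ep.set_model_options(factors=K)
    ep.set_train_options(verbose=False)
    ep.build()
    ep.run()
    model = ep.model
    expectations = model.getExpectations()
    factors = {
        g: np.asarray(expectations["Z"]["E"][i]) for i, g in enumerate(groups)
    }
    weights = {
        v: np.asarray(expectations["W"]["E"][i]) for i, v in enumerate(views)
    }
    return factors, weights


def variance_explained(
    result: FactorModelResult, table: PseudobulkLongTable
) -> pd.DataFrame:
    """Percent of each (group, view) block's variance explained per factor.

    For factor k: ``100 * (1 - SS(Y_gv - f_k w_k^T) / SS(Y_gv))`` on the
    centered data, with missing entries excluded from both sums.  Blocks
    with zero total sum of squares report 0 with a warning.
    """
    blocks, groups, views, group_samples = _blocks_from_table(table)
    rows = []
    for g in groups:
        F = result.factors[g]
        for v in views:
            feats = list(result.weights[v].index)
            blk = blocks[(g, v)].reindex(
                index=list(F.index), columns=feats
            )
            Y = blk.to_numpy() - result.centering[(g, v)].reindex(feats).to_numpy()
            mask = ~np.isnan(Y)
            ss_tot = np.nansum(Y**2)
            W = result.weights[v].to_numpy()
            Fm = F.to_numpy()
            for k, label in enumerate(result.factor_labels):
                recon = np.outer(Fm[:, k], W[:, k])
                resid = np.where(mask, Y - recon, 0.0)
                if ss_tot == 0:
                    warnings.warn(
                        f"zero total variance in block ({g!r}, {v!r})"
                    )
                    pct = 0.0
                else:
                    pct = 100.0 * (1.0 - np.sum(resid**2) / ss_tot)
                rows.append(
                    {"factor": label, "group": g, "view": v, "varexp_pct": pct}
                )
    return pd.DataFrame(rows)


def filter_factors(
    result: FactorModelResult, min_varexp_percent: float = 1.0
) -> FactorModelResult:
    """Drop factors that explain too little variance.

    A factor is retained iff its variance explained, summed over views,
    reaches ``min_varexp_percent`` in at least one group.  Order and
    original factor labels are preserved.
    """
    if result.varexp is None:
        raise ValueError("variance_explained has not been computed")
    per_group = (
        result.varexp.groupby(["factor", "group"], sort=False)["varexp_pct"]
        .sum()
        .reset_index()
    )
    best = per_group.groupby("factor", sort=False)["varexp_pct"].max()
    retained = [lab for lab in result.factor_labels if best.get(lab, 0.0) >= min_varexp_percent]
    if not retained:
        raise ValueError("all factors fell below the variance-explained threshold")
    return replace(
        result,
        factors={g: df[retained] for g, df in result.factors.items()},
        weights={v: df[retained] for v, df in result.weights.items()},
        varexp=result.varexp[result.varexp["factor"].isin(retained)].reset_index(
            drop=True
        ),
        K=len(retained),
        factor_labels=retained,
    )


def _scale_max_abs(df: pd.DataFrame) -> pd.DataFrame:
    scale = df.abs().max(axis=0)
    scale = scale.replace(0.0, 1.0)  # identically-zero columns stay zero
    return df / scale


def integrate_factors(result: FactorModelResult) -> FactorMatrix:
    """Scale per factor per group by max |value| and stack groups row-wise."""
    if not result.factor_labels:
        raise ValueError("no retained factors")
    parts, glabels = [], []
    for g in result.groups:
        scaled = _scale_max_abs(result.factors[g])
        parts.append(scaled)
        glabels.extend([g] * len(scaled))
    table = pd.concat(parts, axis=0)
    return FactorMatrix(table=table, group=pd.Series(glabels, index=table.index))


def integrate_weights(result: FactorModelResult) -> WeightMatrix:
    """Scale per factor per view by max |value| and stack views row-wise."""
    if not result.factor_labels:
        raise ValueError("no retained factors")
    parts = []
    for v in result.views:
        scaled = _scale_max_abs(result.weights[v])
        scaled = scaled.copy()
        scaled.index = pd.MultiIndex.from_arrays(
            [scaled.index, [v] * len(scaled)], names=["feature", "view"]
        )
        parts.append(scaled)
    return WeightMatrix(table=pd.concat(parts, axis=0))


def save_model(result: FactorModelResult, outdir: str) -> None:
    """Serialize factors/weights/varexp as a CSV directory bundle."""
    import json
    import os

    os.makedirs(outdir, exist_ok=True)
    fm = integrate_factors(result)
    out = fm.table.copy()
    out.insert(0, "group", fm.group.to_numpy())
    out.to_csv(os.path.join(outdir, "factors.csv"))
    integrate_weights(result).table.to_csv(os.path.join(outdir, "weights.csv"))
    result.varexp.to_csv(os.path.join(outdir, "varexp.csv"), index=False)
    with open(os.path.join(outdir, "params.json"), "w") as fh:
        json.dump(
            {
                "K": result.K,
                "backend": result.backend,
                "factor_labels": result.factor_labels,
            },
            fh,
            indent=2,
        )
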