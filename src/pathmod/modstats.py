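"""Identification and interpretation of condition-related factor modules.

A factor whose values separate clinical conditions across pseudobulk
samples is read as a disease-related multicellular pathway module.  The
test is auto-selected from the number of condition levels: two levels use
a two-sided Mann-Whitney U test (nonparametric) or t-test (parametric);
more than two use Kruskal-Wallis or one-way ANOVA.  P-values are adjusted
by Benjamini-Hochberg across the retained factors.  Continuous traits are
handled by per-factor Spearman (default) or Pearson correlation, again
with BH across factors.

Interpretation helpers rank (pathway, cell type) pairs by factor weight
and combine several factors' weights into a cell type x pathway matrix by
the maximum absolute weight, filtered to the union of each cell type's
top pathways and ordered by mean combined weight.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import SampleMetadata
from .factors import FactorMatrix, WeightMatrix

ALPHA = 0.05


def _bh(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def _split_by_level(
    values: np.ndarray, labels: np.ndarray
) -> tuple[list[str], list[np.ndarray]]:
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("condition must have >= 2 observed levels")
    groups = [values[labels == lev] for lev in levels]
    for lev, g in zip(levels, groups):
        if g.size < 2:
            raise ValueError(f"condition level {lev!r} has fewer than 2 samples")
    return levels, groups


def test_category(
    factors: FactorMatrix,
    samples: SampleMetadata,
    condition: str,
    mode: str = "nonparametric",
) -> pd.DataFrame:
    """Test every retained factor against a categorical condition.

    Returns one row per factor with columns ``test``, ``statistic``,
    ``p_value``, ``adj_p_value``, ``significant`` and ``group_sizes``;
    rows are ordered by factor label and the BH family is the set of
    retained factors.
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown mode {mode!r}")
    cond = samples.condition(condition)
    missing = set(map(str, factors.table.index)) - set(map(str, cond.index))
    if missing:
        raise ValueError(f"samples without condition label: {sorted(missing)[:5]}")
    labels = cond.loc[list(factors.table.index)].astype(str).to_numpy()

    rows = []
    for lab in factors.factor_columns():
        vals = factors.table[lab].to_numpy(dtype=np.float64)
        levels, groups = _split_by_level(vals, labels)
        two = len(levels) == 2
        if np.all(vals == vals[0]):
            # constant factor: no separation by construction
            test_name = ("mwu" if two else "kw") if mode == "nonparametric" else (
                "t" if two else "anova"
            )
            stat, p = 0.0, 1.0
        elif mode == "nonparametric":
            if two:
                test_name = "mwu"
                stat, p = stats.mannwhitneyu(
                    groups[0], groups[1], alternative="two-sided", method="auto"
                )
            else:
                test_name = "kw"
                stat, p = stats.kruskal(*groups)
        else:
            if two:
                test_name = "t"
                stat, p = stats.ttest_ind(groups[0], groups[1])
                if np.isnan(p):  # zero variance in both groups
                    stat, p = 0.0, 1.0
            else:
                test_name = "anova"
                stat, p = stats.f_oneway(*groups)
                if np.isnan(p):
                    stat, p = 0.0, 1.0
        rows.append(
            {
                "factor": lab,
                "test": test_name,
                "statistic": float(stat),
                "p_value": float(p),
                "group_sizes": {lev: int(g.size) for lev, g in zip(levels, groups)},
            }
        )
    out = pd.DataFrame(rows).set_index("factor")
    out["adj_p_value"] = _bh(out["p_value"].to_numpy())
    out["significant"] = out["adj_p_value"] < ALPHA
    return out


test_category.__test__ = False  # keep pytest from collecting the API function


def correlate_continuous(
    factors: FactorMatrix,
    samples: SampleMetadata,
    trait: str,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlate every factor with a numeric trait; BH across factors."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    tr = pd.to_numeric(samples.condition(trait), errors="coerce")
    tr = tr.loc[list(factors.table.index)]
    ok = tr.notna().to_numpy()
    if ok.sum() < 3:
        raise ValueError("trait must have >= 3 non-missing values")
    t = tr.to_numpy(dtype=np.float64)[ok]
    if np.all(t == t[0]):
        raise ValueError("trait has zero variance")
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for lab in factors.factor_columns():
        v = factors.table[lab].to_numpy(dtype=np.float64)[ok]
        res = fn(v, t)
        rows.append(
            {"factor": lab, "coefficient": float(res[0]), "p_value": float(res[1])}
        )
    out = pd.DataFrame(rows).set_index("factor")
    out["adj_p_value"] = _bh(out["p_value"].to_numpy())
    return out


def top_weight_pairs(
    weights: WeightMatrix, factor: str, k: int, direction: str = "absolute"
) -> pd.DataFrame:
    """Rank (pathway, view) pairs by a factor's weight.

    ``direction`` selects descending signed weight (``positive``),
    ascending signed weight (``negative``) or descending magnitude
    (``absolute``).  Ties break by (pathway, view) lexicographic order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if factor not in weights.table.columns:
        raise KeyError(f"factor {factor!r} not retained")
    df = weights.table[[factor]].rename(columns={factor: "weight"}).reset_index()
    if direction == "positive":
        key, ascending = df["weight"], False
    elif direction == "negative":
        key, ascending = df["weight"], True
    elif direction == "absolute":
        key, ascending = df["weight"].abs(), False
    else:
        raise ValueError(f"unknown direction {direction!r}")
    df = df.assign(_key=key).sort_values(
        ["_key", "feature", "view"],
        ascending=[ascending, True, True],
        kind="mergesort",
    ).drop(columns="_key")
    if k > len(df):
        warnings.warn(f"k={k} exceeds the {len(df)} available pairs; returning all")
        k = len(df)
    return df.head(k).reset_index(drop=True)[["feature", "view", "weight"]]


@dataclass
class CombinedWeightMatrix:
    """Views x pathways abs-max combined weights over selected factors."""

    table: pd.DataFrame  # rows: views, columns: pathways (mean-descending)
    factors: list[str]
    top_n: int

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("combined weights must be nonnegative")


def combine_factor_weights(
    weights: WeightMatrix, factor_subset: list[str], top_n: int = 3
) -> CombinedWeightMatrix:
    """Combine factors into one cell type x pathway weight matrix.

    The combined weight of (view, pathway) is the maximum absolute scaled
    weight over ``factor_subset``.  The matrix is filtered to the union of
    every view's ``top_n`` highest-weighted pathways, and its columns are
    sorted in descending order of mean combined weight across views.
    """
    if not factor_subset:
        raise ValueError("factor_subset is empty")
    for f in factor_subset:
        if f not in weights.table.columns:
            raise KeyError(f"factor {f!r} not retained")
    combined = weights.table[factor_subset].abs().max(axis=1).rename("weight")
    wide = combined.reset_index().pivot(index="view", columns="feature", values="weight")
    union: set[str] = set()
    for _, row in wide.iterrows():
        # deterministic: sort by (-weight, pathway name)
        ranked = sorted(row.dropna().items(), key=lambda kv: (-kv[1], kv[0]))
        union.update(name for name, _ in ranked[:top_n])
    if not union:
        raise ValueError("empty top-pathway union")
    wide = wide[sorted(union)]
    order = wide.mean(axis=0, skipna=True).sort_values(
        ascending=False, kind="mergesort"
    )
    wide = wide[order.index]
    return CombinedWeightMatrix(table=wide, factors=list(factor_subset), top_n=top_n)
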