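"""Pseudobulk aggregation of cell-level pathway activity scores.

Cell-level scores are averaged per (sample, cell type) into a long-format
table with exactly five columns — sample, group, feature, view, value —
where features are pathways and views are cell types.  Quality control
drops (sample, cell type) pairs backed by too few cells and cell types
observed in too few samples; the multi-group variant additionally requires
every retained view to be well covered within every batch group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CellMetadata
from .ucell import PASMatrix

LONG_COLUMNS = ["sample", "group", "feature", "view", "value"]


@dataclass
class PseudobulkLongTable:
    """5-column long table of mean PAS per sample x cell type, plus QC report."""

    table: pd.DataFrame
    params: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.table.columns) != LONG_COLUMNS:
            raise ValueError(f"long table columns must be exactly {LONG_COLUMNS}")
        key = self.table[["sample", "group", "feature", "view"]]
        if key.duplicated().any():
            raise ValueError("duplicate (sample, group, feature, view) rows")

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "PseudobulkLongTable":
        return cls(pd.read_csv(path))


def _cell_table(pas: PASMatrix, meta: CellMetadata) -> pd.DataFrame:
    m = meta.aligned_to(pas.cell_ids)
    df = pas.to_frame()
    df = df.assign(_sample=m["sample_id"].to_numpy(), _view=m["cell_type"].to_numpy())
    return df


def _mean_long(df: pd.DataFrame, min_cells: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean PAS and cell counts per (sample, view); drop pairs below min_cells."""
    grouped = df.groupby(["_sample", "_view"], sort=True, observed=True)
    counts = grouped.size().rename("n_cells")
    means = grouped.mean()
    keep = counts >= min_cells
    return means[keep.to_numpy()], counts.to_frame()


def aggregate_single_group(
    pas: PASMatrix,
    meta: CellMetadata,
    min_cells: int = 10,
    min_samples_per_view: int = 1,
    group_label: str = "single_group",
) -> PseudobulkLongTable:
    """Single-group pseudobulk: one constant group label for all rows.

    A (sample, cell type) pair is kept only when it is backed by at least
    ``min_cells`` cells; a cell type (view) is kept only when it survives
    in at least ``min_samples_per_view`` pseudobulk samples.
    """
    df = _cell_table(pas, meta)
    means, counts = _mean_long(df, min_cells)
    dropped_pairs = [
        t for t in counts.index[counts["n_cells"] < min_cells].tolist()
    ]
    view_counts = means.index.get_level_values("_view").value_counts()
    kept_views = view_counts[view_counts >= min_samples_per_view].index
    dropped_views = sorted(set(view_counts.index) - set(kept_views))
    means = means[means.index.get_level_values("_view").isin(kept_views)]
    dropped = {"pairs_below_min_cells": dropped_pairs, "views": dropped_views}
    if means.empty:
        raise ValueError(f"pseudobulk table empty after filtering; dropped={dropped}")
    long = (
        means.reset_index()
        .melt(id_vars=["_sample", "_view"], var_name="feature", value_name="value")
        .rename(columns={"_sample": "sample", "_view": "view"})
        .assign(group=group_label)
    )[LONG_COLUMNS]
    long = long.sort_values(["view", "feature", "sample"], kind="mergesort").reset_index(
        drop=True
    )
    return PseudobulkLongTable(
        long,
        params={"min_cells": min_cells, "min_samples_per_view": min_samples_per_view},
        dropped=dropped,
    )


def aggregate_multigroup(
    pas: PASMatrix,
    meta: CellMetadata,
    min_cells: int = 10,
    min_fraction: float = 0.75,
    min_samples: int = 15,
) -> PseudobulkLongTable:
    """Multi-group pseudobulk: batch becomes the group column.

    Within EVERY group, a view is retained only if it appears in strictly
    more than ``min_fraction`` of that group's pseudobulk samples AND in at
    least ``min_samples`` of them; a view failing either rule in any group
    is dropped from all groups.  Cells with missing batch are an error, as
    are samples spanning more than one batch.
    """
    if not meta.has_batch:
        raise ValueError("multigroup aggregation requires a 'batch' metadata column")
    m = meta.aligned_to(pas.cell_ids)
    if m["batch"].isna().any():
        raise ValueError("cells with missing batch label")
    sample_batch = m.groupby("sample_id")["batch"].unique()
    bad = sample_batch[sample_batch.map(len) > 1]
    if len(bad):
        raise ValueError(f"samples span multiple batches: {list(bad.index)[:5]}")
    sample_to_group = sample_batch.map(lambda a: a[0])

    df = _cell_table(pas, meta)
    means, _ = _mean_long(df, min_cells)
    long = (
        means.reset_index()
        .melt(id_vars=["_sample", "_view"], var_name="feature", value_name="value")
        .rename(columns={"_sample": "sample", "_view": "view"})
    )
    long["group"] = long["sample"].map(sample_to_group).astype(str)

    pair = long[["sample", "group", "view"]].drop_duplicates()
    group_sizes = pair.groupby("group")["sample"].nunique()
    per = pair.groupby(["group", "view"])["sample"].nunique().rename("n").reset_index()
    per["group_size"] = per["group"].map(group_sizes)
    per["ok"] = (per["n"] > min_fraction * per["group_size"]) & (per["n"] >= min_samples)
    groups = sorted(group_sizes.index)
    ok_views = []
    for view, sub in per.groupby("view"):
        present = set(sub["group"])
        if present == set(groups) and sub["ok"].all():
            ok_views.append(view)
    dropped_views = sorted(set(per["view"]) - set(ok_views))
    long = long[long["view"].isin(ok_views)]
    for g in groups:
        if not (long["group"] == g).any():
            raise ValueError(f"group {g!r} has no pseudobulk samples after filtering")
    if long.empty:
        raise ValueError("pseudobulk table empty after multigroup filtering")
    long = long[LONG_COLUMNS].sort_values(
        ["group", "view", "feature", "sample"], kind="mergesort"
    ).reset_index(drop=True)
    return PseudobulkLongTable(
        long,
        params={
            "min_cells": min_cells,
            "min_fraction": min_fraction,
            "min_samples": min_samples,
        },
        dropped={"views": dropped_views},
    )
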