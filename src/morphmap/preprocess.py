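"""Profile processing: aggregation, robust normalization, feature selection.

The recipe mirrors the standard image-based-profiling workflow: median
aggregation of single-cell features to one profile per well, per-plate
robust scaling against a reference population (negative-control wells
or all wells), redundancy pruning at |Pearson r| > 0.9, and removal of
near-zero-variance features.  An optional well-position mean-centering
step corrects plate-layout artifacts; it is off by default.

The median absolute deviation used here is raw (no 1.4826 normal-
consistency constant), following the cytominer convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .profiles import ControlType, ProfileTable, SingleCellTable

logger = logging.getLogger(__name__)

Reference = Literal["negcon", "all_wells"]


@dataclass
class NormalizationStats:
    """Per-plate, per-feature robust location/scale of the reference wells."""

    reference: str
    median: pd.DataFrame  # index: plate, columns: features
    mad: pd.DataFrame  # raw m.a.d., same shape

    def __post_init__(self) -> None:
        if (self.mad.to_numpy() < 0).any():
            raise ValueError("m.a.d. must be non-negative")


def aggregate_median(cells: SingleCellTable) -> ProfileTable:
    """Collapse single-cell rows to one median profile per well.

    Metadata columns other than the cell identifier must be constant
    within a well and are carried through.
    """
    keys = ["Metadata_Plate", "Metadata_Well"]
    df = cells.data
    feats = cells.feature_names
    grouped = df.groupby(keys, sort=True)
    medians = grouped[feats].median()
    meta_cols = [
        c for c in cells.metadata_columns if c not in keys and c != "Metadata_cell_id"
    ]
    meta = grouped[meta_cols].first() if meta_cols else None
    out = medians.reset_index() if meta is None else meta.join(medians).reset_index()
    out = out.loc[:, keys + meta_cols + feats]
    return ProfileTable(out) if set(ProfileTable.required_metadata) <= set(out.columns) \
        else _as_bare_table(out)


def _as_bare_table(df: pd.DataFrame) -> ProfileTable:
    """Wrap a frame lacking some canonical metadata as a plain table."""

    class _BareTable(ProfileTable):
        required_metadata = ("Metadata_Plate", "Metadata_Well")

    return _BareTable(df)


def compute_normalization_stats(
    table: ProfileTable, reference: Reference = "negcon"
) -> NormalizationStats:
    """Median and raw m.a.d. of the reference wells, per plate per feature."""
    df = table.data
    if reference == "negcon":
        ref = df[df["Metadata_control_type"] == ControlType.NEGCON.value]
        empty = set(df["Metadata_Plate"].unique()) - set(ref["Metadata_Plate"].unique())
        if empty:
            raise ValueError(
                f"no negative-control wells on plate(s): {sorted(map(str, empty))}"
            )
    elif reference == "all_wells":
        ref = df
    else:
        raise ValueError(f"unknown reference {reference!r}")
    feats = table.feature_names
    grouped = ref.groupby("Metadata_Plate", sort=True)[feats]
    median = grouped.median()
    mad = grouped.apply(lambda g: (g - g.median()).abs().median())
    return NormalizationStats(reference=reference, median=median, mad=mad)


def normalize(table: ProfileTable, reference: Reference = "negcon") -> ProfileTable:
    """Robust-scale each feature per plate: (x - median) / m.a.d.

    Features whose reference m.a.d. is zero on any plate are dropped
    table-wide (they carry no usable scale) and logged.
    """
    stats = compute_normalization_stats(table, reference)
    zero_mad = stats.mad.columns[(stats.mad <= 0).any(axis=0)].tolist()
    if zero_mad:
        logger.warning(
            "dropping %d feature(s) with zero reference m.a.d.: %s",
            len(zero_mad),
            zero_mad,
        )
    keep = [f for f in table.feature_names if f not in set(zero_mad)]
    if not keep:
        raise ValueError("no features left after dropping zero-m.a.d. features")
    plates = table.data["Metadata_Plate"].to_numpy()
    med = stats.median.loc[plates, keep].to_numpy()
    mad = stats.mad.loc[plates, keep].to_numpy()
    values = (table.data[keep].to_numpy(dtype=float) - med) / mad
    return table.with_features(values, keep)


def _near_zero_variance(
    values: np.ndarray,
    names: list[str],
    variance_threshold: float,
    freq_cut: float,
    unique_cut: int,
) -> list[str]:
    """Features that are (nearly) constant across all wells of all plates.

    caret-style rule: variance below ``variance_threshold``, or the most
    frequent value occupying more than ``freq_cut`` of wells while fewer
    than ``unique_cut`` distinct values occur.
    """
    drop = []
    n = values.shape[0]
    for j, name in enumerate(names):
        col = values[:, j]
        if np.var(col) < variance_threshold:
            drop.append(name)
            continue
        uniques, counts = np.unique(col, return_counts=True)
        if len(uniques) < unique_cut and counts.max() / n > freq_cut:
            drop.append(name)
    return drop


def select_features(
    table: ProfileTable,
    corr_threshold: float = 0.9,
    variance_threshold: float = 1e-10,
    freq_cut: float = 0.95,
    unique_cut: int = 10,
) -> ProfileTable:
    """Drop near-zero-variance features, then prune correlated pairs.

    Pruning is iterative: while some pair exceeds ``corr_threshold`` in
    |Pearson r|, the feature with the highest mean absolute correlation
    to the other retained features is removed; ties break toward the
    lexicographically later name.  The retained set is therefore
    independent of the input column order.
    """
    if table.n_wells < 2:
        raise ValueError("feature selection requires at least 2 wells")
    names = table.feature_names
    values = table.features
    nzv = _near_zero_variance(values, names, variance_threshold, freq_cut, unique_cut)
    if nzv:
        logger.info("near-zero-variance features removed: %s", nzv)
    keep = [f for f in names if f not in set(nzv)]

    while True:
        if len(keep) < 2:
            raise ValueError(
                "fewer than 2 features remain after selection; downstream "
                "cosine similarity is undefined"
            )
        idx = [names.index(f) for f in keep]
        corr = np.corrcoef(values[:, idx], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        abs_corr = np.abs(corr)
        violating = np.flatnonzero((abs_corr > corr_threshold).any(axis=0))
        if violating.size == 0:
            break
        mean_abs = abs_corr.mean(axis=0)
        # candidates: features in a violating pair; pick worst offender
        best = max(
            violating, key=lambda j: (mean_abs[j], keep[j])
        )
        removed = keep[int(best)]
        logger.info("correlation pruning removed %s", removed)
        keep.remove(removed)
    keep_sorted = [f for f in names if f in set(keep)]
    idx = [names.index(f) for f in keep_sorted]
    return table.with_features(values[:, idx], keep_sorted)


def center_by_well_position(table: ProfileTable) -> ProfileTable:
    """Subtract the cross-plate mean at each well position, per feature.

    Corrects plate-layout artifacts by removing whatever is common to a
    well address across plates.  Requires at least two plates; off by
    default in the processing recipe.
    """
    if table.data["Metadata_Plate"].nunique() < 2:
        raise ValueError("well-position centering requires at least 2 plates")
    feats = table.feature_names
    df = table.data
    centered = df[feats] - df.groupby("Metadata_Well")[feats].transform("mean")
    return table.with_features(centered.to_numpy(), feats)
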