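"""Tabular assay quantifications: proliferation indices from per-cell marker
tables and spheroid migration ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ProliferationResult", "proliferation_index", "migration_ratio"]


@dataclass
class ProliferationResult:
    """Proliferation indices (percent) at several aggregation levels.

    ``pooled_percent`` is 100 * (sum of numerators) / (sum of denominators)
    over all retained fields; ``field_mean_percent`` is the unweighted mean of
    the per-field percentages. Both are reported because field-sampled counts
    are commonly averaged per field. ``group_means`` averages per-field
    percentages within each group (animal/well).
    """

    per_field: pd.DataFrame
    pooled_percent: float
    field_mean_percent: float
    group_means: pd.Series


def proliferation_index(
    table: pd.DataFrame,
    numerator=("EdU",),
    denominator: str = "DAPI",
) -> ProliferationResult:
    """Percent of denominator-positive cells that are positive for every
    numerator marker, per field and pooled.

    ``table`` has one row per cell with boolean marker columns plus
    ``field_id`` and (optionally) ``group_id``. Fields with a zero
    denominator count are excluded with a warning; if every field is
    excluded an error is raised.
    """
    numerator = [numerator] if isinstance(numerator, str) else list(numerator)
    for col in [*numerator, denominator, "field_id"]:
        if col not in table.columns:
            raise ValueError(f"cell table lacks column {col!r}")
    den_mask = table[denominator].astype(bool)
    num_mask = den_mask.copy()
    for col in numerator:
        num_mask &= table[col].astype(bool)

    group_col = table["group_id"] if "group_id" in table.columns else "all"
    df = pd.DataFrame(
        {"field_id": table["field_id"], "group_id": group_col,
         "den": den_mask, "num": num_mask}
    )
    per_field = (
        df.groupby(["group_id", "field_id"], sort=True)
        .agg(n_denominator=("den", "sum"), n_numerator=("num", "sum"))
        .reset_index()
    )
    empty = per_field["n_denominator"] == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} field(s) excluded: zero {denominator}-positive cells"
        )
        per_field = per_field[~empty]
    if per_field.empty:
        raise ValueError("every field excluded: no denominator-positive cells")
    per_field = per_field.copy()
    per_field["percent"] = 100.0 * per_field["n_numerator"] / per_field["n_denominator"]
    pooled = 100.0 * per_field["n_numerator"].sum() / per_field["n_denominator"].sum()
    return ProliferationResult(
        per_field=per_field,
        pooled_percent=float(pooled),
        field_mean_percent=float(per_field["percent"].mean()),
        group_means=per_field.groupby("group_id")["percent"].mean(),
    )


def migration_ratio(measurements: pd.DataFrame):
    """Spheroid invasion ratios normalized to each well's time-zero diameter.

    ``measurements`` has columns ``well_id``, ``time_h``, ``invasive_diameter``
    (and optionally ``group_id``). Returns ``(per_well, group_mean)`` where
    ``per_well`` adds a ``ratio`` column and ``group_mean`` is the mean ratio
    per (group, time point).
    """
    for col in ("well_id", "time_h", "invasive_diameter"):
        if col not in measurements.columns:
            raise ValueError(f"measurement table lacks column {col!r}")
    if (measurements["invasive_diameter"] <= 0).any():
        raise ValueError("diameters must be positive")
    df = measurements.copy()
    if "group_id" not in df.columns:
        df["group_id"] = "all"
    t0 = df[df["time_h"] == 0].set_index("well_id")["invasive_diameter"]
    missing = sorted(set(df["well_id"]) - set(t0.index))
    if missing:
        raise ValueError(f"wells without a time-0 diameter: {missing}")
    if t0.index.has_duplicates:
        dupes = sorted(t0.index[t0.index.duplicated()].unique())
        raise ValueError(f"wells with duplicate time-0 records: {dupes}")
    df["ratio"] = df["invasive_diameter"].to_numpy() / t0.reindex(df["well_id"]).to_numpy()
    group_mean = (
        df.groupby(["group_id", "time_h"], sort=True)["ratio"].mean().rename("mean_ratio")
    )
    return df, group_mean
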