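"""Turn raw census-style counts into per-area metric proportions.

The census table has one row per small area (LSOA-like unit) with an area
ID, a population and household base, the polygon area in km2, and one
numerator column per registry metric.  Indicators are simple quotients:
numerator / base for proportions, residents / km2 for population density.
Missingness (zero or missing denominators) is preserved as NaN and summed
up by :func:`summarise_missingness`; downstream aggregation renormalises
weights over the non-missing metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .registry import MetricRegistry

__all__ = ["compute_indicators", "summarise_missingness", "AREA_ID"]

AREA_ID = "area_id"

# numerators may exceed denominators by at most this relative amount before
# the row is treated as corrupt rather than rounding noise
_REL_TOL = 1e-9


def compute_indicators(
    census_counts: pd.DataFrame,
    registry: MetricRegistry,
    include_separate: bool = True,
) -> pd.DataFrame:
    """Per-area metric values: one row per area, one column per metric_id.

    Proportion metrics are numerator/denominator in [0, 1]; rate metrics
    (population density) are left unbounded.  A zero denominator yields a
    missing value and the area is retained.

    Raises
    ------
    SchemaError
        If a referenced column or the area ID column is absent, or area IDs
        repeat.
    DataError
        If a numerator exceeds its denominator beyond floating tolerance.
    """
    if AREA_ID not in census_counts.columns:
        raise SchemaError(f"census table lacks required column {AREA_ID!r}")
    if census_counts[AREA_ID].duplicated().any():
        dupes = census_counts[AREA_ID][census_counts[AREA_ID].duplicated()].tolist()
        raise SchemaError(f"duplicate area IDs in census table: {dupes[:5]}")
    if len(census_counts) == 0:
        raise SchemaError("census table has no areas")

    metrics = list(registry.metrics) + (list(registry.separate_metrics) if include_separate else [])
    needed = {f for m in metrics for f in (m.numerator_field, m.denominator_field)}
    missing_cols = sorted(needed - set(census_counts.columns))
    if missing_cols:
        raise SchemaError(f"census table lacks required columns: {missing_cols}")

    out = pd.DataFrame({AREA_ID: census_counts[AREA_ID].to_numpy()})
    for m in metrics:
        num = census_counts[m.numerator_field].astype(float).to_numpy()
        den = census_counts[m.denominator_field].astype(float).to_numpy()
        if m.is_proportion:
            excess = num > den * (1.0 + _REL_TOL)
            excess &= ~(np.isnan(num) | np.isnan(den))
            excess &= den > 0  # zero-base rows become missing, not errors
            if excess.any():
                i = int(np.argmax(excess))
                raise DataError(
                    f"metric {m.metric_id!r}, area "
                    f"{census_counts[AREA_ID].iloc[i]!r}: numerator {num[i]} "
                    f"exceeds denominator {den[i]}"
                )
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where((den > 0) & ~np.isnan(num), num / den, np.nan)
        if m.is_proportion:
            val = np.clip(val, 0.0, 1.0)  # shave float dust only; gross cases raised above
        out[m.metric_id] = val
    return out


def summarise_missingness(table: pd.DataFrame) -> dict:
    """Missing fractions per metric, per area, and overall.

    Returns a dict with keys ``per_metric`` (Series indexed by metric_id),
    ``per_area`` (Series indexed by area_id) and ``overall`` (float).
    """
    if len(table) == 0:
        raise SchemaError("indicator table has no areas")
    values = table.drop(columns=[AREA_ID])
    isna = values.isna()
    return {
        "per_metric": isna.mean(axis=0),
        "per_area": pd.Series(isna.mean(axis=1).to_numpy(), index=table[AREA_ID]),
        "overall": float(isna.to_numpy().mean()),
    }
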