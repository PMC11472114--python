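"""Per-area flood exposure: flooded-building proportions and decile ranks.

An area's exposure is the proportion of its buildings standing in water
deeper than the threshold (default 0.10 m, strictly greater) anywhere in
their footprint — buildings are points, so the footprint reduces to the
grid cell the point falls in.  Areas are then ranked into deciles by that
proportion; areas with no buildings carry a missing proportion and are
excluded from ranking but retained in the output.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CRSError, DataError, ParameterError
from .grids import HazardGrid
from .indicators import AREA_ID
from .ranking import decile_rank
from .registry import FloodScenario

__all__ = ["building_depths", "flag_flooded", "area_flood_exposure", "flood_exposure_table"]

log = logging.getLogger(__name__)


def building_depths(grid: HazardGrid, buildings: pd.DataFrame, crs: str | None = None) -> np.ndarray:
    """Flood depth (m) at each building point.

    The depth is the grid value of the cell owning the point under the
    half-open rule.  No-data cells count as dry (depth 0), as flood grids
    conventionally omit dry cells; buildings outside the grid extent also
    get depth 0 and their count is logged.
    """
    if len(buildings) == 0:
        raise ParameterError("building set is empty")
    if crs is not None and crs != grid.crs:
        raise CRSError(f"building CRS {crs!r} != grid CRS {grid.crs!r}")
    vals, inside = grid.sample(buildings["x"].to_numpy(), buildings["y"].to_numpy())
    n_outside = int((~inside).sum())
    if n_outside:
        log.warning("%d buildings fall outside the flood grid; treated as dry", n_outside)
    return np.where(np.isnan(vals), 0.0, vals)


def flag_flooded(depths, threshold: float = 0.10) -> np.ndarray:
    """Boolean flooded flags: depth strictly greater than the threshold.

    A depth of exactly the threshold (10 cm by default) is NOT flooded.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    d = np.asarray(depths, dtype=float)
    if (d < 0).any():
        raise DataError(f"negative flood depth encountered: {d[d < 0][:5]}")
    return d > threshold


def area_flood_exposure(
    flags,
    building_area_ids,
    all_area_ids,
    scenario: FloodScenario | None = None,
) -> pd.DataFrame:
    """Aggregate building flags to per-area proportions and deciles.

    Parameters
    ----------
    flags : boolean array, one per building
    building_area_ids : array of area IDs, one per building
    all_area_ids : every area in the study region (zero-building areas are
        reported with a missing proportion and no decile)
    scenario : attached to the output columns for traceability
    """
    flags = np.asarray(flags, dtype=bool)
    owners = pd.Series(np.asarray(building_area_ids, dtype=object))
    if len(flags) != len(owners):
        raise ParameterError("flags and building_area_ids differ in length")
    known = set(all_area_ids)
    unknown = set(owners) - known
    if unknown:
        raise DataError(f"buildings assigned to unknown areas: {sorted(unknown)[:5]}")
    grouped = pd.DataFrame({AREA_ID: owners, "flooded": flags}).groupby(AREA_ID)
    agg = grouped.agg(n_buildings=("flooded", "size"), n_flooded=("flooded", "sum"))
    out = pd.DataFrame({AREA_ID: list(all_area_ids)}).set_index(AREA_ID)
    out["n_buildings"] = agg["n_buildings"].reindex(out.index).fillna(0).astype(int)
    out["n_flooded"] = agg["n_flooded"].reindex(out.index).fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        out["proportion_flooded"] = np.where(
            out["n_buildings"] > 0, out["n_flooded"] / out["n_buildings"].replace(0, 1), np.nan
        )
    out["flood_decile"] = decile_rank(out["proportion_flooded"])
    if scenario is not None:
        out["return_period_years"] = scenario.return_period_years
        out["climate_pathway"] = scenario.climate_pathway
        out["horizon_year"] = scenario.horizon_year
        out["scenario_role"] = scenario.role
    return out.reset_index()


def flood_exposure_table(
    grid: HazardGrid,
    buildings: pd.DataFrame,
    all_area_ids,
    threshold: float = 0.10,
    scenario: FloodScenario | None = None,
) -> pd.DataFrame:
    """Convenience: depths -> flags -> per-area exposure table in one call."""
    depths = building_depths(grid, buildings)
    flags = flag_flooded(depths, threshold=threshold)
    return area_flood_exposure(flags, buildings[AREA_ID], all_area_ids, scenario=scenario)
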