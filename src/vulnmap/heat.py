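"""Per-area heat exposure, building-density weighted.

Two summer heat metrics are reduced from daily 2-D temperature stacks:

* mean summer daily-maximum temperature (degC) over the configured season
  and years (default June-August 2015-2019);
* the fraction of in-season days whose daily mean strictly exceeds a
  mortality-relevant threshold (default 15 degC).

Cell values are aggregated to areas as a building-count-weighted mean: a
cell contributes with weight equal to the number of the area's buildings
it contains, so the area summary reflects where people actually live.
Areas with no buildings fall back to the unweighted mean over cells
intersecting the area and are flagged.  Both metrics are decile-ranked
independently.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
import xarray as xr

from .errors import CRSError, ParameterError
from .grids import HazardGrid
from .indicators import AREA_ID
from .ranking import decile_rank
from .registry import PipelineConfig

__all__ = [
    "cell_mean_summer_tmax",
    "cell_exceedance_fraction",
    "building_weighted_area_value",
    "heat_exposure_table",
]

log = logging.getLogger(__name__)


def _season_mask(stack: xr.DataArray, config: PipelineConfig) -> xr.DataArray:
    t = stack["time"]
    mask = t.dt.month.isin(sorted(config.season_months)) & t.dt.year.isin(list(config.years))
    sel = stack.sel(time=mask)
    if sel.sizes.get("time", 0) == 0:
        raise ParameterError("temperature stack contains no days in the configured season/years")
    return sel


def _grid_from_dataarray(da: xr.DataArray) -> HazardGrid:
    x = da["x"].to_numpy()
    y = da["y"].to_numpy()
    if len(x) > 1:
        cell = float(x[1] - x[0])
    elif len(y) > 1:
        cell = float(y[1] - y[0])
    else:
        cell = float(da.attrs.get("cell_size", 1.0))
    return HazardGrid(
        values=da.to_numpy(),
        xmin=float(x[0]) - cell / 2,
        ymin=float(y[0]) - cell / 2,
        cell_size=cell,
        crs=str(da.attrs.get("crs", "unknown")),
        metadata=dict(da.attrs),
    )


def cell_mean_summer_tmax(daily_tmax: xr.DataArray, config: PipelineConfig | None = None) -> xr.DataArray:
    """Per-cell mean of daily maxima over all in-season days of all years."""
    config = config or PipelineConfig()
    sel = _season_mask(daily_tmax, config)
    out = sel.mean("time", skipna=True)
    out.attrs = dict(daily_tmax.attrs)
    out.attrs["variable"] = "mean_summer_tmax_c"
    return out


def cell_exceedance_fraction(
    daily_tmean: xr.DataArray,
    threshold: float | None = None,
    config: PipelineConfig | None = None,
) -> xr.DataArray:
    """Per-cell fraction of in-season days with daily mean strictly > threshold.

    A day at exactly the threshold does not count as an exceedance.
    """
    config = config or PipelineConfig()
    if threshold is None:
        threshold = config.heat_exceedance_threshold_c
    sel = _season_mask(daily_tmean, config)
    out = (sel > threshold).mean("time")
    out.attrs = dict(daily_tmean.attrs)
    out.attrs["variable"] = f"exceedance_fraction_gt_{threshold:g}c"
    return out


def building_weighted_area_value(
    cell_values: xr.DataArray | HazardGrid,
    buildings: pd.DataFrame,
    areas: pd.DataFrame,
) -> pd.DataFrame:
    """Building-count-weighted mean of a per-cell field, per area.

    value(a) = sum_c w_ac v_c / sum_c w_ac with w_ac = number of area a's
    buildings in cell c.  Zero-building areas fall back to the unweighted
    mean over cells intersecting the area polygon (``fallback`` column
    True); an area intersecting no cells gets a missing value and is
    logged.

    Returns a DataFrame with columns area_id, value, total_weight, fallback.
    """
    grid = cell_values if isinstance(cell_values, HazardGrid) else _grid_from_dataarray(cell_values)
    if AREA_ID not in areas.columns:
        raise ParameterError(f"areas table lacks {AREA_ID!r}")

    rows, cols, inside = grid.cell_index(buildings["x"].to_numpy(), buildings["y"].to_numpy())
    flat = rows * grid.nx + cols
    bdf = pd.DataFrame({AREA_ID: buildings[AREA_ID].to_numpy(), "cell": flat})[inside]

    vals_flat = grid.values.ravel()
    weighted = (
        bdf.assign(v=vals_flat[bdf["cell"].to_numpy()])
        .groupby(AREA_ID)
        .agg(total_weight=("v", "size"), value=("v", "mean"))
    )

    out = pd.DataFrame({AREA_ID: areas[AREA_ID].to_numpy()}).set_index(AREA_ID)
    out["value"] = weighted["value"].reindex(out.index)
    out["total_weight"] = weighted["total_weight"].reindex(out.index).fillna(0).astype(int)
    out["fallback"] = out["total_weight"] == 0

    if out["fallback"].any() and "geometry" in areas.columns:
        # unweighted mean over cells whose extent intersects the area polygon
        xs, ys = np.meshgrid(grid.x_centers(), grid.y_centers())
        half = grid.cell_size / 2
        boxes = shapely.box(xs.ravel() - half, ys.ravel() - half, xs.ravel() + half, ys.ravel() + half)
        tree = shapely.STRtree(boxes)
        geo = areas.set_index(AREA_ID)["geometry"]
        for aid in out.index[out["fallback"]]:
            hits = tree.query(geo.loc[aid], predicate="intersects")
            if len(hits) == 0:
                log.warning("area %s intersects no temperature cells; value missing", aid)
                continue
            out.loc[aid, "value"] = float(np.nanmean(vals_flat[hits]))
    return out.reset_index()


def heat_exposure_table(
    daily_tmax: xr.DataArray,
    daily_tmean: xr.DataArray,
    buildings: pd.DataFrame,
    areas: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Both heat metrics per area, each decile-ranked independently.

    Columns: area_id, mean_summer_tmax, exceedance_fraction, decile_tmax,
    decile_exceed, total_weight, fallback.
    """
    config = config or PipelineConfig()
    crs_max = str(daily_tmax.attrs.get("crs", "unknown"))
    crs_mean = str(daily_tmean.attrs.get("crs", "unknown"))
    if crs_max != crs_mean:
        raise CRSError(f"tmax CRS {crs_max!r} != tmean CRS {crs_mean!r}")

    tmax_cells = cell_mean_summer_tmax(daily_tmax, config)
    exc_cells = cell_exceedance_fraction(daily_tmean, config=config)

    a = building_weighted_area_value(tmax_cells, buildings, areas)
    b = building_weighted_area_value(exc_cells, buildings, areas)
    out = a.rename(columns={"value": "mean_summer_tmax"})
    out["exceedance_fraction"] = b["value"].to_numpy()
    out["decile_tmax"] = decile_rank(out["mean_summer_tmax"])
    out["decile_exceed"] = decile_rank(out["exceedance_fraction"])
    return out
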