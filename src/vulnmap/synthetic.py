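"""Synthetic study region with planted ground truth.

Everything the pipeline consumes can be generated here: an n x n lattice of
unit-square areas (stand-ins for LSOAs, populations 1,000-3,000), a latent
spatially-smooth vulnerability factor L(a), census-style counts whose
prevalences load on L(a), building point locations, a flood-depth grid
decaying away from a synthetic river channel, and daily summer temperature
grids with an urban-heat-island (UHI) term proportional to building
density.  All planted parameters and per-area truths are recorded in
``SyntheticRegion.truth`` so tests can measure recovery.

Determinism: every generator takes a seed; independent components draw from
independent child streams spawned from it, so regenerating any one product
with the same seed is byte-identical regardless of what else was generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
from shapely.geometry import LineString, Polygon

from .errors import ParameterError, SchemaError
from .grids import DEFAULT_CRS, HazardGrid
from .indicators import AREA_ID
from .registry import FloodScenario, MetricRegistry, PipelineConfig

__all__ = [
    "SyntheticRegion",
    "generate_region",
    "generate_census_counts",
    "generate_flood_depths",
    "generate_daily_temperatures",
]

# default planted-field parameters (one planar unit ~ one grid-square side)
_LATENT_SMOOTH_SIGMA = 1.2   # areas; spatial autocorrelation of L
_MEAN_HOUSEHOLD_SIZE = 2.4
_CHANNEL_X_FRACS = (0.45, 0.55)  # slightly oblique channel, south to north

# flood-field defaults: peak depth (m) at the channel and linear decay per
# unit distance; the typical/disaster pair differ only in peak depth so the
# disaster field dominates cell-wise under a shared noise realisation
FLOOD_H0 = {"typical": 0.8, "disaster": 1.5}
FLOOD_GAMMA = 0.08
FLOOD_NOISE_SD = 0.05

# temperature defaults (degC): regional summer daily-mean baseline, mean
# diurnal gap between daily mean and daily max, day-to-day and cell-day noise
TEMP_BASE_TMEAN = 15.5
TEMP_DIURNAL_GAP = 5.0
TEMP_DAY_SD = 2.5
TEMP_CELL_DAY_SD = 1.0


@dataclass
class SyntheticRegion:
    """A generated study region and its planted truth."""

    areas: pd.DataFrame        # area_id, geometry, population, households, building_count, latent
    buildings: pd.DataFrame    # building_id, x, y, area_id
    channel: LineString
    truth: dict
    n_side: int
    crs: str = DEFAULT_CRS
    seed: int | None = None

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def building_density(self) -> pd.Series:
        """Buildings per unit area (areas are unit squares)."""
        return pd.Series(
            self.areas["building_count"].to_numpy(dtype=float),
            index=self.areas[AREA_ID],
            name="building_density",
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_region(n_side: int, seed: int) -> SyntheticRegion:
    """Generate the lattice of areas, populations, latent factor and buildings.

    Areas are axis-aligned unit squares on an n_side x n_side lattice in a
    projected planar CRS.  L(a) is an iid standard-normal field smoothed
    with a Gaussian kernel (sigma = 1.2 areas) and re-standardised, giving
    positive spatial autocorrelation.  Populations are uniform on
    [1000, 3000]; households = population / 2.4 (rounded); the building
    count is households plus a small Poisson excess for non-residential
    stock, and building points are uniform within their area.
    """
    if n_side < 2:
        raise ParameterError(f"n_side must be >= 2, got {n_side}")
    rng_latent, rng_pop, rng_bld = _child_rngs(seed, 3)

    raw = rng_latent.normal(size=(n_side, n_side))
    smooth = gaussian_filter(raw, sigma=_LATENT_SMOOTH_SIGMA, mode="reflect")
    latent = (smooth - smooth.mean()) / smooth.std()

    rows, cols = np.divmod(np.arange(n_side * n_side), n_side)
    population = rng_pop.integers(1000, 3001, size=n_side * n_side)
    households = np.maximum(1, np.round(population / _MEAN_HOUSEHOLD_SIZE)).astype(int)
    building_count = households + rng_bld.poisson(0.05 * households)

    area_ids = [f"A{r:03d}{c:03d}" for r, c in zip(rows, cols)]
    geoms = [Polygon.from_bounds(c, r, c + 1, r + 1) for r, c in zip(rows, cols)]
    areas = pd.DataFrame(
        {
            AREA_ID: area_ids,
            "geometry": geoms,
            "row": rows,
            "col": cols,
            "population": population,
            "households": households,
            "building_count": building_count,
            "latent": latent[rows, cols],
            "area_km2": 1.0,
        }
    )

    total = int(building_count.sum())
    xy = rng_bld.random(size=(total, 2))
    owner = np.repeat(np.arange(n_side * n_side), building_count)
    bx = cols[owner] + xy[:, 0]
    by = rows[owner] + xy[:, 1]
    buildings = pd.DataFrame(
        {
            "building_id": np.arange(total),
            "x": bx,
            "y": by,
            AREA_ID: np.asarray(area_ids, dtype=object)[owner],
        }
    )

    x0, x1 = (f * n_side for f in _CHANNEL_X_FRACS)
    channel = LineString([(x0, 0.0), (x1, float(n_side))])
    centroids = shapely.points(np.column_stack([cols + 0.5, rows + 0.5]))
    channel_dist = shapely.distance(centroids, channel)

    truth = {
        "seed": int(seed),
        "n_side": int(n_side),
        "latent_smooth_sigma": _LATENT_SMOOTH_SIGMA,
        "mean_household_size": _MEAN_HOUSEHOLD_SIZE,
        "latent": dict(zip(area_ids, latent[rows, cols].tolist())),
        "building_count": dict(zip(area_ids, building_count.tolist())),
        "channel_distance": dict(zip(area_ids, channel_dist.tolist())),
        "channel_wkt": channel.wkt,
    }
    return SyntheticRegion(
        areas=areas, buildings=buildings, channel=channel, truth=truth,
        n_side=n_side, seed=seed,
    )


def generate_census_counts(
    region: SyntheticRegion,
    registry: MetricRegistry,
    effect_size: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Census-style count table whose prevalences load on the latent factor.

    For each indexed metric m and area a the numerator is
    Binomial(base_a, p_ma) with logit(p_ma) = logit(p0_m) +
    effect_size * polarity_m * L(a); the baseline prevalence p0_m is drawn
    uniformly from [0.02, 0.4] per metric.  The base is the area population
    or household count according to the metric's denominator field.  The
    separate %-female metric is Binomial(population, 0.51) and population
    density comes directly from the population and area columns.
    """
    if effect_size < 0:
        raise ParameterError(f"effect_size must be >= 0, got {effect_size}")
    rng_base, rng_draw = _child_rngs(seed, 2)
    areas = region.areas
    latent = areas["latent"].to_numpy()
    bases = {"population": areas["population"].to_numpy(), "households": areas["households"].to_numpy()}

    out = pd.DataFrame(
        {
            AREA_ID: areas[AREA_ID],
            "population": areas["population"],
            "households": areas["households"],
            "area_km2": areas["area_km2"],
        }
    )
    baselines = {}
    for m in registry.metrics:
        if m.denominator_field not in bases:
            raise SchemaError(
                f"metric {m.metric_id!r}: unknown denominator field {m.denominator_field!r}"
            )
        p0 = rng_base.uniform(0.02, 0.4)
        baselines[m.metric_id] = p0
        p = expit(logit(p0) + effect_size * m.polarity * latent)
        out[m.numerator_field] = rng_draw.binomial(bases[m.denominator_field], p)
    out["n_female"] = rng_draw.binomial(bases["population"], 0.51)
    region.truth.setdefault("census", {})[
        "baseline_prevalence"
    ] = baselines
    region.truth["census"]["effect_size"] = float(effect_size)
    region.truth["census"]["seed"] = int(seed)
    return out


def generate_flood_depths(
    region: SyntheticRegion,
    cell_size: float = 0.05,
    seed: int = 0,
    scenario: FloodScenario | None = None,
    h0: float | None = None,
    gamma: float = FLOOD_GAMMA,
    noise_sd: float = FLOOD_NOISE_SD,
) -> HazardGrid:
    """Flood-depth grid (metres) decaying linearly from the channel.

    depth(x) = max(0, H0 - gamma * dist(x, channel) + eps), with eps a
    zero-mean Gaussian truncated at +/-3 sd.  The peak depth H0 defaults by
    scenario role (typical 0.8 m, disaster 1.5 m); the noise field depends
    only on the seed and grid geometry, so grids for both scenarios from
    the same seed differ only through H0 and the disaster depth dominates
    cell-wise.
    """
    if cell_size <= 0:
        raise ParameterError(f"cell_size must be positive, got {cell_size}")
    scenario = scenario or FloodScenario()
    if h0 is None:
        h0 = FLOOD_H0[scenario.role]
    n = region.n_side
    ncell = int(round(n / cell_size))
    xs = (np.arange(ncell) + 0.5) * cell_size
    ys = (np.arange(ncell) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    dist = shapely.distance(pts, region.channel).reshape(ncell, ncell)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    eps = np.clip(rng.normal(0.0, noise_sd, size=dist.shape), -3 * noise_sd, 3 * noise_sd)
    depth = np.maximum(0.0, h0 - gamma * dist + eps)
    meta = {
        "variable": "flood_depth_m",
        "scenario": {
            "return_period_years": scenario.return_period_years,
            "climate_pathway": scenario.climate_pathway,
            "horizon_year": scenario.horizon_year,
            "role": scenario.role,
        },
        "h0": h0,
        "gamma": gamma,
        "noise_sd": noise_sd,
        "seed": int(seed),
    }
    region.truth.setdefault("flood", {})[scenario.role] = {k: meta[k] for k in ("h0", "gamma", "noise_sd", "seed")}
    return HazardGrid(values=depth, xmin=0.0, ymin=0.0, cell_size=cell_size,
                      crs=region.crs, metadata=meta)


def _season_dates(config: PipelineConfig) -> pd.DatetimeIndex:
    parts = []
    for year in config.years:
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        parts.append(days[days.month.isin(config.season_months)])
    if not parts or sum(len(p) for p in parts) == 0:
        raise ParameterError("configured season/years contain no days")
    return pd.DatetimeIndex(np.concatenate([p.to_numpy() for p in parts]))


def generate_daily_temperatures(
    region: SyntheticRegion,
    config: PipelineConfig | None = None,
    uhi_strength: float = 3.0,
    seed: int = 0,
    cell_size: float = 1.0,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Daily maximum and mean temperature stacks over the configured season.

    Per cell c and day t:
        tmean[t, c] = base + day_anomaly[t] + uhi_strength * density(c) + noise
        tmax[t, c]  = tmean[t, c] + diurnal_gap[t, c]            (gap >= 0)
    where density(c) is the cell's building count normalised by the maximum
    cell count (the planted urban-heat-island), day anomalies are shared
    across cells, and the diurnal gap is a folded normal so the daily max
    never undercuts the daily mean.

    Returns (daily_tmax, daily_tmean) as DataArrays with dims (time, y, x)
    and cell-center coordinates in the region's planar CRS.
    """
    if uhi_strength < 0:
        raise ParameterError(f"uhi_strength must be >= 0, got {uhi_strength}")
    config = config or PipelineConfig()
    dates = _season_dates(config)
    n = region.n_side
    ncell = int(round(n / cell_size))

    grid = HazardGrid(values=np.zeros((ncell, ncell)), cell_size=cell_size, crs=region.crs)
    rows, cols, inside = grid.cell_index(region.buildings["x"], region.buildings["y"])
    counts = np.zeros((ncell, ncell))
    np.add.at(counts, (rows[inside], cols[inside]), 1.0)
    density = counts / counts.max() if counts.max() > 0 else counts

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    nt = len(dates)
    day_anom = rng.normal(0.0, TEMP_DAY_SD, size=nt)[:, None, None]
    cell_noise = rng.normal(0.0, TEMP_CELL_DAY_SD, size=(nt, ncell, ncell))
    gap = np.abs(rng.normal(TEMP_DIURNAL_GAP, 1.0, size=(nt, ncell, ncell)))

    tmean = TEMP_BASE_TMEAN + day_anom + uhi_strength * density[None, :, :] + cell_noise
    tmax = tmean + gap

    coords = {"time": dates, "y": grid.y_centers(), "x": grid.x_centers()}
    attrs = {
        "crs": region.crs,
        "cell_size": cell_size,
        "uhi_strength": uhi_strength,
        "base_tmean_c": TEMP_BASE_TMEAN,
        "seed": int(seed),
    }
    da_max = xr.DataArray(tmax, dims=("time", "y", "x"), coords=coords,
                          attrs={**attrs, "variable": "daily_tmax_c"}, name="daily_tmax")
    da_mean = xr.DataArray(tmean, dims=("time", "y", "x"), coords=coords,
                           attrs={**attrs, "variable": "daily_tmean_c"}, name="daily_tmean")
    region.truth.setdefault("temperature", {}).update(
        {"uhi_strength": float(uhi_strength), "seed": int(seed), "cell_size": cell_size}
    )
    return da_max, da_mean
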