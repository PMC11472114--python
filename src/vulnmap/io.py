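"""File formats, the pipeline driver, and the run manifest.

Vector layers travel as GeoJSON FeatureCollections (with a legacy ``crs``
member naming the projected planar system), rasters as ESRI ASCII grids,
temperature stacks as NetCDF, and tables as CSV.  Geographic (lon/lat)
coordinates are refused with a reprojection hint: every spatial operation
in the pipeline assumes a projected CRS with metre-like units.

``run_pipeline`` executes the whole chain — indicators, vulnerability
index, flood and heat exposure, risk matrices — and writes one joined
GeoJSON dataset plus per-stage CSVs and a JSON manifest recording the
configuration hash, seed, row counts and warning counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import mapping, shape

from . import __version__ as _version
from .errors import CRSError, SchemaError
from .flood import flood_exposure_table
from .grids import DEFAULT_CRS, HazardGrid
from .heat import heat_exposure_table
from .index import vulnerability_index
from .indicators import AREA_ID, compute_indicators, summarise_missingness
from .matrix import build_risk_matrix, matrix_summary
from .registry import FloodScenario, MetricRegistry, PipelineConfig, default_registry
from .synthetic import (
    generate_census_counts,
    generate_daily_temperatures,
    generate_flood_depths,
    generate_region,
)

__all__ = [
    "read_area_polygons",
    "write_polygon_layer",
    "read_points",
    "write_point_layer",
    "read_census_csv",
    "write_temperature_stack",
    "read_temperature_stack",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# GeoJSON vector layers


def _looks_geographic(geoms) -> bool:
    bounds = shapely.bounds(np.asarray(geoms, dtype=object))
    xmin, ymin = np.nanmin(bounds[:, 0]), np.nanmin(bounds[:, 1])
    xmax, ymax = np.nanmax(bounds[:, 2]), np.nanmax(bounds[:, 3])
    return -180.0 <= xmin <= xmax <= 180.0 and -90.0 <= ymin <= ymax <= 90.0


def _read_feature_collection(path) -> tuple[pd.DataFrame, str]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    crs = doc.get("crs", {}).get("properties", {}).get("name", "")
    records = []
    geoms = []
    for feat in doc.get("features", []):
        records.append(feat.get("properties", {}))
        geoms.append(shape(feat["geometry"]))
    df = pd.DataFrame.from_records(records)
    df["geometry"] = geoms
    if not crs:
        if _looks_geographic(geoms):
            raise CRSError(
                f"{path}: coordinates look geographic (lon/lat) and no projected "
                "CRS is declared; reproject to a planar metre-based CRS first"
            )
        crs = DEFAULT_CRS
    elif any(tag in crs.upper() for tag in ("CRS84", "4326", "WGS84", "OGC:1.3")):
        raise CRSError(
            f"{path}: declared CRS {crs!r} is geographic; reproject to a "
            "projected metre-based CRS before running the pipeline"
        )
    return df, crs


def read_area_polygons(path) -> pd.DataFrame:
    """Read the area boundary layer; enforces unique IDs and a projected CRS."""
    df, crs = _read_feature_collection(path)
    if AREA_ID not in df.columns:
        raise SchemaError(f"{path}: features lack an {AREA_ID!r} property")
    if df[AREA_ID].duplicated().any():
        dupes = df[AREA_ID][df[AREA_ID].duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate area IDs: {dupes[:5]}")
    df.attrs["crs"] = crs
    return df


def read_points(path) -> pd.DataFrame:
    """Read a point layer (buildings); adds x/y columns from the geometry."""
    df, crs = _read_feature_collection(path)
    df["x"] = [g.x for g in df["geometry"]]
    df["y"] = [g.y for g in df["geometry"]]
    df.attrs["crs"] = crs
    return df


def _round_coords(obj, ndigits=8):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, ndigits) for o in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def _write_feature_collection(df: pd.DataFrame, path, crs: str) -> None:
    feats = []
    for _, row in df.iterrows():
        props = {}
        for k, v in row.items():
            if k == "geometry":
                continue
            if pd.isna(v):
                props[k] = None
            elif isinstance(v, (np.integer,)):
                props[k] = int(v)
            elif isinstance(v, (np.floating,)):
                props[k] = round(float(v), 10)
            else:
                props[k] = v
        geom = mapping(row["geometry"])
        geom["coordinates"] = _round_coords(geom["coordinates"])
        feats.append({"type": "Feature", "properties": props, "geometry": geom})
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": feats,
    }
    Path(path).write_text(json.dumps(doc, separators=(",", ":")), encoding="utf-8")


def write_polygon_layer(df: pd.DataFrame, path, crs: str = DEFAULT_CRS) -> None:
    _write_feature_collection(df, path, crs)


def write_point_layer(df: pd.DataFrame, path, crs: str = DEFAULT_CRS) -> None:
    out = df.copy()
    if "geometry" not in out.columns:
        out["geometry"] = shapely.points(out[["x", "y"]].to_numpy())
        out = out.drop(columns=["x", "y"])
    _write_feature_collection(out, path, crs)


# ---------------------------------------------------------------------------
# tables and stacks


def read_census_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if AREA_ID not in df.columns:
        raise SchemaError(f"{path}: census CSV lacks an {AREA_ID!r} column")
    return df


def write_temperature_stack(da: xr.DataArray, path) -> None:
    """Write a daily stack as NetCDF (classic format, no compression)."""
    attrs = {k: v for k, v in da.attrs.items() if not isinstance(v, dict)}
    da = da.copy()
    da.attrs = attrs
    da.to_dataset(name=da.name or "data").to_netcdf(path, engine="scipy")


def read_temperature_stack(path, name: str | None = None) -> xr.DataArray:
    ds = xr.open_dataset(path, engine="scipy")
    var = name or list(ds.data_vars)[0]
    da = ds[var].load()
    ds.close()
    return da


def _csv_bytes(df: pd.DataFrame) -> bytes:
    return df.to_csv(index=False, float_format="%.10g", lineterminator="\n").encode()


def _write_csv(df: pd.DataFrame, path) -> None:
    Path(path).write_bytes(_csv_bytes(df))


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(
    out_dir,
    config: PipelineConfig | None = None,
    registry: MetricRegistry | None = None,
    n_side: int = 20,
    seed: int | None = None,
    effect_size: float = 1.0,
    uhi_strength: float = 3.0,
    census_path=None,
    areas_path=None,
    buildings_path=None,
    flood_grid_paths: dict | None = None,
    tmax_path=None,
    tmean_path=None,
) -> dict:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    With no input paths, a synthetic study region is generated (n_side x
    n_side areas, planted effect sizes as given) — the self-contained demo
    mode.  With explicit paths, the same stages run on user data: census
    CSV, area polygons and buildings (GeoJSON), flood grids (ASCII grid,
    keyed "typical"/"disaster") and temperature stacks (NetCDF).

    Returns the run manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or PipelineConfig()
    registry = registry or default_registry()
    seed = config.rng_seed if seed is None else seed

    scen_typical = FloodScenario(return_period_years=100, role="typical")
    scen_disaster = FloodScenario(return_period_years=1000, role="disaster")

    synthetic = census_path is None
    if synthetic:
        ss = np.random.SeedSequence(seed)
        sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
        region = generate_region(n_side, seed=sub[0])
        census = generate_census_counts(region, registry, effect_size=effect_size, seed=sub[1])
        areas = region.areas
        buildings = region.buildings
        grids = {
            "typical": generate_flood_depths(region, seed=sub[2], scenario=scen_typical),
            "disaster": generate_flood_depths(region, seed=sub[2], scenario=scen_disaster),
        }
        tmax, tmean = generate_daily_temperatures(
            region, config, uhi_strength=uhi_strength, seed=sub[3]
        )
        write_polygon_layer(areas.drop(columns=["latent"]), out / "areas.geojson", crs=region.crs)
        write_point_layer(buildings, out / "buildings.geojson", crs=region.crs)
        _write_csv(census, out / "census_counts.csv")
        (out / "truth.json").write_text(json.dumps(region.truth, indent=1, sort_keys=True))
    else:
        census = read_census_csv(census_path)
        areas = read_area_polygons(areas_path)
        buildings = read_points(buildings_path)
        grids = {
            role: HazardGrid.from_ascii(p, crs=areas.attrs.get("crs", DEFAULT_CRS))
            for role, p in (flood_grid_paths or {}).items()
        }
        tmax = read_temperature_stack(tmax_path, "daily_tmax")
        tmean = read_temperature_stack(tmean_path, "daily_tmean")

    # stage 1-2: indicators and index
    ind = compute_indicators(census, registry)
    missing = summarise_missingness(ind)
    vuln = vulnerability_index(ind, registry, config)
    _write_csv(ind, out / "indicators.csv")
    _write_csv(vuln.table, out / "vulnerability.csv")

    # stage 3: flood exposure per scenario
    flood_tables = {}
    scen_by_role = {"typical": scen_typical, "disaster": scen_disaster}
    for role, grid in grids.items():
        ft = flood_exposure_table(
            grid, buildings, areas[AREA_ID],
            threshold=config.flood_depth_threshold_m,
            scenario=scen_by_role.get(role),
        )
        flood_tables[role] = ft
        _write_csv(ft, out / f"flood_exposure_{role}.csv")

    # stage 4: heat exposure
    heat = heat_exposure_table(tmax, tmean, buildings, areas, config)
    _write_csv(heat, out / "heat_exposure.csv")

    # stage 5: risk matrices
    heat_metric = (
        heat.set_index(AREA_ID)["mean_summer_tmax"]
        if config.heat_matrix_metric == "tmax"
        else heat.set_index(AREA_ID)["exceedance_fraction"]
    )
    matrices = {"heat": build_risk_matrix(vuln, heat_metric, "heat")}
    for role, ft in flood_tables.items():
        matrices[f"flood_{role}"] = build_risk_matrix(
            vuln,
            ft.set_index(AREA_ID)["proportion_flooded"],
            "flood",
            scenario=scen_by_role.get(role),
        )
    for name, mt in matrices.items():
        _write_csv(mt, out / f"risk_matrix_{name}.csv")

    # stage 6: one joined geospatial dataset
    joined = areas[[AREA_ID, "geometry"]].merge(
        vuln.table[
            [AREA_ID, "vulnerability_index", "index_tercile"]
            + [c for c in vuln.table.columns if c.startswith(("sd_", "dom_"))]
        ],
        on=AREA_ID, how="left",
    )
    for role, ft in flood_tables.items():
        joined = joined.merge(
            ft[[AREA_ID, "proportion_flooded", "flood_decile"]].rename(
                columns={
                    "proportion_flooded": f"flood_prop_{role}",
                    "flood_decile": f"flood_decile_{role}",
                }
            ),
            on=AREA_ID, how="left",
        )
    joined = joined.merge(
        heat[[AREA_ID, "mean_summer_tmax", "exceedance_fraction", "decile_tmax", "decile_exceed"]],
        on=AREA_ID, how="left",
    )
    for name, mt in matrices.items():
        joined = joined.merge(
            mt[[AREA_ID, "cell_code", "cell_label"]].rename(
                columns={"cell_code": f"risk_{name}_code", "cell_label": f"risk_{name}_label"}
            ),
            on=AREA_ID, how="left",
        )
    write_polygon_layer(joined, out / "joined_dataset.geojson",
                        crs=areas.attrs.get("crs", DEFAULT_CRS))

    cfg_doc = {k: sorted(v) if isinstance(v, frozenset) else v for k, v in asdict(config).items()}
    manifest = {
        "software_version": _version,
        "seed": int(seed),
        "config": cfg_doc,
        "config_hash": _sha256(json.dumps(cfg_doc, sort_keys=True, default=str).encode()),
        "synthetic": synthetic,
        "n_areas": int(len(areas)),
        "n_buildings": int(len(buildings)),
        "missing_overall": missing["overall"],
        "excluded_areas": vuln.excluded_areas,
        "row_counts": {
            "indicators": len(ind),
            "vulnerability": len(vuln.table),
            **{f"flood_{r}": len(t) for r, t in flood_tables.items()},
            "heat": len(heat),
            **{f"risk_matrix_{n}": len(m) for n, m in matrices.items()},
        },
        "matrix_counts": {
            n: matrix_summary(m).loc[[1, 2, 3], [1, 2, 3]].to_numpy().tolist()
            for n, m in matrices.items()
        },
        "input_checksums": {
            "census_counts": _sha256(_csv_bytes(census)),
        },
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
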