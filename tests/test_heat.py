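"""Summer heat metrics, building-weighted zonal means, and decile ranks."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy.stats import spearmanr
from shapely.geometry import Polygon

from vulnmap import (
    ParameterError,
    PipelineConfig,
    building_weighted_area_value,
    cell_exceedance_fraction,
    cell_mean_summer_tmax,
    generate_daily_temperatures,
    heat_exposure_table,
)
from vulnmap.grids import HazardGrid


def stack(values, dates):
    """2x1 or arbitrary (time, y, x) stack with unit cells."""
    arr = np.asarray(values, dtype=float)
    ny, nx = arr.shape[1:]
    return xr.DataArray(
        arr,
        dims=("time", "y", "x"),
        coords={
            "time": pd.DatetimeIndex(dates),
            "y": np.arange(ny) + 0.5,
            "x": np.arange(nx) + 0.5,
        },
        attrs={"crs": "synthetic:planar", "cell_size": 1.0},
    )


class TestCellSummaries:
    def test_constant_field_mean_is_constant(self):
        s = stack(np.full((3, 2, 2), 20.0), ["2015-06-01", "2015-07-01", "2015-08-01"])
        out = cell_mean_summer_tmax(s)
        assert np.allclose(out.to_numpy(), 20.0)

    def test_mean_of_two_days(self):
        s = stack([[[18.0]], [[22.0]]], ["2015-06-01", "2015-06-02"])
        assert cell_mean_summer_tmax(s).item() == pytest.approx(20.0)

    def test_out_of_season_days_ignored(self):
        with_may = stack(
            [[[50.0]], [[18.0]], [[22.0]]], ["2015-05-31", "2015-06-01", "2015-06-02"]
        )
        without = stack([[[18.0]], [[22.0]]], ["2015-06-01", "2015-06-02"])
        assert cell_mean_summer_tmax(with_may).item() == cell_mean_summer_tmax(without).item()

    def test_no_in_season_days_rejected(self):
        s = stack([[[20.0]]], ["2015-01-15"])
        with pytest.raises(ParameterError):
            cell_mean_summer_tmax(s)

    def test_exceedance_all_days_above(self):
        s = stack(np.full((4, 1, 1), 16.0), pd.date_range("2015-06-01", periods=4))
        assert cell_exceedance_fraction(s).item() == 1.0

    def test_exceedance_threshold_is_strict(self):
        """A day at exactly 15.0 degC is not an exceedance."""
        s = stack([[[15.0]], [[15.1]]], ["2015-06-01", "2015-06-02"])
        assert cell_exceedance_fraction(s, threshold=15.0).item() == pytest.approx(0.5)

    def test_exceedance_zero_when_cool(self):
        s = stack(np.full((4, 1, 1), 10.0), pd.date_range("2015-06-01", periods=4))
        assert cell_exceedance_fraction(s).item() == 0.0

    def test_exceedance_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(2)
        s = stack(rng.normal(15, 3, size=(50, 2, 2)), pd.date_range("2016-06-01", periods=50))
        f = [cell_exceedance_fraction(s, threshold=t).to_numpy() for t in (13.0, 15.0, 17.0)]
        assert np.all(f[0] >= f[1]) and np.all(f[1] >= f[2])


def unit_area(aid, x0, y0, w=2, h=1):
    return {"area_id": aid, "geometry": Polygon.from_bounds(x0, y0, x0 + w, y0 + h)}


class TestBuildingWeightedAreaValue:
    def test_weighted_mean_of_two_cells(self):
        cells = HazardGrid(values=np.array([[10.0, 20.0]]), cell_size=1.0)
        buildings = pd.DataFrame(
            {"x": [0.5, 1.2, 1.5, 1.8], "y": [0.5] * 4, "area_id": ["a"] * 4}
        )
        areas = pd.DataFrame([unit_area("a", 0, 0)])
        out = building_weighted_area_value(cells, buildings, areas)
        assert out.loc[0, "value"] == pytest.approx(17.5)  # (1*10 + 3*20)/4
        assert out.loc[0, "total_weight"] == 4

    def test_all_buildings_in_one_cell_give_that_cell(self):
        cells = HazardGrid(values=np.array([[10.0, 20.0]]), cell_size=1.0)
        buildings = pd.DataFrame({"x": [0.2, 0.8], "y": [0.5, 0.5], "area_id": ["a", "a"]})
        areas = pd.DataFrame([unit_area("a", 0, 0)])
        assert building_weighted_area_value(cells, buildings, areas).loc[0, "value"] == 10.0

    def test_zero_building_area_falls_back_to_unweighted_mean(self):
        cells = HazardGrid(values=np.array([[10.0, 20.0]]), cell_size=1.0)
        buildings = pd.DataFrame({"x": [0.5], "y": [0.5], "area_id": ["a"]})
        areas = pd.DataFrame([unit_area("a", 0, 0), unit_area("b", 0, 0)])
        out = building_weighted_area_value(cells, buildings, areas).set_index("area_id")
        assert out.loc["b", "value"] == pytest.approx(15.0)
        assert bool(out.loc["b", "fallback"])
        assert not bool(out.loc["a", "fallback"])

    def test_equal_counts_equal_unweighted_mean(self):
        cells = HazardGrid(values=np.array([[10.0, 30.0]]), cell_size=1.0)
        buildings = pd.DataFrame(
            {"x": [0.5, 1.5], "y": [0.5, 0.5], "area_id": ["a", "a"]}
        )
        areas = pd.DataFrame([unit_area("a", 0, 0)])
        assert building_weighted_area_value(cells, buildings, areas).loc[0, "value"] == 20.0


class TestHeatExposureTable:
    def test_planted_uhi_recovered_in_tmax_deciles(self, region_400, config):
        tmax, tmean = generate_daily_temperatures(region_400, config, uhi_strength=3.0, seed=4)
        out = heat_exposure_table(tmax, tmean, region_400.buildings, region_400.areas, config)
        dens = region_400.building_density()
        dec = out.set_index("area_id")["decile_tmax"].astype(float).reindex(dens.index)
        assert spearmanr(dec, dens).statistic >= 0.7

    def test_null_uhi_leaves_no_density_signal(self, region_400, config):
        tmax, tmean = generate_daily_temperatures(region_400, config, uhi_strength=0.0, seed=4)
        out = heat_exposure_table(tmax, tmean, region_400.buildings, region_400.areas, config)
        dens = region_400.building_density()
        dec = out.set_index("area_id")["decile_tmax"].astype(float).reindex(dens.index)
        assert abs(spearmanr(dec, dens).statistic) < 0.15

    def test_deciles_invariant_under_monotone_transform(self, region_small, config):
        from vulnmap import decile_rank

        tmax, tmean = generate_daily_temperatures(region_small, config, uhi_strength=2.0, seed=4)
        out = heat_exposure_table(tmax, tmean, region_small.buildings, region_small.areas, config)
        warped = decile_rank(np.exp(out["mean_summer_tmax"] / 10))
        pd.testing.assert_series_equal(out["decile_tmax"], warped, check_names=False)

    def test_exceedance_fraction_in_unit_interval(self, region_small, config):
        tmax, tmean = generate_daily_temperatures(region_small, config, seed=4)
        out = heat_exposure_table(tmax, tmean, region_small.buildings, region_small.areas, config)
        assert out["exceedance_fraction"].between(0, 1).all()
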