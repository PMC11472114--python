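"""Synthetic study-region generator: determinism, construction invariants,
and the planted signals it is supposed to carry."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from vulnmap import (
    FloodScenario,
    ParameterError,
    PipelineConfig,
    generate_census_counts,
    generate_daily_temperatures,
    generate_flood_depths,
    generate_region,
)


class TestGenerateRegion:
    def test_area_count_and_population_bounds(self, region_400):
        assert region_400.n_areas == 400
        pops = region_400.areas["population"]
        assert pops.between(1000, 3000).all()

    def test_minimum_lattice(self):
        assert generate_region(2, seed=7).n_areas == 4

    def test_too_small_lattice_rejected(self):
        with pytest.raises(ParameterError):
            generate_region(1, seed=0)

    def test_determinism_same_seed(self):
        a = generate_region(6, seed=11)
        b = generate_region(6, seed=11)
        pd.testing.assert_frame_equal(a.areas, b.areas)
        pd.testing.assert_frame_equal(a.buildings, b.buildings)
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = generate_region(6, seed=1)
        b = generate_region(6, seed=2)
        assert not np.array_equal(a.areas["latent"], b.areas["latent"])

    def test_latent_factor_standardised_and_spatially_smooth(self, region_400):
        areas = region_400.areas
        lat = areas["latent"].to_numpy()
        assert abs(lat.mean()) < 1e-9 and abs(lat.std() - 1) < 1e-9
        # neighbours on the lattice correlate: positive spatial autocorrelation
        grid = lat.reshape(20, 20)
        rho = np.corrcoef(grid[:, :-1].ravel(), grid[:, 1:].ravel())[0, 1]
        assert rho > 0.3

    def test_every_building_inside_its_area(self, region_small):
        geo = region_small.areas.set_index("area_id")["geometry"]
        b = region_small.buildings
        for aid, grp in b.groupby("area_id"):
            minx, miny, maxx, maxy = geo.loc[aid].bounds
            assert grp["x"].between(minx, maxx).all()
            assert grp["y"].between(miny, maxy).all()

    def test_building_counts_conserved(self, region_small):
        assert region_small.areas["building_count"].sum() == len(region_small.buildings)
        per_area = region_small.buildings.groupby("area_id").size()
        expected = region_small.areas.set_index("area_id")["building_count"]
        pd.testing.assert_series_equal(
            per_area.sort_index(), expected.sort_index(), check_names=False, check_dtype=False
        )


class TestGenerateCensusCounts:
    def test_numerators_within_binomial_support(self, census_400, registry):
        for m in registry.metrics:
            base = census_400[m.denominator_field]
            num = census_400[m.numerator_field]
            assert ((num >= 0) & (num <= base)).all()

    def test_effect_size_plants_positive_metric_correlations(self, region_400, census_400, registry):
        lat = region_400.areas["latent"]
        rhos = [
            spearmanr(census_400[m.numerator_field] / census_400[m.denominator_field], lat).statistic
            for m in registry.metrics
        ]
        assert min(rhos) > 0

    def test_null_effect_leaves_metrics_uncorrelated(self, region_400, registry):
        census = generate_census_counts(region_400, registry, effect_size=0.0, seed=0)
        lat = region_400.areas["latent"]
        rhos = [
            abs(spearmanr(census[m.numerator_field] / census[m.denominator_field], lat).statistic)
            for m in registry.metrics
        ]
        assert max(rhos) < 0.15

    def test_negative_effect_size_rejected(self, region_small, registry):
        with pytest.raises(ParameterError):
            generate_census_counts(region_small, registry, effect_size=-1.0, seed=0)

    def test_deterministic_for_fixed_seed(self, region_small, registry):
        a = generate_census_counts(region_small, registry, 1.0, seed=9)
        b = generate_census_counts(region_small, registry, 1.0, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateFloodDepths:
    def test_deterministic_raster(self, region_small):
        a = generate_flood_depths(region_small, seed=3)
        b = generate_flood_depths(region_small, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_depth_decays_from_channel_in_expectation(self, region_small):
        depths = []
        for seed in range(5):
            g = generate_flood_depths(region_small, seed=seed)
            xs, ys = np.meshgrid(g.x_centers(), g.y_centers())
            import shapely

            d = shapely.distance(
                shapely.points(np.column_stack([xs.ravel(), ys.ravel()])), region_small.channel
            )
            near = g.values.ravel()[d < 0.5].mean()
            far = g.values.ravel()[(d > 3) & (d < 4)].mean()
            depths.append((near, far))
        arr = np.array(depths)
        assert (arr[:, 0] > arr[:, 1]).all()

    def test_cells_beyond_decay_range_are_dry(self, region_small):
        g = generate_flood_depths(region_small, seed=3)
        xs, ys = np.meshgrid(g.x_centers(), g.y_centers())
        import shapely

        d = shapely.distance(
            shapely.points(np.column_stack([xs.ravel(), ys.ravel()])), region_small.channel
        ).reshape(g.values.shape)
        h0, gamma, sd = g.metadata["h0"], g.metadata["gamma"], g.metadata["noise_sd"]
        beyond = d > (h0 + 3 * sd) / gamma
        assert np.all(g.values[beyond] == 0.0)

    def test_disaster_dominates_typical_cellwise(self, region_small):
        t = generate_flood_depths(region_small, seed=3, scenario=FloodScenario(100, role="typical"))
        d = generate_flood_depths(region_small, seed=3, scenario=FloodScenario(1000, role="disaster"))
        assert np.all(d.values >= t.values)


class TestGenerateDailyTemperatures:
    def test_date_axis_covers_season_years(self, region_small):
        tmax, tmean = generate_daily_temperatures(region_small, PipelineConfig(), seed=4)
        assert tmax.sizes["time"] == 92 * 5  # JJA days x 2015-2019
        assert tmean.sizes["time"] == 92 * 5

    def test_daily_max_never_below_daily_mean(self, region_small):
        tmax, tmean = generate_daily_temperatures(region_small, seed=4)
        assert np.all(tmax.to_numpy() >= tmean.to_numpy())

    def test_uhi_zero_gives_spatially_flat_expected_field(self, region_small):
        tmax, _ = generate_daily_temperatures(region_small, uhi_strength=0.0, seed=4)
        cell_means = tmax.mean("time").to_numpy()
        assert cell_means.std() < 0.2  # only residual day noise

    def test_uhi_raises_densest_cell_most_in_expectation(self, region_small):
        """Averaged over seeds (removing day noise), the densest-built cell
        tops the mean summer maximum field and the field tracks density."""
        from scipy.stats import spearmanr

        fields = [
            generate_daily_temperatures(region_small, uhi_strength=3.0, seed=s)[0]
            .mean("time").to_numpy().ravel()
            for s in range(5)
        ]
        pooled = np.mean(fields, axis=0)
        dens = region_small.areas["building_count"].to_numpy().astype(float)
        assert spearmanr(pooled, dens).statistic > 0.9
        assert pooled[np.argmax(dens)] > np.median(pooled) + 1.0

    def test_empty_season_rejected(self, region_small):
        with pytest.raises(Exception):
            generate_daily_temperatures(
                region_small, PipelineConfig(season_months=frozenset({2}), years=()), seed=0
            )
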