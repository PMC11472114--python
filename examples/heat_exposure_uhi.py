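"""Building-weighted summer heat metrics with a planted urban heat island.

Generates five summers (June-August 2015-2019) of daily maximum and mean
temperature grids in which dense built-up cells run up to 3 degC warmer,
then summarises each area by its building-weighted mean summer maximum and
the fraction of days whose mean strictly exceeds 15 degC.
"""

from scipy.stats import spearmanr

from vulnmap import PipelineConfig, generate_daily_temperatures, generate_region, heat_exposure_table

config = PipelineConfig()  # JJA 2015-2019, 15 degC exceedance threshold
region = generate_region(n_side=20, seed=1)
tmax, tmean = generate_daily_temperatures(region, config, uhi_strength=3.0, seed=4)
print(f"temperature stack: {tmax.sizes['time']} days "
      f"({len(config.years)} summers x 92 days), {tmax.sizes['y']}x{tmax.sizes['x']} cells")

heat = heat_exposure_table(tmax, tmean, region.buildings, region.areas, config)
print("\nhottest areas by building-weighted mean summer maximum:")
print(heat.nlargest(3, "mean_summer_tmax")[
    ["area_id", "mean_summer_tmax", "exceedance_fraction", "decile_tmax", "decile_exceed"]
].to_string(index=False))

dens = region.building_density()
dec = heat.set_index("area_id")["decile_tmax"].astype(float).reindex(dens.index)
print(f"\nSpearman(heat decile, building density) = {spearmanr(dec, dens).statistic:.3f}")
print("the decile ranking recovers the planted urban-heat-island gradient.")
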