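# Methods

This note documents the models and procedures implemented in `vulnmap`,
the parameters that matter, the design choices made where the method left
room, and what the synthetic test bed does and does not establish.

## Vulnerability index

The index follows the hierarchical rank–transform–weight methodology used
by the English Indices of Multiple Deprivation (IMD) family:

1. **Indicators.** Each metric is a per-area proportion
   numerator/denominator, with person-based metrics over the resident
   population and household-based metrics (car access, living alone,
   tenure, housing condition) over the household count; population density
   is residents per km². Zero denominators yield missing values; a
   numerator exceeding its denominator beyond floating tolerance is a hard
   data error naming the area and metric.
2. **Rank normalisation.** Within each metric, areas receive mean-ranks
   (ties share the mean of the positions they span) divided by the number
   of non-missing areas: R ∈ (0, 1], 1 = most vulnerable. A metric's
   polarity (−1 for protective metrics) reverses the order before ranking.
   Mean-ranks make every downstream quantity independent of input row
   order and stable under ties.
3. **Exponential transform.** Sub-domain scores are
   score(R) = −s·ln(1 − R·(1 − e^(−100/s))) with s = 23, the IMD scale
   constant (exposed in the registry as `transform_scale`). The map is a
   strict bijection (0, 1] → (0, 100]; small s concentrates resolution in
   the vulnerable tail. At R = 1 the closed form equals 100 exactly and the
   implementation pins the floating result to it.
4. **Aggregation.** Sub-domain score = transform of the re-ranked weighted
   mean of member metric ranks; domain score = weighted mean of sub-domain
   scores; overall index = weighted combination of re-ranked, re-transformed
   domain scores. The second transform mirrors IMD practice of transforming
   domain ranks before combination and can be switched off
   (`PipelineConfig.second_transform=False`), which preserves the ordering
   but changes the score shape.

**Weights** default to equal at every level and are fully configurable in
the registry YAML. The default hierarchy has 33 metrics — 31 indexed (the
seven income-deprivation components counted individually) in 9 sub-domains
(eight thematic ones plus a single health sub-domain holding the five
health/disability metrics) under 4 domains — plus 2 separate layers
(% female, population density) that are mapped but never enter the index.
A registry edit can fold the separate layers in as single-metric
sub-domains if desired.

**Missing data.** Sub-domain scores renormalise weights over the
non-missing member metrics; an area missing an entire sub-domain gets a
missing domain and a missing index, and is listed in
`VulnerabilityResult.excluded_areas` rather than silently dropped or
imputed. This is deliberately conservative: partial information within a
sub-domain is used, a wholly unmeasured domain is not guessed.

## Classification primitives

Deciles and terciles are ceil(k·R) of the same normalised mean-ranks
(k = 10, 3). The rule is deterministic, tie-stable and matches a
sort-and-bin enumeration exactly (property-tested against a brute-force
oracle). All-tied inputs land in the middle class (decile 6, tercile 2).
Hazard terciles for the risk matrix are computed from the *continuous*
exposure metric, not by collapsing deciles, because ten bins do not
partition evenly into three; deciles remain available as display layers.

## Flood exposure

Building depth is the depth-grid value of the cell owning the building
point under a half-open cell rule ([x, x+c) × [y, y+c)), so every point
belongs to exactly one cell and results cannot depend on edge tie-breaks.
No-data cells are treated as dry (flood products conventionally omit dry
cells) and buildings outside the grid are dry with a logged count. A
building is flooded iff depth > 0.10 m **strictly**; the threshold is a
`PipelineConfig` parameter in metres. Area exposure is the flooded
proportion of its buildings; zero-building areas carry missing proportions
and no decile. The two scenario grids (typical: 1-in-100-year RCP 8.5
2050; disaster: 1-in-1000-year) are ranked separately and both emitted.

## Heat exposure

Per cell: the mean of daily maxima over the configured season
(default months {6,7,8}, years 2015–2019), and the fraction of in-season
days with daily mean **strictly** above 15 °C. The 15 °C value is the
regional temperature–mortality threshold consumed as a parameter, not
derived here. Cell-to-area reduction is a building-count-weighted mean —
counts within equal-area cells are proportional to building density, which
is the stated weighting — with a flagged fallback to the unweighted mean
over intersecting cells for zero-building areas. The risk matrix uses the
mean summer maximum by default (`heat_matrix_metric="exceedance"` switches).

## Synthetic study region

The generator emulates the real inputs at study scale with known truth:

* **Areas.** An n×n lattice of unit squares in a planar CRS (one unit ≈
  one LSOA diameter); populations uniform on [1000, 3000] per the LSOA
  definition; households ≈ population/2.4.
* **Latent vulnerability L(a).** Standard-normal field smoothed with a
  Gaussian kernel (σ = 1.2 areas) and restandardised — spatially
  autocorrelated, as real deprivation is.
* **Census counts.** numerator ~ Binomial(base, p) with
  logit p = logit(p₀) + effect_size·polarity·L(a), baseline prevalences p₀
  uniform on [0.02, 0.4]. effect_size = 1 is the planted-signal condition;
  0 is the null.
* **Buildings.** One per household plus a 5 % Poisson excess for
  non-residential stock, uniform within each area; density variation comes
  from the population draw.
* **Flood grid.** depth = max(0, H₀ − γ·dist(channel) + ε) on a 0.05-unit
  grid, with a slightly oblique channel crossing the region,
  H₀ = 0.8 m (typical) / 1.5 m (disaster), γ = 0.08 m per unit, and ε
  Gaussian (σ = 0.05 m) truncated at ±3σ. γ is chosen so the depth
  gradient spans most of the region, making channel distance the dominant
  exposure signal; the noise field depends only on the seed, so the
  disaster grid dominates the typical one cell-wise by construction.
* **Temperatures.** tmean = 15.5 + day anomaly (σ = 2.5) +
  uhi_strength·(cell building count / max count) + cell-day noise (σ = 1);
  tmax = tmean + |N(5, 1)|, so the daily maximum never undercuts the mean.
  uhi_strength = 3 °C is the planted urban-heat-island condition. One cell
  per area mirrors the ~1 km grid vs LSOA-scale geometry of the real data.

All components draw from independent child streams of a master seed
(`numpy.random.SeedSequence`), so every product is reproducible in
isolation and full runs are byte-identical.

**What the synthetic bed does not show.** Real census metrics are not
conditionally independent given one latent factor; real flood fields are
not monotone in channel distance (defences, pluvial ponding); real heat
fields have topography and coastal gradients; areas are not squares of
equal size. Passing recovery tests therefore demonstrates the pipeline's
correctness and sensitivity, not the validity of any particular real-world
index.

## Numerical and interface choices

* Ranks use `scipy.stats.rankdata(method="average")`; weights are stored
  normalised (bit-exact if already normalised) and renormalised over
  non-missing members at aggregation time.
* Problem sizes: recovery experiments use 400 areas (20×20), the scale at
  which rank correlations stabilise; the axis-independence check under the
  null runs 100 seeds at 10×10.
* Geospatial I/O uses GeoJSON with a named planar CRS, ESRI ASCII grids
  and NetCDF; geographic (lon/lat) inputs are refused with a reprojection
  hint because all zonal operations assume metre-like planar units.
* The joined output keeps one row per input area, with missing codes for
  unclassified areas; the run manifest records config hash, seed, row
  counts and warning counts.

## Known limitations

* No uncertainty quantification on the index and no data-driven weighting
  (principal components etc.); the hierarchy and weights are fixed inputs.
* No imputation or small-area estimation for missing metrics.
* Buildings are points; footprints spanning multiple cells are reduced to
  the cell of the point.
* Coastal/fluvial/pluvial flood components are assumed pre-combined in the
  input grid; no defence modelling.
* Terciles are area-count-based; population-weighted terciles would be a
  natural extension.
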