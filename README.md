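# vulnmap

Small-area mapping of social vulnerability to climate-related hazards.
`vulnmap` builds a hierarchical vulnerability index from census-style count
tables, computes per-area flood and heat exposure from hazard grids and
building locations, and cross-classifies the two into a 3×3 risk matrix —
the map layers a local authority needs to target climate-adaptation work
(flood defences, cool spaces, community outreach) at the neighbourhoods
where high vulnerability and high hazard exposure coincide.

It is written for public-health analysts and researchers working with
LSOA-scale data (UK small areas of 1,000–3,000 residents), but everything
runs end to end on a built-in synthetic study region with planted ground
truth, so the whole pipeline is testable without any licensed data.

## The method

**Vulnerability index.** 33 metrics (31 indexed + 2 separate map layers)
from census and deprivation-index counts are grouped into 9 sub-domains and
4 domains: sensitivity, adaptive capacity, health, living environment.
Aggregation follows the rank–transform–weight recipe of the English Indices
of Multiple Deprivation. Each metric proportion is reduced to a normalised
mean-rank R ∈ (0, 1] (1 = most vulnerable), sub-domain scores are the
exponential transform of re-ranked weighted mean ranks,

```
score(R) = −s · ln(1 − R · (1 − e^(−100/s))),    s = 23,
```

a strictly increasing map of ranks onto 0–100 with score(1) = 100 that
spreads the vulnerable tail. Domains are weighted means of sub-domain
scores; the overall index re-ranks and transforms the domains and combines
them with (by default equal) domain weights.

**Flood exposure.** A building counts as flooded when the depth grid under
it exceeds 0.10 m *strictly*. Areas are ranked into deciles by the
proportion of their buildings flooded, separately for a "typical"
(1-in-100-year, RCP 8.5, 2050) and a "disaster" (1-in-1000-year) scenario.

**Heat exposure.** From daily temperature grids over June–August 2015–2019:
the mean daily maximum, and the fraction of days whose daily mean strictly
exceeds 15 °C (a regional mortality-risk threshold, consumed as a
parameter). Cell values are averaged to areas weighted by the number of
buildings per cell, then decile-ranked.

**Risk matrix.** Vulnerability and hazard scores are split into terciles
and crossed into 9 cells, coded `(v−1)·3 + h` and labelled `V{v}-H{h}`;
`V3-H3` is the priority cell.

## Worked example

```bash
python examples/build_vulnerability_index.py
```

prints (abridged):

```
registry: 31 indexed + 2 separate metrics, 9 sub-domains, 4 domains

most vulnerable areas (index 0-100, tercile 3 = worst third):
area_id  vulnerability_index  index_tercile
A007019           100.000000              3
A006019            95.984089              3
A005007            91.078722              3

Spearman(index, planted latent factor) = 1.000
```

The synthetic region plants a latent vulnerability factor L(a) and draws
every census numerator as Binomial with logit(p) shifted by L(a); a
Spearman correlation of ~1 between the computed index and L shows the
hierarchy recovers the planted ordering. The other examples
(`flood_exposure_deciles.py`, `heat_exposure_uhi.py`, `risk_matrix_map.py`)
demonstrate the exposure stages and the bivariate choropleth.

The same pipeline runs from the shell:

```bash
vulnmap run --synthetic 20 --seed 1 --out out/
```

writes `joined_dataset.geojson` (one feature per area with index, domain
scores, hazard deciles and both risk-matrix layers), per-stage CSVs, the
planted-truth record and a run manifest. `vulnmap dump-config` prints the
default metric registry YAML for editing; subcommands `synth`,
`indicators`, `index`, `flood`, `heat`, `matrix` run individual stages on
files.

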