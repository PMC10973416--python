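# n2oph

Soil pH is the dominant, non-linear control on the fraction of fertilizer
nitrogen that soils emit as nitrous oxide. `n2oph` is a Python toolkit for
quantifying that control: it turns heterogeneous field-study records into
N₂O **emission factors**, aggregates them into replicate-weighted pH bins,
fits competing linear/quadratic models with small-sample AICc selection to
locate the **peak-emission pH**, relates **denitrifier functional-gene
abundances** (nirK, nirS, nosZ clade I) to pH, and computes **headspace
fluxes, potential denitrification activity (PDA) and the N₂O/(N₂O+N₂)
product ratio** from sealed-bottle incubations. A synthetic-data generator
with known ground truth makes every stage testable end to end.

It is written for biogeochemists and microbial ecologists running
meta-analyses or acidity-manipulation experiments on soil N₂O.

## The quantities

**Emission factor** of a fertilization experiment, in % of applied N:

```
EF = 100 · (E_N − E_O) / N
```

with `E_N`, `E_O` the cumulative N₂O-N emissions (kg N ha⁻¹) of fertilized
and control plots and `N` the fertilization rate (kg N ha⁻¹). Because field
experiments cluster in popular pH ranges, a regression on raw EFs
over-weights those ranges; the *averaged* analysis therefore groups EFs
into 0.1-pH-unit bins and computes one weighted mean per bin,

```
M = Σ(Yᵢ·Wᵢ) / Σ(Wᵢ),   Wᵢ = nᵢ / o
```

where `nᵢ` is the replicate count of observation *i* and `o` the number of
observations in the bin. Hump-shaped responses are modelled as concave
quadratics; a degree-1 and a degree-2 fit compete on AICc (`k` counts the
error variance; ΔAICc > 2 required to prefer the quadratic), and the peak
is the vertex `pH* = −b/(2a)`. Incubation fluxes follow the ideal-gas
headspace conversion

```
F = ρ · V · ΔC · 273/(273+T) · f_N / (W · Δt)   [µg N kg⁻¹ h⁻¹]
```

and the denitrification product ratio is the quotient of the rates without
and with acetylene blockage of the N₂O reductase, clamped to [0, 1].

## Worked example

Generate a synthetic global field dataset (2000 observations, true EF-pH
curve peaking at pH 5.99) and run the full meta-analysis:

```
$ n2oph synth field --seed 42 --out studies.csv
$ n2oph meta1 --input studies.csv --out run1
{"read": 2000, "rejected": 0, "ef_observations": 2000, "negative_efs": 105, "bins": 64}
```

`run1/meta1.json` then contains, per fit:

```
coarse    quadratic  peak 5.97  adj_r2 0.124  delta_aicc 224.4
averaged  quadratic  peak 5.98  adj_r2 0.879  delta_aicc 131.4
```

Both the coarse fit (all 2000 individual EFs) and the averaged fit (one
weighted mean per 0.1-pH bin, 64 non-empty bins here) select the quadratic
decisively (ΔAICc ≫ 2) and place the emission peak within 0.02 pH units of
the generating truth; the averaged fit explains far more variance because
binning removes the within-bin scatter. `run1/meta1/bins.tsv` holds the bin
table (`bin_lower, bin_upper, o, sum_weights, weighted_mean_ef, ...`).

Incubation series work the same way from a long-format CSV
(see `examples/incubations.csv`, paired bottles with and without acetylene):

```
$ n2oph field --input examples/incubations.csv --out run2
sample_id    ratio   total_rate_ug_n_kg_h  net_rate_ug_n_kg_h  ph_h2o
  GN-A0-1    0.775              99.96               77.51         6.0
  GY-A4-3    0.678             116.44               79.00         7.2
```

i.e. at pH 6.0 about 78% of denitrification leaves the soil as N₂O, falling
to 68% at pH 7.2 — the product ratio declines with pH while total
denitrification rises.

## Input schemas

One example file per table ships under `examples/`:

* **Field studies** (`field_studies.csv`): required `study_id, ph_reported,
  n_rate, emission_fertilized, emission_control, replicates`; optional
  `site_id, latitude, ecosystem, ph_medium` (H2O/CaCl2/KCl/unknown; absent
  column ⇒ unknown, treated as water with a warning), `map_mm, mat_c, soc,
  tn, sand_pct, silt_pct, clay_pct`. Malformed rows are collected as
  rejects, not fatal (use `--strict` to abort).
* **Gene abundances** (`gene_abundances.csv`): `study_id, gene,
  copies_per_g, ph_h2o`; optional `sample_id, n2o_flux, ecosystem`. Gene
  names accept common synonyms ("nosZ clade I" → nosZI; bare "nosZ" is
  clade I). nosZII is stored but never enters the (nirK+nirS)/nosZI ratio.
* **Incubations** (`incubations.csv`): long format, `sample_id, acetylene,
  soil_dry_mass, bottle_volume, temperature_c, time_h, ppm` (+ optional
  `ph_h2o`); rows group into per-bottle series, paired by the sample-id
  stem before the last `-`.

CLI verbs: `meta1`, `meta2`, `field`, `bins`, `synth`; YAML run configs via
`--config` (pH-conversion coefficients, bin width, AICc threshold, gas
constants — all echoed into every report for provenance). Exit codes:
0 success, 2 schema error, 3 insufficient data.

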