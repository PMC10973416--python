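# Methods

## Scope and model

`n2oph` treats the response of soil N₂O emission factors (EFs) — and of the
denitrifier community markers that mechanistically underlie them — to soil
pH as a unimodal ("hump-shaped") curve, modelled throughout as a concave
second-order polynomial fitted by least squares. The package covers four
stages: harmonizing heterogeneous field records to a common basis,
computing and binning emission factors, model fitting with information-
criterion selection and peak location, and the laboratory calculators
(headspace flux, potential denitrification, product ratio) used in
acidity-manipulation experiments.

## Harmonization

* **pH basis.** Salt-suspension pH (CaCl₂, KCl) reads systematically lower
  than water pH. Conversions are affine maps with defaults CaCl₂ → +0.6 and
  KCl → +1.0 at unit slope. These are deliberately simple placeholders of
  the right magnitude: the appropriate map depends on soil population and
  ionic strength, so publication-grade runs must supply calibrated
  coefficients through the run config (they are echoed into every report).
  Unknown media are assumed water-measured, with a warning and a count.
* **Climate zones** by absolute latitude: tropical [0°, 23.4°], subtropical
  (23.4°, 35.0°], temperate (35.0°, 90°]. Boundary latitudes are assigned to
  the zone nearer the equator; the printed band edges are ambiguous at
  exactly 23.4° and 35.0°, and the closed-upper-edge convention makes the
  classification a true partition.
* **Acidity classes** follow the USDA ten-class table (ultra-acidic < 3.5
  … strongly alkaline 8.5–9.0). Inputs are rounded to one decimal before
  lookup, since the class edges are printed at 0.1 resolution; values above
  9.0 are labelled strongly alkaline and flagged as out of table.

## Emission factors and weighted binning

EF = 100·(E_N − E_O)/N, defined only for N > 0. Negative EFs (control plot
emitted more) are retained in all analyses and counted, never dropped.

Bins are half-open intervals [k·w, (k+1)·w) anchored at pH 0 with default
width w = 0.1. The bin index uses a round-before-floor so that a value
sitting exactly on an edge (e.g. 5.7, which floats represent as
5.699999…) lands in the bin whose lower edge it is. Only non-empty bins
are reported; the number of non-empty bins is a property of the data, not
a constant of the method.

Within a bin, the weighted mean is M = Σ(Yᵢ·Wᵢ)/Σ(Wᵢ) with Wᵢ = nᵢ/o
(replicates over bin occupancy): better-replicated experiments count more
*within* a bin, while each bin enters the averaged regression with equal
weight — this removes the over-representation of heavily studied pH
ranges. `o` counts observations (not studies) per bin. Observations with
unknown replicate count receive the neutral weight 1/o and are flagged,
since the weighting rule is undefined without n. M is invariant to
rescaling all weights in a bin, and reduces to the plain mean when all
replicates are equal; both properties are asserted in tests.

## Model fitting and peak location

Degree-1 and degree-2 polynomials are fitted by (optionally weighted)
least squares on the raw Vandermonde design; adjusted R² =
1 − (1−R²)(n−1)/(n−p−1). The information criterion is the small-sample
AICc, `n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1)`, with k = p+2 counting the
Gaussian error variance as an estimated parameter — the convention of the
common model-selection packages, stated explicitly here because it changes
the correction term. The quadratic is selected only when it beats the line
by more than 2 AICc units; within the threshold the linear model wins on
parsimony and the tie is flagged. When n is too small for the correction
term (n ≤ p+3) the fit carries AICc = NaN and selection falls back to the
linear model. A perfect fit (rss = 0) carries AICc = −∞, so an exact
quadratic always beats a non-trivial linear competitor.

For a concave fit the peak is the vertex pH* = −c₁/(2c₂); a convex
quadratic has no peak (None), and a vertex outside the observed x-range is
flagged rather than suppressed. Peaks are reported at full precision with
a one-decimal rounding alongside, matching the precision at which such
peaks are conventionally published. Pointwise confidence bands for the
mean response are t-based, `t·√(σ̂²·x₀ᵀ(XᵀWX)⁻¹x₀)`; Monte-Carlo coverage
is verified at ~95% ± 3% in the suite.

The "coarse" fit uses every individual observation; the "averaged" fit
uses one weighted bin mean per bin. The averaged regression is unweighted
by default (each pH increment counts equally, which is the point of the
averaging); a `weight_bins` switch weights it by the bin weight sums for
sensitivity analysis.

## Gene meta-analysis

Abundances enter as copies per g dry soil. Published tables usually report
log₁₀ values; bin averages are computed on the **linear** scale and then
re-logged. The order matters: by Jensen's inequality log(mean) ≥
mean(log), with equality only for constant bins, and the suite asserts
this on random inputs. The (nirK+nirS)/nosZI ratio — N₂O-producing over
N₂O-consuming marker genes — is computed per sample only when all three
abundances are present; nosZ clade II is read and counted but never enters
the ratio (too few published records pair it with flux data to support an
analysis). Ratio-vs-pH fits use log₁₀(ratio) as the response in the
meta-analysis mode and the linear-scale ratio in the field-experiment
mode; the mode is explicit in every report. Flux–ratio coupling is a
linear fit of flux (µg N m⁻² h⁻¹) on log₁₀(ratio), slope sign reported.

## Incubation calculators

Headspace flux: F = ρ·V·ΔC·273/(273+T)·f_N/(W·Δt) in µg N kg⁻¹ h⁻¹, with
ρ = 1.964 kg m⁻³ (N₂O at 0 °C, 1 atm), f_N = 28/44 (mass fraction of N in
N₂O) and Δt the sealed-accumulation interval, default 6 h. The printed
form of this conversion in the source protocol carries no explicit time
divisor and does not say whether ρ is N₂O or N₂O-N density; this package
resolves the ambiguity by dividing by the sealed interval and converting
gas mass to N mass via f_N. All three constants are configurable and
echoed in reports. Headspace volume is taken as the full bottle volume
(soil volume not subtracted) — a documented simplification of the
protocol. Multi-timepoint series use the least-squares slope of ppm
against time (with r²); two-point series the difference quotient. Negative
slopes (net N₂O uptake) are reported as negative rates, never zeroed.

PDA is the same slope calculation on the acetylene-blocked slurry bottle,
reported in mg N kg⁻¹ h⁻¹ (the customary unit). The product ratio
N₂O/(N₂O+N₂) is net rate (no C₂H₂) over total rate (10% C₂H₂); noise can
push the raw quotient outside [0, 1], so it is clamped with a flag, and
clamping applies only to the ratio, never to the rates.

## Synthetic data

The generators emulate the structure of compiled global datasets rather
than any particular deposit: pH from a three-component normal mixture at
5.0/6.5/8.0 (sd 0.8/0.6/0.5, weights 0.3/0.5/0.2, truncated to 2.8–9.7),
which places roughly 60% of draws between pH 5.5 and 7.5; replicates
uniform on {3..6}; N rates uniform on 50–600 kg N ha⁻¹; control emissions
lognormal (median 1 kg N ha⁻¹); true EF from a concave quadratic peaking
at pH 5.99 with additive Gaussian noise (sd 0.5% EF). The fertilized
emission is constructed as E_N = E_O + EF_noisy/100·N, so the EF computed
downstream inverts the generator exactly at zero noise — a designed
inversion used as the identity test. Gene log-abundances are quadratic in
pH (nirK peaking at 6.0, nirS at 6.3) with flat nosZI; incubation pairs
are built from the linear product-ratio law (−0.082·pH + 1.265) and a
concave total-denitrification curve, translated to ppm slopes by an inline
dimensional analysis that never calls the flux calculator under test.

What the generators do **not** emulate: within-study correlation (all
observations are exchangeable), measurement-error structure that varies
with pH or laboratory, spatial/temporal autocorrelation of emissions,
publication bias, and the covariance between pH and covariates like SOC.
A passing recovery test therefore shows the estimators are consistent
under clean unimodal truth — not that real compiled data satisfy the
model's assumptions.

## Problem sizes and numerical choices

Default synthetic sizes — 2000 field observations, 500 gene samples, 35
incubation pairs — were chosen so a full pipeline run completes in well
under a second while leaving bin occupancies (tens per mid-range bin)
comparable in order to real compilations. Peak recovery on the default
field dataset is accurate to ≈ ±0.05 pH units (median over seeds ≈ 0.05;
the seed-to-seed 90th percentile is near 0.1, which is the intrinsic
precision of the vertex estimator at this size and noise level — not a
tolerance that further engineering can tighten without more data).

Degenerate inputs: rank-deficient designs (all x equal) raise with a named
condition; duplicate incubation timepoints raise; empty bins cannot occur
(only non-empty bins are materialized); an EF with n_rate ≤ 0 is a
domain error, not a NaN. Ties in model selection resolve to the simpler
model. All randomness flows through `numpy.random.default_rng(seed)`;
equal configs give byte-identical datasets.

## Limitations

* The default pH-conversion offsets are placeholders; region-calibrated
  maps are the user's responsibility.
* No random-effects meta-analytic variance model: the weighting is the
  fixed replicate-over-occupancy rule only, and no bootstrap or delta-method
  uncertainty is attached to peak locations.
* No mixed-effects or hierarchical structure for multi-site field
  experiments; site is carried as metadata only.
* Emission periods (seasonal vs annual cumulative) are stored as given;
  harmonizing accumulation periods across studies is out of scope.
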