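# Methods

## Tract-level SUHI intensity

The surface urban heat island intensity of an urban census tract is the
difference between the tract's mean land surface temperature and a rural
reference, `SUHI_t = LST_t − LST_r`, computed on aligned categorical
land-cover and LST grids:

- `LST_r` is the unweighted mean LST over **nonurban, nonwater** cells of
  the tract's urbanized area. If no such cell has valid LST the urbanized
  area has *no rural reference* and the computation fails loudly, naming
  the area.
- `LST_t` averages LST over cells assigned to both the tract and its
  urbanized area, so outlying portions of boundary tracts never
  contribute. Water cells are excluded by default, mirroring the
  rural-side nonwater rule; `include_water=True` restores the
  all-pixels-in-tract behavior, and the choice is recorded in run logs.
- Missing LST cells are dropped from both numerators. A tract with zero
  qualifying cells is skipped and logged, never emitted as NaN.
- A pixel is atomic: no area-weighting of partial boundary cells. When
  zone maps come from GeoJSON polygons, a cell belongs to a zone iff its
  center lies strictly inside the polygon (half-open convention; grids are
  row-major with a top-left origin).
- Invariant checks (uniform grid ⇒ SUHI = 0, translation cancellation) use
  an absolute tolerance of 1e-9 °C.

Because `rasterio` is not part of this stack, GeoTIFF I/O is implemented
directly with `tifffile`, writing and reading the standard
ModelPixelScale/ModelTiepoint georeference tags and the GDAL nodata tag;
polygon rasterization uses `shapely`.

## Exposure estimands and inference

Everyone residing in a tract is assigned the tract's SUHI intensity. The
exposure of a demographic group is the mean over *persons*, i.e. a
tract-level weighted mean with person counts as weights; the reported SD
is the population (not sample) form. Tracts where a group has zero count
contribute zero weight rather than being dropped; tract identifiers that
fail to join between the SUHI table and the demographics are logged and
excluded from both sides.

Group differences are estimated by weighted least squares of SUHI on a
group indicator over stacked (tract × group) observations, weights equal
to group person counts. This reproduces the difference of weighted means
exactly (the model is saturated in the indicator), while providing a
regression framework for robust covariance:

- **National and climate-zone scopes:** cluster-robust (CR1) sandwich
  errors by urbanized area, *t* reference with G − 1 degrees of freedom
  (G = number of areas) — conservative for small G. With a single cluster
  the code falls back to HC1 with a warning.
- **Per-city tests:** tracts are the units within one city, so errors are
  HC1. Per-city tests weight tracts by group population, keeping the
  per-city estimand identical to the national one. Cities missing either
  group are marked non-comparable and leave the tally denominator.
- Degenerate designs (saturated two-observation fits, exact fits with zero
  residual variance) return SE 0 and a p-value of 1 for a zero difference
  and 0 otherwise, rather than propagating division noise.

Model fitting is delegated to `statsmodels` WLS; the test suite verifies
the covariances against an independently coded sandwich formula and a
1000-resample cluster bootstrap.

Significance stars follow the three-level scheme * p<0.10, ** p<0.05,
*** p<0.01. Threshold tallies ("cities above 2 °C") use strict inequality;
ties count as not-above.

Kernel densities of city means use a Gaussian kernel with scipy's
Silverman bandwidth, evaluated on 512 points spanning the data range ± 3
bandwidths; curves are reported both unit-normalized and rescaled so the
area equals the number of cities (the convention for overlaying groups).
Identical means degenerate to a narrow spike with a warning.

## Kolm–Pollak index and EDE

For exposures x with weights w, total W and weighted mean x̄, the index at
aversion κ < 0 (units 1/°C so the exponent is dimensionless) is

    I(x) = −(1/κ) ln Σ_n (w_n/W) exp(κ (x̄ − x_n))

The weighted form generalizes the equal-weight 1/N version: individuals
within a tract share one exposure, so tract weights are person counts.
Evaluation goes through a max-shifted log-sum-exp, so exposure ranges of
10^6 °C at κ = −1 do not overflow. Jensen's inequality guarantees I ≥ 0
with equality iff exposure is perfectly equal; results with |I| below
1e-12·max(1, |x̄|) are clamped to exactly zero, since at that magnitude
the value is summation noise. The EDE is x̄ + I ≥ x̄. As κ → 0⁻,
I → |κ|·Var(x)/2, which the tests verify at κ = −10⁻³ within 1%.

The default κ is −0.5, labeled "moderate"; it is configurable everywhere,
always echoed in outputs, and κ-sweeps are first-class
(`kp_sweep`, `kappa_list` in run configs) since conclusions should be
shown stable across aversion levels. City indices are aggregated to zone
or national scope as population-weighted means over cities (weights = the
group's city population), and cross-group differences in mean city indices
use the same WLS machinery with cities as units, weighted by city group
population, with HC1 errors — both choices recorded here because the
aggregation convention is genuinely open.

## Synthetic-city generator

Each city is a disk on an n×n grid (default 40×40): an urban core
(radius 0.30 n) inside an urbanized-area disk (radius 0.48 n) whose
nonurban ring supplies the rural reference; outside the disk is
unassigned nonurban land. Water patches (2% of UA cells) and missing LST
cells (2%) exercise the exclusion rules. LST = rural base (30 °C) +
amplitude · Gaussian kernel of distance + N(0, noise²) per cell. Tracts
are contiguous equal-cell chunks of the disk in scan order (default 50
per city, echoing mid-sized urbanized areas at desk scale).

Demographics follow a multinomial-logit link: group g's share in tract t
has log-odds α_g + β_g·SUHI_t, so β_g ("disparity slope", 1/°C) is the
recoverable parameter; β > 0 concentrates a group in hotter tracts.
Person counts are **drawn multinomially** from those shares. Sampling
(rather than deterministically rounding share × population) is essential:
with deterministic counts every group under β = 0 weights tracts
proportionally, all null differences collapse to machine zero, and the
null distribution of the disparity test would be degenerate — the
multinomial draw gives the test a real sampling distribution while keeping
partition sums exact by construction. Age bands, which do not partition
the population, are independent binomials. Tract populations are
lognormal (mean 4000 persons, σ = 0.5).

Defaults are fixed at magnitudes typical of the multi-city summer-daytime
setting this package targets: amplitude 12 °C and noise 1.5 °C give a
population-weighted mean SUHI near 2 °C with SD near 2 °C, and the default
slopes (e.g. +0.16 for Hispanic and non-Hispanic Black, −0.24 for
non-Hispanic white, +0.14/−0.12 for below/above-2× poverty, small slopes
for age bands) produce people-of-color and poverty gaps on the order of
1–1.5 °C. Climate-zone labels (arid/snow/temperate/equatorial) are
assigned round-robin — they are grouping labels, not mechanisms, here.

Each city stores a truth record (tract SUHI, counts, per-group weighted
means and KP indices) computed by arithmetic independent of the analysis
modules; `truth_disparity` returns the realized gap, which must agree with
the pipeline estimator to 1e-9 °C. `expected_disparity` evaluates the
*superpopulation* gap — the large-panel limit of the national estimator,
using expected rather than sampled counts — and is the fixed target for
parameter-recovery experiments. Panels derive per-city seeds from the
master seed through counter-based `SeedSequence` spawning, so regeneration
is order-independent and byte-identical.

What the generator does **not** emulate: realistic urban morphology or
land-use patterns, spatially correlated LST noise, residential sorting
beyond the single logit link, ACS sampling error (margins of error are
ignored, as in typical tract-level practice), or calibrated facsimiles of
actual US cities. Passing tests therefore demonstrate correctness of the
estimators under the stated data-generating process, not robustness to
real-data pathologies such as spatial autocorrelation of residuals beyond
the urbanized-area level.

## Problem sizes and calibration conditions

Frequentist checks run at: 400 null panels (β = 0) of 40 cities × 50
tracts for type-I calibration of the clustered national test (nominal 5%,
accepted 5% ± 2%); 200 disparity panels for recovery (bias within twice
the Monte-Carlo SE; 95% CI coverage within 95% ± 3%); the
superpopulation gap evaluated over 20,000 expected-count cities. The SUHI
oracle equivalence uses 100 random grids up to 50×50 against a naive
double loop, compared exactly.

## Pipeline and reproducibility

`heat-equity run` validates inputs (grid alignment, duplicate tract ids,
join coverage with the exact missing ids listed, partition sums), then
emits the summary tables; any stage failure removes partial outputs and
reports the stage name. CSV floats are formatted at 6 significant digits
so reruns with identical config and seed are byte-identical; `run.log`
records package version, seed, and all design-decision toggles. Exit
codes: 0 success, 1 validation failure, 2 runtime failure.

## Known limitations

- Inequality metrics are limited to Kolm–Pollak/EDE; no Atkinson or Gini
  variants.
- Spatial dependence is addressed only through clustering by urbanized
  area, matching the estimand's design; no explicit spatial-autocorrelation
  model.
- SUHI is a surface (skin) temperature construct — a proxy for the urban
  contribution to heat exposure, not an air-temperature or humidity-based
  heat-stress index.
- Real-data reproduction requires externally obtained LST/land-cover
  rasters and census tables arranged into the bundle layout; the package
  itself ships no downloads.
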