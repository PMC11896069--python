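# Methods

This package implements an area-based approach (ABA) to forest inventory
from UAS-lidar point clouds for wet-Miombo woodland conditions: plot-level
forest structural attributes (FSA) — aboveground biomass (AGB, Mg/ha),
basal area (BA, m²/ha), mean diameter at breast height (DBH, cm) and stem
volume (Vol, m³/ha) — are regressed on canopy metrics computed from
height-normalized lidar returns over field-plot footprints. Because no
per-tree or per-plot data are distributed with the package, it ships a
synthetic-data generator that reproduces the statistical structure such a
study relies on, so every stage is testable end to end.

## Synthetic stands and lidar

**Terrain.** A sum of `n_components` random low-frequency sinusoids around
a base altitude. Each component carries `amplitude / n_components`, so the
surface's total relief is guaranteed within ±amplitude (peak-to-peak at
most twice the amplitude) and the minimum wavelength parameter keeps it
band-limited (default 60 m: gentle, dissected plateau relief rather than
rugged topography).

**Stands.** Tree counts are Poisson with mean stem density × area
(defaults 420 and 480 stems/ha for the two site templates); positions are
uniform. Species follow a categorical mixture. Each species' DBH is
lognormal, truncated to the 5 cm census threshold below and to 1.2× the
species' observed maximum above; the log-scale spread is set from the
species' diameter range as ln(max/min)/4 (a ±2σ reading of the range).
Height follows a site-level log-log curve ln H = c₀ + c₁ ln D + N(0, σ²)
with σ = 0.15 and a 27.5 m canopy ceiling; c₀, c₁ are fitted at
config-construction time to the per-species mean DBH/height pairs of the
two site templates, which differ deliberately (the first site is taller at
a given diameter than the second). Wood densities are representative
genus-level values (synthetic, 0.54–0.72 g/cm³).

**Crowns and echoes.** Crowns are vertically stretched ellipsoids with
radius 0.55·D^0.6 (m, D in cm) and depth 0.45·H. Pulses sit on a jittered
square grid at the configured density (default 300 pulses/m²). A pulse
intersecting crowns returns first from the highest crown envelope and
pierces the canopy with probability transmittance^(number of crowns)
(default transmittance 0.35); a piercing pulse ends in a ground echo, with
an intermediate echo on the second crown envelope when three echoes are
allowed. Open-ground pulses give single ground returns. All elevations
receive N(0, 0.03 m) ranging noise, and 0.1 % of returns are replaced by
gross outliers 20–80 m above/below the scene. The simulator keeps exact
per-return truth labels (ground / canopy / outlier) and the true terrain
elevation under every return.

What the generator does **not** emulate: radiometric intensity, full
waveforms, flight-line geometry and overlap, GNSS/IMU drift, understorey
vegetation layers, leaf-off conditions, and species-level crown shape
differences. Passing tests therefore demonstrate the correctness and
internal consistency of the processing chain under known truth, not
accuracy on any particular real acquisition.

## Point-cloud preprocessing

1. **Outlier removal.** For each point, the mean 3-D distance to its k
   nearest neighbours (default k = 10); points beyond the global mean +
   3 SD of that statistic are classed as noise (ASPRS class 7) and
   excluded downstream.
2. **Ground classification.** Progressive TIN densification: seed with
   the lowest return per coarse cell (default 20 m; use ~1/3 of the tile
   width for small tiles), add virtual corner vertices so the TIN spans
   the full bounding box, then iteratively accept points whose vertical
   distance to the enclosing facet is below 1.4 m and whose maximum
   point-to-vertex angle is below 8°. At survey-grade densities facets
   shrink to the point spacing and the angle test starts rejecting points
   that differ from the facet only by ranging noise, so points within
   0.2 m of the facet are accepted on distance alone; the angle rule
   still rejects vegetation, which sits well above that band.
3. **DTM.** Inverse-distance-weighted interpolation (power 2, 12
   neighbours) of ground returns to a 1 m raster; an exact hit returns the
   point's elevation. IDW is exact for constant fields and, with a
   point-symmetric neighbour set, for tilted planes; with one-sided
   neighbourhoods (tile edges, steep slopes) it biases toward the
   neighbourhood mean — tile buffers around plot footprints keep this out
   of the analysis area.
4. **Normalization.** Height = elevation − bilinear DTM sample. Slightly
   negative heights are retained; the 2 m canopy threshold downstream
   makes clamping unnecessary.

## Canopy metrics

Computed per plot (20 m radius circle, boundary inclusive; a 40 m
half-open grid mode is also provided) with a 2 m height threshold.
First-return statistics: height percentiles H1…H99 (linear interpolation
of order statistics, the "type 7" convention), mean height, and canopy
cover CC = first returns above threshold / all first returns. All-return
(above threshold) statistics: Hmax, variance/SD (sample, n−1), CV,
skewness and kurtosis (biased moment ratios; kurtosis non-excess),
MAD-median, quadratic mean, canopy relief ratio (mean−min)/(max−min), and
height-range decile densities Dk = share of returns above
min + k/10·(max−min). The published description of the density metrics as
shares above empirical height quantiles is degenerate (≈ 1−q by
construction); the height-range-decile reading implemented here is the
standard one and is monotone non-increasing in k. Gap fraction GF = 1 −
CC, floored at 10⁻⁴ before the Beer–Lambert inversion LAI = −ln(GF)/κ
with κ = 0.5 (configurable). Degenerate plots signal with NaNs rather
than invented values.

## Field attributes

Tree AGB (kg) = a·(ρD²H)^b with configurable coefficients (defaults
a = 0.0673, b = 0.976 — generic moist-tropical values, intended to be
replaced by locally fitted coefficients for real data); BA (m²) =
π(D/200)²; Vol (m³) = BA·H·f with form factor f = 0.74. Wood density is
looked up by species, then genus mean, then (opt-in) table mean. Plot
sums scale by 10⁴/area to per-hectare; plot DBH is the arithmetic mean
(quadratic mean available).

## Model selection and fitting

Collinearity screen: among predictor pairs with |Pearson r| > 0.85
(resolved in descending |r|, alphabetical tie-break), the member less
correlated with the response is dropped; constants are dropped first.
Best subsets: exhaustive OLS of ln(y) over all subsets up to the maximum
size, scored with R², adjusted R², predicted R² (leave-one-out PRESS via
the hat matrix), Mallows' Cp against the full screened model, and
Gaussian-likelihood AICc/BIC with k = p + 2 parameters:
AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1), BIC = n·ln(SSE/n) + k·ln(n).
Ranking is by AICc ascending with smaller subsets preferred on ties.
The default maximum subset size is 7 (the largest published ABA equations
of this kind use seven predictors); the end-to-end study runs use 5, a
prudent cap for n = 16 plots per site. Predictions back-transform as
ŷ = exp(Xβ̂)·exp(MSE/2); the multiplicative factor corrects the
lognormal retransformation bias, and MSE uses the unbiased n−p−1
denominator.

## Evaluation

RMSE, Bias, and their percentages of the mean observed attribute
(switchable to mean predicted); R² is the squared Pearson correlation of
observed vs predicted. Cross-validation uses seeded random folds (sizes
differing by at most one), pools the out-of-fold predictions, and applies
the statistics once to the pooled table (k = 10 by default, clipped to n).
Transfer applies one site's fitted model to the other site's plots
without refitting. In the synthetic two-site study this reproduces the
expected qualitative ordering: site-specific models fit tightest,
combined-data models are intermediate, and transferred models are worst,
because the two site templates differ in height–diameter allometry and
species structure.

## Problem sizes and determinism

End-to-end study runs (tests and `scripts/acceptance.py`) use 16 plots
per site and 25 pulses/m² — a deliberate test problem size that keeps a
full two-site run under a minute while leaving >100k returns per plot
tile; the ground-filter and DTM accuracy benchmark runs at the full 300
pulses/m² on a 30 m tile. Per-plot tiles are 46 m squares (20 m plot
radius + 3 m buffer), so off-plot crowns overhang plot edges as in
reality. All randomness flows from one root seed through
`numpy.random.SeedSequence` splits; identical seeds give bit-identical
tree lists, clouds, folds and reports.

## Known limitations

- The echo model is binary per crown (pierce or stop): no partial
  returns, no intensity, at most one intermediate echo.
- The terrain is smooth by construction; the ground filter is not
  exercised against break lines, ditches or buildings.
- IDW DTMs bias toward the neighbourhood mean on slopes with one-sided
  neighbour sets (tile edges).
- With 16 plots per site, best-subsets selection is variance-dominated:
  the chosen predictor set varies between replicates even when the
  generating process is fixed. This mirrors the instability that
  small-sample ABA studies report, and is why the evaluation relies on
  pooled cross-validation rather than fit statistics.
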