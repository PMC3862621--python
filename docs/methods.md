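# Methods

## Data model

The experimental unit is a *diurnal temperature regime*: 16 h at a cool
temperature and 8 h at a warm temperature, both drawn from
{5, 10, …, 40} °C with cool ≤ warm, giving 36 regimes.  Each regime is
observed as three replicates of 50 seeds; the response is the endpoint
germination percentage (germinated/total × 100 after 15–20 days).
Internally regimes are always stored as (cool, warm) with cool ≤ warm;
files use explicit `cool_temp`/`warm_temp` columns so the ambiguous
"30/5 vs 5/30" notation cannot arise.

A `GerminationMatrix` holds, per regime, the mean percentage and a
half confidence-interval width, plus a set of regimes flagged optimal.
For the three packaged cultivar matrices both numbers and flags are
transcribed fixture data; the flags are carried as printed even where
they disagree with the classification rule below (one cell per cultivar
at most), because the published flag set is the ground truth the profile
statistics are defined against.  Means and half-CIs are stored at full
precision; table-parity reports round half-away-from-zero to one decimal.

### Confidence intervals

The half-CI of a replicate record defaults to the t interval on the
replicate percentages, t₍₁₋α/₂, n−1₎ · SD/√n with α = 0.05.  How the
published ± values were actually derived is not stated beyond "from
regression equations", so a second method, `regression_se`, is provided:
the prediction standard error of a quadratic surface fitted to the
replicate-level percentages.  Published half-CIs in the fixtures are
treated as given data and never re-derived.

### Synthetic replicates

Replicate-count fixtures are generated from the matrix means: the pooled
count is round(mean × 1.5) out of 150, split as evenly as possible over
three replicates.  This reproduces every transcribed mean at one decimal
except one cell ('Savannah' at 20/20 °C, printed 13.7 %), which is not an
integer count out of 150; the fixture uses 21/150 = 14.0 % there.  These
files exercise the replicate-level I/O and aggregation paths; they do not
carry real between-replicate variance, so half-CIs computed from them are
not the published ones.

## Optimal-regime classification and profile statistics

A regime r is optimal when mean(r) ≥ max − half-CI, evaluated with a
small numerical guard (10⁻⁹) so a cell exactly on the boundary counts as
optimal.  Two rule variants exist: `own_ci` (default) uses each cell's
own half-CI; `max_ci` uses the maximum cell's.  The maximum regime(s)
always qualify; ties for the maximum are all retained, with the
row-major-smallest (cool, warm) as the canonical maximum.

The six profile statistics are means over the unrounded cell values,
reported rounded half-up to one decimal.  Share-of-regimes statistics use
the design size 36 as denominator; non-triangular matrices are rejected
upstream.  "Some germination" means a strictly positive unrounded mean.

## Polynomial response surfaces

The basis is the full bivariate monomial set in canonical order (for
total degree k = 0…d, terms T₁^(k−j)T₂^j for j = 0…k), 6 terms for the
quadratic and 21 for the quintic.  Temperatures may be divided by a
`normalizer` before expansion (40 °C = the design maximum) — this changes
coefficient scale, not the fitted surface — and an `orientation` decides
which of (cool, warm) occupies the T₁ slot.  Responses are germination
fractions in [0, 1]; predictions are clamped to [0, 1] at use time, with
the unclamped value exposed for diagnostics and residual work.

OLS fitting uses statsmodels (giving coefficient standard errors); the
bisquare backend is an explicit IRLS loop: residual scale = MAD/0.6745
re-estimated each iteration, Tukey biweight with tuning constant 4.685,
convergence when the coefficient change falls below 10⁻⁸ or after 100
iterations (non-convergence is flagged on the result, not raised).  R²
for every backend is computed on unweighted residuals so backends are
comparable on one scale.  When the robust scale collapses to ~0 (an
exact fit) the loop stops; nothing is left to down-weight.

### Transcribed published equations

Nine fitted equations (three cultivars × quadratic / quintic+bisquare /
quintic+BP-ANN) ship as a checksummed fixture.  Two metadata items were
resolved by calibration against the cultivar matrices rather than taken
from their source's caption:

- **Orientation.**  Although the equations are captioned with T₁ = cool,
  every one of the nine only reproduces its observed surface with the
  *warm* temperature in the T₁ slot (e.g. the *C. dactylon* quadratic
  evaluated warm-first at the 15/35 °C maximum gives 0.863 vs the
  observed 0.873; cool-first is wildly off).  `calibrate_orientation`
  re-derives this choice by maximizing R² over both orientations.
- **Normalizer.**  Quadratic and quintic+bisquare coefficients
  (magnitudes 10⁻⁷–10⁻¹) are raw-temperature equations; quintic+BP-ANN
  coefficients (magnitudes up to ~700) only make sense with inputs
  divided by 40.

The quintic+bisquare fixtures reproduce their published R² almost exactly
(e.g. 0.919 recomputed vs 0.9191 printed for 'Princess VII'), validating
the transcription.  The quintic+BP-ANN equations are kept as fixtures but
not used for precise numeric work: their four-significant-digit
coefficients cancel heavily and the evaluation is numerically fragile.

## The BP-ANN and its quintic projection

Architecture: 2 inputs (cool, warm, each divided by 40 °C) → 10 sigmoid
hidden units → 1 linear output; targets are germination fractions, so no
output squashing is needed.  Weights and biases initialize uniformly in
[−0.5, 0.5] from a seed; training is full-batch on the summed squared
error for 10,000 epochs and is bit-reproducible from the seed.

Width 10 was chosen as the smallest round width that comfortably
out-fits the quintic OLS surface while training in about a second; the
epoch count follows the convention of running the forward/backward
cycle about ten thousand times.

**Optimizer.**  The default trainer is resilient back-propagation
(Rprop): each weight keeps its own step size, grown ×1.2 while its
gradient sign is stable and halved (with the step skipped) on a sign
flip, clipped to [10⁻⁶, 50], starting at 0.01.  Plain full-batch gradient
descent with momentum is available as `optimizer="gdm"` (learning rate
0.05, momentum 0.9), but on these 36-cell matrices it is not usable as a
default: with the summed-error gradient the steps oscillate into sigmoid
saturation and the network degenerates to predicting the mean (R² ≈ 0),
and rescaled or per-pattern variants stall around R² 0.88–0.92.  Rprop
reaches network R² ≈ 0.95–0.99 on all three cultivars across seeds while
remaining a classic batch back-propagation scheme.  Divergence (non-finite
loss) raises immediately with advice to reduce the step.

**Projection.**  The trained network is sampled on a regular
30 × 30 mesh restricted to the cool ≤ warm triangle of [5, 40]² — the
region where data exist; the unobserved warm < cool corner is never
sampled — and projected onto the 21-term quintic basis by *weighted*
least squares, the weights being triangle quadrature weights (interior
cell corners ¼ each, diagonal half-cells ⅙ per vertex).  The weights
matter: with a plain masked grid the staircase boundary moves with the
sampling density and the projection converges only linearly, whereas the
weighted version is a proper midpoint/vertex quadrature of the continuum
L² projection and converges quadratically (measured max prediction
changes at the 36 regimes: 0.035 for 30→60 points per axis, 0.0095 for
60→120, 0.0025 for 120→240).  Because the trained network is rough, a
few hundred points per axis are needed for 10⁻³-level stability; the
default of 30 is kept for speed, as the scientific conclusions
(projection R² ordering) are insensitive to it.

The projected quintic's in-sample R² is necessarily ≤ the directly
fitted quintic OLS R² (OLS optimality) and in practice exceeds the
quadratic OLS R²; both the network R² and the projected-quintic R² are
reported, clearly labelled, since they answer different questions.

## Suitability mapping

A fitted model is applied cell-wise to a monthly climate grid: the
monthly mean daily minimum temperature plays the cool (16 h) role and the
monthly mean daily maximum the warm (8 h) role, by direct substitution
with no day-length weighting.  Predictions are clamped to [0, 1] and
scaled to percent; nodata propagates.  Cells outside the 5–40 °C
calibration range are still evaluated but counted as `extrapolated_cells`
in the map's provenance — extrapolation is allowed but loud.

Grids are cell-centered regular lat/lon meshes.  I/O formats: ESRI ASCII
grid (standard 6-line header, rows north→south, nodata −9999, 6-decimal
values — lossless at that precision) and a long CSV
(lat, lon, month, tmin, tmax).

### Synthetic climate generator

The generator emulates the broad structure of a mid-latitude monthly
temperature climatology: monthly mean maximum =
base_temp − base_gradient·|lat| + amplitude·cos(2π(m − m_peak)/12) +
Gaussian noise, with the warm peak in July north of the equator and
January south; the monthly minimum sits `diurnal_range` (default 10 °C)
below the maximum, applied after the noise so tmin ≤ tmax always holds.
Defaults (base 32 °C at the equator, gradient 0.55 °C/degree, amplitude
12 °C, noise SD 0.5 °C) give subtropical-to-temperate values over a
China-like 20–50° N box.  The generator does **not** emulate topography,
continentality, humidity effects or interannual variance, so map-level
tests demonstrate the mapping contract (pointwise evaluation, clamping,
nodata, I/O) and qualitative seasonality — e.g. northern mid-latitude
winters map to ~0 % suitability — not real-geography accuracy.  Mapping
real regions requires observational grids, which are outside the package.

## Numerical choices and degenerate inputs

- Table-parity rounding is half-away-from-zero at one decimal.
- R² requires ≥ 2 observations and a non-zero total sum of squares;
  constant observations raise.
- Rank-deficient polynomial designs (e.g. all regimes on a line) raise
  with the deficiency named, as does a degenerate projection grid.
- Optimality comparisons use a 10⁻⁹ guard against float representation
  of one-decimal percentages.
- Ties for the matrix maximum: all tied regimes retained; canonical
  `max_regime` is the row-major smallest.
- Matrix CSV floats are written with `repr` and parsed in round-trip
  mode, so write→read is bit-exact.

## Known limitations

- Only endpoint germination percentages are modelled; germination
  time-courses are out of scope.
- The published equation coefficients are not re-derived by refitting —
  the original fits used replicate-level data and software defaults that
  are not recoverable; fits here are to the 36 cell means by default
  (replicate-level fitting is possible via the constructor arrays).
- No significance testing between cultivar maxima and no coefficient
  inference beyond OLS standard errors.
- The projected quintic inherits the polynomial's inability to track
  sharp network features; its R² typically sits between the quadratic
  and the direct quintic OLS fits.
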