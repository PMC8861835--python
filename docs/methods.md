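# Methods

This note documents the models implemented in `mesopred`, the design of
the synthetic data that exercises them, and the numerical choices a user
should know about.

## Step-selection model

An integrated step-selection function (iSSF) treats each observed hourly
movement step as the chosen alternative in a stratum of 1 observed + 10
available steps.  Available step lengths are drawn from a gamma
distribution fitted by maximum likelihood (location fixed at 0) to the
*observed* step lengths of the animals being analysed; available turning
angles are uniform on (−π, π] relative to the previous observed bearing.
Sampling availability from anything other than the observed-step
distribution biases the movement terms and lets spatially structured
covariates absorb the residual, so the pipeline always re-estimates the
gamma; the constants quoted in the documentation (shape 0.38, scale
1402.57 m for the full season; 0.38/1177.75 pre-encounter and
0.41/1413.39 post-encounter) are the simulator defaults.  Step length
and its natural log enter every model as movement terms, which corrects
the tentative gamma toward the selection-adjusted distribution.

When the analysis runs on a synthetic landscape, available endpoints
falling outside the mapped area are redrawn: the availability
distribution is truncated to the study area, matching what the simulated
animal could actually do.  Strata are only formed from contiguous
hourly triples (gap tolerance 5 min); missing fixes split bursts and no
interpolation is performed, because interpolation would manufacture
movement.

The conditional (per-stratum multinomial) log-likelihood is maximized by
Newton–Raphson with step-halving; convergence requires a relative score
norm below 1e−8 within 50 iterations, and a coefficient exceeding 25 in
absolute value raises a separation error naming the covariate (all
design columns are standardized, so legitimate coefficients are small).
The naive covariance is the inverse observed information; the robust
covariance is the sandwich with per-stratum scores summed within animal
(the cluster).  With a single animal the sandwich is rank-deficient and
the fit falls back to the naive covariance for inference.

QIC is computed as −2Q + 2·tr(Â V̂_r) with Â the naive information and
V̂_r the robust covariance (Pan's 2001 form); when robust and naive
covariances coincide the trace equals K and QIC reduces to −2Q + 2K, an
identity the tests assert.  The five-model candidate set is: the base
model (step length, ln step length, and ten habitat covariates:
distances to road/aspen/forest, elevation, TPI, TRI, shrub height, bare
ground, herbaceous and sage-height fractions) plus the four
combinations of direct/indirect risk (lion) and reward (kill) terms.

## Direct metrics

The direct assessment of a source set at a query fix is the minimum,
over sources with timestamps at or before the query ("time since" is
strictly past-looking), of distance (km) × elapsed time (days).  Both
factors are floored (1 m, 60 s) so the log transform is always defined;
kill events are timestamped by the kill's first lion fix (configurable).
Query fixes with no past source drop their whole stratum from iSSF
designs, with a log entry.  Units cancel out of standardized regression
coefficients; km·days is used for interpretability.

## Encounters

An encounter candidate is one coyote fix and one lion fix within 1 km
and 2 h (both thresholds inclusive — the conservative reading of
"within").  Qualifying coyote fixes at consecutive nominal intervals
merge into one bout; the bout ends when the criterion fails.  An
encounter starting less than 5 h (strict) after the previous retained
encounter's end for the same coyote is discarded; the gap is measured
from the previous encounter's end, since an encounter cannot be "within
five hours of" one that has not ended.  Encounters are detected per
coyote–lion dyad and pooled per coyote for the independence filter.

Movement rates are consecutive-fix displacements on the nominal
schedule, evaluated only before the bout starts and after it ends.  The
rate model is a gamma-family (log link) penalized additive model:
smooth of signed time-to-encounter, cyclic smooth of hour of day
(period 24 h), random intercepts for coyote and encounter; non-positive
rates are floored at 1 m/h.  The encounter iSSF samples availability
with separate pre/post gamma distributions and interacts each main
effect (cos turn angle, shrub and tree proportions in a 256-m-diameter
buffer — half the mean step length — distance to the lion's most recent
fix, TRI) with standardized time-to-encounter.

## Kill-site use

Rings are half-open upper-inclusive annuli, ring k covering
(100(k−1), 100k] m; the ten ring areas sum exactly to the 1-km disc.
Day bins are 24-h multiples of the first lion fix at the kill; pre-kill
days count backwards (day 3 = the third day before the kill).  A kill
enters the pre (post) model only if a coyote fix fell inside 1000 m
(inclusive) during the 14 days before (after) the kill.  Each eligible
kill contributes exactly 10 × 14 binary records per window.  The
fix-rate adjustment divides raw counts by the obtained/expected fix
fraction; when several collars contribute, the mean rate of the
contributing collars is used.  Probability-of-use predictions are
reported at the median local count, ring-1 area and fix rate 1, giving
single curves in day and in ring distance; the ring curve is evaluated
at the fitted peak day.

## Penalized-smooth engine

Smooths are cubic P-splines: B-spline bases on uniform (unclamped)
knots with second-order difference penalties, so constants and
linear-in-x functions span the exact penalty null space; the cyclic
variant wraps basis and penalty at the stated period.  Bases are
centered (sum-to-zero) with the level carried by the intercept.  Random
intercepts are ridge-penalized dummy blocks — a deliberate
simplification of full mixed-model machinery that is adequate for the
intercept-only groupings used here.  Fitting is penalized IRLS with
step-halving on the penalized deviance; smoothing parameters (one per
term, bounded to 10^±[−4,10]) minimize GCV for the gamma family and
UBRE-style deviance + 2·EDF for binomial (known scale), via Nelder–Mead
on log-λ.  The final fit solves an augmented least-squares system
(square-root penalty rows), which stays accurate when a λ is pushed to
extremes; a tiny relative ridge (1e−8 of the mean information diagonal)
bounds the condition number when the data barely constrain a null-space
direction.  EDF is tr[(X'WX + S_λ)⁻¹ X'WX], per-term over the term's
columns; term p-values are Wald-type on the penalized block with EDF
degrees of freedom and are flagged approximate.  Model comparison uses
AIC = deviance + 2·EDF_total.  Backwards elimination repeatedly removes
the removable term whose removal most decreases AIC and stops when no
removal helps.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions the analyses assume:
hourly coyote fixes over a 15 May–30 Sep season with 89.8% independent
fix success; 3-h lion fixes; lion kill residencies exponential with
mean 4.5 days (the observed t_first→t_last span is shorter by roughly
half a fix interval plus flooring, ≈4.38 days in large samples); kill
sites clustered within 50 m; 30-m landscape grids with Gaussian-filter
spatial autocorrelation, a three-class escape-cover map in which shrubs
≤0.5 m tall are reclassified open, and Euclidean distance-to-feature
layers.

Coyote tracks are the generative dual of the iSSF: 50 candidate steps
per hour from the availability distribution, one chosen with
probability ∝ exp(β·z) on grid-standardized layers.  The default truth
is avoidance of the lion occurrence surface (−0.5), mild selection for
the kill-site surface (+0.3), and two habitat effects (+0.15
herbaceous, −0.2 bare ground); no response to actual lion or kill
positions.  The truth occurrence surfaces mix a mild habitat
association with an independent autocorrelated latent field — an
occurrence model trained on another species' data carries information
beyond the focal species' habitat covariates, and surfaces built purely
from base-model layers would be collinear with the base model.  Lions
travel as correlated walks, by default biased toward their own
occurrence surface; the model-ranking recovery scenario uses unbiased
lions so the direct and indirect lion covariates are not confounded
through lion habitat selection.  Replicate-based checks use 2 coyotes ×
900 steps (ranking) and single 2,000-step tracks (coefficient
coverage), sizes at which the effects of interest are comfortably
identified.

What passing tests on these data do *not* show: the simulator has no
home-range attraction, no GPS positional error, no temporal variation
in behaviour (apart from what encounter conditioning induces), and its
landscapes are stationary Gaussian fields rather than real terrain.
One emergent property is worth noting: because encounters happen more
often while the simulated coyote is moving fast, movement rates near
encounters are elevated even though the animals do not react to each
other — the same selection effect that complicates interpreting rate
peaks around encounters with ambush predators on real data.

## Known limitations

- The GAMM layer is a self-contained P-spline engine, not a clone of
  any published implementation; EDFs and p-values can differ in detail
  from other software even when fitted curves agree.
- Indirect occurrence surfaces may be supplied as external rasters (the
  faithful path for real data) or fitted internally with a
  random-forest used/available classifier; the internal path is a
  generic stand-in, with provenance recorded on the surface object.
- Rasters are plain-text ESRI ASCII grids; for large real datasets a
  GeoTIFF reader should be put behind `grids.Landscape`.
- Boundary conventions the source data leave open (inclusive
  thresholds, tie-breaks, day/ring binning) are fixed as documented
  above and exposed as parameters where they plausibly matter.
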