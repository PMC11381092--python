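# Methods

This note records the models, parameter choices and numerical conventions
behind `murretrax`, and what the synthetic-data generator does and does not
emulate.

## Behaviour model

Each GPS fix is one observation row with four channels: wing-beat frequency
(Hz), body pitch (degrees), per-interval maximum depth (m) and great-circle
distance from the colony (km).  The two native streams run at different
rates (GPS every 1 or 3 min, depth at 1 Hz and 0.1 m resolution); depth is
summarized to the fix interval (interval maximum) before classification so
the hidden Markov model stays a standard one-row-per-fix model.

The latent state is one of COLONY, FLY, SWIM, DIVE (fixed order; Viterbi
ties break toward the lower index for determinism).  Channels are
conditionally independent given the state.  Pitch is Gaussian.  The three
non-negative channels are exactly zero outside their active behaviour —
depth is 0.0 at the surface, wing-beat 0.0 when not flapping, colony
distance 0.0 on the ledge — so they use a zero-inflated gamma emission:
a point mass `pi0` at zero plus Gamma(shape, rate) on the positive part.
This handles the exact zeros natively instead of forcing a continuous
density through them.

Fitting is Baum–Welch EM over multiple deployments as independent
sequences sharing parameters.  The E-step uses the scaled forward–backward
recursions; the forward log-likelihood is also the quantity reported per
decoded sequence.  The M-step fits each state × channel emission by
weighted maximum likelihood (gamma shape by Newton on
`log a − ψ(a) = log m − mean(log x)`); when the positive part of a channel
degenerates the update is capped, and the M-step keeps whichever of the
candidate and incumbent parameters has the higher weighted likelihood, so
the algorithm is a generalized EM and the total log-likelihood is
non-decreasing by construction (asserted every iteration).  A state whose
total responsibility falls below 1e−8 raises a degenerate-state error
naming the state rather than silently collapsing.  Initialization is
either an explicit starting spec, physically informed defaults, or k-means
over the standardized channels with clusters mapped to behaviours by their
channel means (deepest → DIVE, fastest wing-beat → FLY, nearest the
colony → COLONY); optional seeded random restarts keep the best
log-likelihood.  Missing channel values drop out of the emission product;
an all-missing fix is decoded from the transition structure alone.

The number of states and the emission families are modelling choices of
this package; no attempt is made to mirror any particular HMM package's
defaults.

## Segmentation rules

* **Dive**: maximal run of the 1 Hz depth trace with depth ≥ 1.0 m (10×
  the sensor resolution; configurable).  Runs separated by at least one
  surface second, or by a break in the trace, are distinct dives.
* **Bout**: consecutive dives whose surface gap (next start − previous
  end) is ≤ the 5-minute post-dive interval.  The boundary convention is
  ≤ (a gap of exactly 5 min stays in-bout); the interval itself is the
  field-standard criterion and is configurable.
* **Trip**: maximal interval between leaving and re-entering the COLONY
  state, bounded by the adjacent colony fixes when present.  Trips
  touching a deployment edge are flagged truncated: they contribute dives
  and distance but are excluded from duration means.
* **Foraging trip**: more than one dive, or exactly one dive deeper than
  18.1 m (strictly greater).  The depth rule keeps single prey-delivery
  dives while dropping near-colony preening dips.
* Deployment-level diving metrics are computed over the dives of foraging
  trips only (a switch exposes the all-dives alternative); per-day rates
  divide by deployment days; metrics with nothing to average stay missing
  rather than zero.

Behavioural sexing uses diel nest attendance: females on the nest
consistently 23:30–03:30 and males 11:30–15:30.  "Consistently" is
operationalized as ≥ 80% of in-window fixes decoded COLONY on every
observed night/day (configurable).  The windows are applied in local solar
time (UTC + longitude/15 h, east-positive), the reproducible choice given
that the original field clock convention is not recoverable; birds
satisfying both windows or neither, and deployments under 24 h, return
UNDETERMINED.

## Energetics

DEE (kJ/day) is the activity-budget linear combination with rates
COLONY 32.0, FLY 532.8, SWIM 100.8, DIVE 97.2 kJ per hour of activity,
normalized by deployment duration and scaled to 24 h.  Each fix owns the
interval to the next fix; the final fix owns the median interval.
Unclassified or missing time contributes zero energy but remains in the
denominator (a `renormalize` flag switches to classified-time
normalization).  By construction DEE is scale-invariant in duration and
bounded by the minimum and maximum rate × 24 when the budget fills the
deployment.

## Space use

Diving locations (only DIVE-state fixes; swimming, flying and colony fixes
are excluded) are projected to an azimuthal-equidistant plane centred on
the colony on a sphere of radius 6371 km — radial distances from the
colony are exact and the error versus an ellipsoid is below 0.5% at the
≤ 150 km scale of the data.  The UD is an isotropic bivariate-normal KDE
on an 800 m grid with the ad hoc reference bandwidth
`h = (sd_x + sd_y)/2 · n^(−1/6)` (sample SDs).  The grid pads the point
bounding box by 3h per side and the density is renormalized to unit mass,
so truncation never violates normalization.

Isopleths use ranked-cell accumulation: the p% region is the smallest set
of cells, in descending density order, holding p of the mass; its area is
the cell count × cell area.  Polygon output (for display) is the union of
the cell squares.

Bhattacharyya affinity between two UDs on a common grid is
`BA = Σ √(p₁ p₂) · cell²`.  When grids differ, both are resampled
(nearest-cell, piecewise-constant) to the union extent at the finer cell
size and renormalized.  Because foraging-range comparisons are usually
stated between 95% ranges, the default masks each UD to its own 95%
isopleth and renormalizes before computing BA; `mask_fraction=None` gives
the unmasked affinity.  Whether the original ranges were renormalized
before overlap is not recoverable, so both variants are one flag apart.

## Environmental covariates

Ice (%) and SST (°C) arrive as daily lon/lat rasters.  A bird's covariate
is the unweighted mean over all cells whose centre lies within 130 km
great-circle distance of the colony (≤ convention at the boundary; the
radius is the maximum observed foraging range) and all calendar days
intersecting its deployment window — any partial day counts.  Cells are
unweighted (no cos-latitude area weighting; a flag enables it), missing
cells are excluded, and the radius mask is pooled across years.

## PCA and rotation

Metric tables are reduced by correlation PCA (variables standardized to
zero mean, unit sample variance), so the eigenvalues sum to the number of
variables.  Components with eigenvalue strictly greater than 1 (Kaiser)
are retained; with ≥ 2 retained, loadings are varimax-rotated by the
classic pairwise planar-rotation algorithm with Kaiser row normalization.
The rotation is orthogonal, preserves per-variable communalities to 1e−10,
and the criterion trace is exposed and non-decreasing.  Component signs
are arbitrary, so each loading column is flipped to make its
largest-magnitude loading positive — interpretation is invariant, and the
convention makes downstream regressions reproducible.  Scores use the
regression method `Z L (LᵀL)⁻¹`; they are exactly centred on the fitting
sample.  "Strongly loaded" for reporting means |loading| ≥ 0.5
(configurable).  PCA pools all deployments per metric set by default;
stratified runs are a caller-side subset.

## Biomarkers and model selection

Foraging success is `∆ = log(post) − log(pre)` in natural logarithm for
mass and each analyte; values must be strictly positive.  Assay QC:
intra-assay CV is the mean over plates of the within-plate control
CV (100·SD/mean, sample SD), inter-assay CV the CV of plate means.

Collinearity screening removes terms iteratively — interactions before
main effects, worst first — using VIF = 1/(1−R²) > 5 for single-df terms
and the Fox–Monette GVIF^(1/(2·df)) > 2.2 for multi-df terms, computed
from determinants of the predictor correlation matrix.

Candidate fixed-effect structures are fitted by maximum likelihood
(statsmodels: MixedLM with a bird-level random intercept when repeats
exist, otherwise OLS) and ranked by AICc
`= −2ℓ + 2k + 2k(k+1)/(n−k−1)`, where k counts fixed effects plus the
residual variance plus the random-intercept variance when present (stated
because conventions differ).  Akaike weights are normalized within the
candidate set.  The top model is compared to the nested null by a
likelihood-ratio χ² test.  Selected models are refitted by REML for
coefficient t-statistics; the denominator df uses the residual
approximation n − p (simpler than a Satterthwaite approximation and
conservative only in small clusters; documented here since the choice is
not standardized).  A singular REML fit (random-intercept variance at the
boundary) falls back to OLS and is flagged.  Marginal and conditional R²
follow the variance-partition definitions
`r²m = σ²_f / (σ²_f + σ²_r + σ²_e)` and
`r²c = (σ²_f + σ²_r) / (…)`, with σ²_f the sample variance of the
fixed-effect predictions.  No multiple-testing correction is applied
across responses, matching the per-model workflow this layer supports.

## Synthetic data

The generator is the package's test bed and defines its study conditions.
Defaults: 20 birds, even sex ratio, 2-day deployments, 3-min fixes,
1 Hz depth, 4 trips/day with ~2.5 h mean duration, colony at
62.95°N 82.01°W.  Each bird alternates colony attendance with trips;
within a trip, behaviour follows a first-order Markov chain over
FLY/SWIM/DIVE at fix resolution (matching the decoder's model class so
parameter-recovery tests are well-posed), with commute legs forced to FLY.
Movement is kinematic: 75 km/h flight toward a per-trip target, small
drift while swimming/diving, and a forced flight home so every trip closes
at the colony.  Dive maximum depths are lognormal with log-location
log(18 m) — so the sample median matches the 18.1 m single-dive threshold
regime — and log-SD = sd/mean; each dive is a symmetric 1 Hz V (the
simplest shape with unambiguous maximum depth and duration); within-bout
surface gaps are 30–90 s and between-bout gaps exceed the 5-min interval,
with bout sizes ~1 + Poisson(mean−1).  Females are held at the colony
23:30–03:30 solar and males 11:30–15:30.  Wing-beat and pitch are drawn
from the truth HMM's emissions given the state; per-fix depth and colony
distance come from the physical dive/track simulation.

Ice rasters decline linearly from 90% over a 62-day season with a smoothed
seeded spatial anomaly, clipped to [0, 100]; SST rises from −1 to 8 °C.
Biomarker panels draw positive lognormal pre-values per analyte and plant
`log(post) = log(pre) + Σ effect·covariate + N(0, noise_sd)` with
standardized per-bird covariates (default noise SD 0.3 on the log scale,
a realistic residual spread for plasma metabolites).  Planted behavioural
effects act multiplicatively: trip rate × exp(−effect·ice_z), trip
duration and dive-depth median × exp(+…), mirroring the
fewer-longer-deeper pattern the analyses are designed to detect.
Everything is a pure function of the scenario seed: identical seeds give
identical output.

What the generator does **not** emulate: autocorrelated GPS error, dive
shapes beyond the V, prey fields, oceanographically realistic ice
dynamics, semi-Markov dwell times, or covariate-dependent transition
probabilities.  Passing tests therefore demonstrate correctness of the
computational chain and recoverability of planted effects under the
model's own assumptions — not robustness to the messiness of real field
data.

## Problem sizes used in the test-bed runs

The self-checks run at desk scale by design: exhaustive-path HMM oracles
use 2–4 states and sequences of ≤ 10 fixes (200 random cases); transition
recovery uses 20 two-day deployments at 3-min fixes; the planted-effect
selection study uses 100 seeded runs of 100 birds each, decoding with an
HMM fitted once from physically informed starting values.  The kernel-UD
reference checks use single-point and few-hundred-point UDs where the
analytic answers are closed-form.

## Known limitations

* The HMM assumes first-order dynamics and state-independent fix
  intervals; dwell-time distributions are geometric.
* Ranked-cell isopleths are grid-resolution-limited; areas of very peaked
  UDs depend on cell size.
* The nearest-cell UD resampling is mass-preserving only approximately on
  very coarse grids (renormalization restores unit mass exactly).
* MixedLM variance components come from a numerical optimizer; agreement
  with closed-form balanced-design estimators is at optimizer tolerance
  (~1e−5 relative), not machine precision.
* Degrees of freedom for REML t-statistics use the residual approximation,
  which is anti-conservative for few clusters with many repeats.
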