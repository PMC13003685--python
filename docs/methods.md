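# Methods

This note documents the models, conventions, and numerical choices behind
`divetrace`, and what the synthetic-data tests do and do not demonstrate
about real tag data.

## Behavior-log standardization

Satellite depth-transmitting tags report alternating *dive* and *surface*
records with minimum/maximum estimates of depth and duration (the depth
sensor is accurate to about ±1%, hence the bracket); analyses use the mean
of each bracket. Because onboard dive-detection thresholds differ across
deployments, records are standardized to a common dive definition before
any analysis: a record remains a dive iff depth ≥ 50 m **and** duration ≥
120 s (both configurable); everything else becomes surface time, and
consecutive surface records merge. The rule is deliberately conjunctive —
a 400-m, 100-s record is reclassified, as is a 49-m, 300-s record. Total
covered time is conserved exactly by construction, standardization is
idempotent, and raising either threshold can only reduce the dive count.

Quality control is a report, not a mutation: implausible depths (negative,
or beyond 3,000 m), duration/interval mismatches beyond 60 s, record
overlaps, and a transducer-drift proxy (a rolling minimum of reported dive
depths regressed on time; a slope above 2 m/day flags the deployment). The
drift proxy is a documented stand-in for vendor-specific transducer QC.

## TDR processing

1-Hz depth series are zero-offset corrected against a rolling surface
baseline (a low quantile of readings shallower than 15 m per 30-min window,
interpolated and subtracted). Dives are maximal excursions at ≥ 10 m.
*Duration* is the time between the threshold crossings (number of in-dive
samples × the sampling step); this makes dive time plus non-dive time equal
the record length exactly. *Bottom time* is the time at ≥ 80% of the dive's
maximum depth, and the bottom-time fraction of duration sets the shape code
(square > 0.5; u in (0.2, 0.5]; v ≤ 0.2 — ties resolved by the strict
inequalities). Note a boundary artifact of these definitions: an ideal
symmetric triangular dive has bottom fraction 0.2·max/(max − threshold),
always marginally above 0.2, so triangles classify as *u*; genuinely
spike-like dives (brief deep excursions within longer shallow phases)
classify as *v*. Descent/ascent rates are depth change over time from the
threshold crossing to the first/last bottom-phase sample. Dives truncated
by the record edge are flagged partial and excluded by default; dives
within 2 m of a configured sensor ceiling are flagged saturated (depth is
a lower bound). No hysteresis is applied at the 10-m threshold.

## Diel and lunar geometry

Solar elevation uses standard low-precision solar ephemeris formulas
(declination, equation of time, hour angle), geometric, without refraction;
the accuracy contract is ±0.5°, ample for a 12°-wide twilight band. Civil
diel categories: *day* above +6°, *night* below −6°, and *dawn*/*dusk*
inside the band according to whether elevation is increasing over a ±5-min
window. At the study latitude the band takes ≈ 50 min to cross.

Moon phase is the mean synodic phase: 2π·frac((t − t₀)/29.530589 d) with t₀
the new moon of 2000-01-06 18:14 UTC. It is exact at the epoch, monotone,
and periodic; it omits the few-hour wobble of the true anomalistic cycle,
which is far below the resolution of a cyclic spline on [0, 2π).

Surface records spanning category or clock-hour boundaries are split; dives
are never split and take the label of their start time (configurable to
midpoint). Splitting finds boundaries by a coarse scan plus bisection to
1 ms, so child durations sum exactly to the parent. Local clock time is
Hawaiian Standard Time, fixed at UTC−10 with no daylight saving. For data
without geolocation, the deployment locality supplies the diel position.

## CTCRW track model

Each planar axis carries position and an Ornstein–Uhlenbeck velocity,
dv = −β v dt + σ dW, giving velocity autocorrelation e^(−βΔt) and
stationary speed ~ Rayleigh(σ/√(2β)). The exact Gaussian transition over
each irregular time step drives a Kalman filter whose observation noise
comes from each record's error ellipse. Stored ellipses are treated as 95%
ellipses: the 1-σ covariance is the ellipse rotated from
diag((a/√5.991)², (b/√5.991)²), orientation measured clockwise from north;
axes floor at 10 m, and GPS fixes without ellipses get a 50-m circular 95%
ellipse. The likelihood is maximized over (log β, log σ) by Nelder–Mead
with dispersed restarts (tolerance 1e-8 on the objective). The initial
state is the first fix with zero velocity, position variance (100 km)², and
stationary velocity variance — this prior is part of the model definition
and is reproduced by the brute-force joint-Gaussian likelihood oracle in
the tests. Updates use the Joseph form for covariance stability.

All math is planar (km) on a spherical azimuthal equidistant projection
centered on the median fix; distances from the center are exact and
distortion is negligible at deployment scale.

Smoothing (RTS) provides positions and covariances at arbitrary times; the
95% position-ellipse semi-major axis is √(5.991·λmax). Multiple imputation
uses forward-filter backward-sampling on the union of observation and
request times, so across-imputation moments converge to the smoother's.
Dives whose 95% semi-major axis exceeds 4 km are excluded from spatial
analyses (strictly greater; the semi-major axis is the screening quantity,
chosen and exposed in config since the convention is not standardized).

Prefiltering removes fixes implying speeds above 5.5 m/s — but only when
the displacement exceeds a 1-km floor, because near-simultaneous noisy
fixes imply arbitrary speeds without being evidence of a bad location —
and out-and-back spikes (turn angle < 15° with both legs > 2.5 km).
Rerouting moves any point shallower than the 20-m isobath to the nearest
sufficiently deep grid cell; it is nearest-cell, not path-topology-aware.

## Covariates

Rasters are xarray grids. Seafloor slope is a Horn 3×3 gradient with
latitude-scaled cell sizes. Current magnitude is √(u²+v²); chlorophyll is
log10-transformed with non-positive values as nodata. Extraction is
nearest-cell — dive positions carry km-scale uncertainty, so sub-cell
interpolation is spurious precision — and daily fields match on the HST
calendar date, with the 30-day lag applied by date arithmetic before
lookup. Dives in chlorophyll cells flagged as land-contaminated are
dropped. Predictor screening computes pairwise Pearson correlations on
complete cases and, within any pair with |r| > 0.5, keeps the
higher-priority member; the default priority puts 30-day-lagged
chlorophyll above the contemporaneous product and SST.

## Near-seafloor classification

For each candidate dive (95% ellipse ≤ 4 km), seafloor depth is extracted
beneath each of K = 20 imputed positions. A dive is a probable
near-seafloor dive iff the sample (n−1) SD of the K seafloor depths is
≤ 100 m (spatial-precision filter) and |max seafloor − dive depth| ≤ 100 m.
The ± reading allows dives up to 100 m deeper than the deepest plausible
seafloor. The depth/seafloor ratio is computed at the smoothed
point-estimate position. With zero location error the chain reduces exactly
to the depth-difference rule, and it is monotone in both thresholds. The
classifier is intentionally conservative: under realistic location noise a
large fraction of genuinely near-seafloor dives on steep terrain fails the
SD filter, which is the designed behavior, not a defect.

## Dive metrics

Dive rate = dives ÷ summed duration of dive and surface records, so
transmission gaps never inflate denominators; per-category rates therefore
recombine exactly to the total dive count. Hourly model units are
animal × HST-date × hour cells with the count of dives starting in the hour
and the covered fraction; cells under 75% coverage are dropped. Group
summaries are medians (or proportions) per animal first, then mean, SD and
CV across animals — never pooled dives — and single-animal groups report SD
and CV as absent. Inter-dive surface durations are censored when a data gap
longer than 10 min hides part of the interval. Depth bins are labeled by
their upper edge (a 75-m dive falls in bin "100").

## Penalized-smooth models

Dive depth and duration are Gamma with log link; hourly dive counts are
negative binomial with log link and an offset of log covered-hours (so the
model is a rate model, and doubling covered time exactly doubles the
expected count on the link scale). Time of day (period 24 h) and moon phase
(period 2π) use cyclic cubic regression splines; other covariates use
shrinkage thin plate splines, all with basis dimension k = 5. Smoothness is
selected by REML with an additional double penalty, so uninformative terms
shrink toward zero effective degrees of freedom — implicit variable
selection via both the shrinkage basis and the double penalty. Individual
variation enters as either a random intercept per animal or a random factor
smooth (per-animal cyclic deviation curve on time of day, shared smoothing
parameter); the structures are compared by conditional AIC (the
penalized-edf AIC of the REML fit) and percent deviance explained.
Fitting is delegated to mgcv through `Rscript` — the reference
implementation of this estimator — while this package owns the
specification, data contract, serialization, and prediction surfaces.
Effect curves condition all other covariates on their training means with
random terms excluded ("typical individual"), with 95% intervals from the
link-scale standard errors; a basis-adequacy k-index is reported with each
fit, with no automatic refit.

## Synthetic data

The generator emulates a deployment campaign on an island-associated
population of deep-diving delphinids. Defaults: 16 animals for ~13 days of
behavior data each; CTCRW with β = 1 h⁻¹ and σ = 4 km·h^−1.5 (median speed
≈ 3.3 km/h); ~12 locations/day with 1.5-km-scale 95% ellipses; dive onsets
from an inhomogeneous Poisson process averaging 0.45 dives/h with a
sinusoidal diel intensity; log dive depth = log 180 m + diel cosine
(amplitude 0.2) + lunar cosine (amplitude 0.1) + slopes on standardized
current magnitude (+0.15), mixed layer depth (+0.10) and lagged log₁₀
chlorophyll (−0.15) + N(0, 0.55); durations coupled to depth by a Gaussian
copula targeting Spearman 0.7 (the realized value in full scenarios is
lower, ~0.5–0.6, because near-seafloor replacement and gap truncation break
the coupling for a subset of dives); 15% of dives over water deeper than
55 m track the seafloor at depth − U(0, 50) m; reported min/max brackets are
±1% so their mean is exact. Records below a per-tag threshold pair (30 m,
60 s — emitted as dives when deeper **or** longer, per onboard truncation
logic) dissolve into surface time, and an optional dropout process deletes
record blocks (default off). Bathymetry is a smooth analytic island slope
(abyssal 3,500 m, 45-km shelf scale) with a shallow bank; environmental
fields are smooth Gaussian random fields evolving as a daily AR(1) on a
coarser grid (≈ 8 km), with a land flag on the chlorophyll layer.

What passing tests show: the estimators invert their own generative models
(CTCRW recovery and calibration, GAMM effect recovery and shrinkage,
classifier performance under known truth) and every bookkeeping identity
holds exactly. What they do not show: robustness to behaviors absent from
the generator — Argos duty cycling, heavy-tailed location errors,
depth-bin quantization of onboard summaries, behavior-state switching, or
prey-field structure beyond smooth covariate fields.

## Problem sizes and numerics

The test suite runs scaled-down versions of every stochastic check (e.g.,
20 CTCRW recovery replicates of ~500 locations; 20-replicate shrinkage and
structure-selection experiments at n = 800–1,500; a 3-animal end-to-end
determinism run), chosen so the whole suite completes in a few minutes.
All randomness flows from explicit seeds through `numpy` `SeedSequence`
spawning; reruns are bit-identical. Degenerate inputs are rejected with
messages (non-positive rates, overlapping records, unsorted bins, K < 2);
covariance matrices are symmetrized and eigenvalue-clipped before sampling;
timestamps are forced to nanosecond resolution before sub-second interval
arithmetic.
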