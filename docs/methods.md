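# Methods

This note documents the models and procedures implemented in petrelbio,
the defaults chosen where the design was genuinely open, and what the
synthetic tests do and do not demonstrate about real data.

## Trip geometry

GPS fixes are assumed WGS-84 decimal degrees; no projection is used and
all distances are great-circle (haversine) on a sphere of R = 6371 km,
which is accurate to well under 0.5% at foraging-trip scales. The speed
filter is a single forward pass: a fix is dropped when the implied speed
from the last *retained* fix exceeds 25 m s⁻¹; the first fix is always
kept, which makes the filter idempotent.

On-land records are removed by a colony-radius rule (default 1 km)
rather than a coastline polygon; a trip is a maximal run of ≥3 fixes
outside the radius, bracketed by the nearest inside fixes. Home range is
the convex hull of trip locations (duplicates dropped first; hulls built
in lon/lat, which is adequate at sub-degree extents), with area from the
sum of spherical-triangle excesses (l'Huilier) times R².

The bimodality coefficient uses the bias-corrected sample skewness and
excess kurtosis, so its large-sample limits are 5/9 for a uniform and
1/3 for a normal distribution; 5/9 is the flag threshold. Modes are
estimated by 1- vs 2-component Gaussian mixtures on untransformed hours,
selected by BIC; zero-variance fits fall back to a single mode.

## Ethogram

*Static/dynamic split.* The static component is a centred running mean
over 1 s (25 samples at 25 Hz) with the window shrinking at the edges,
so static + dynamic reconstructs the raw signal exactly.

*Spectral features.* Per-second non-overlapping Fourier spectra of the
heave axis, DC excluded; the dominant cycle is the inverse of the argmax
frequency and the amplitude is 2|c|/N at that bin. A windowed Fourier
spectrum was preferred over a continuous-wavelet transform because it
yields the same dominant-cycle/amplitude features at 25 Hz with far
simpler, directly testable numerics.

*Flap separation.* K-means (k = 2, k-means++ with 10 restarts, fixed
seed) on the standardized (cycle, amplitude) features; the cluster with
the higher mean amplitude is flapping. A deployment whose features are
all identical is flagged all non-flapping with a warning.

*Water vs air.* Non-flapping seconds are rafting when the per-second raw
heave s.d. is ≤ 0.12 g **and** the static heave lies in the water band
(0.70–0.95 g); otherwise they are gliding flight. The water band is this
package's decision: it encodes the observation that the static heave
level differs between a bird sitting on water and one holding its wings
in glide, with the defaults calibrated on the synthetic signal model
below. Labels are smoothed by a 3 s majority vote to remove
single-second flicker before foraging detection.

*Foraging.* A second is foraging when the bird is not flying (label
raft) and the *minimum* within-second pitch is below −25°; the minimum,
not the mean, so that 1–2-sample strikes are not averaged away.
Pressure-detected dive seconds also count as foraging, and override the
label to raft (a submerged bird is not flying). Foraging seconds
separated by ≤ 5 s merge into one foraging event; an event containing a
dive second is a dive event. Activity budgets report flap/glide/raft
percentages (summing to 100) with foraging reported separately since it
overlaps rafting; hourly profiles use local solar time = UTC +
longitude/15 h.

## Dives

Depth is D = 0.01 (Pm − Pa). Zero-offset correction subtracts a rolling
2% lower-quantile baseline (10 min window; a window longer than the
series degrades to a global baseline). Because a low quantile of noisy
surface samples sits ~2.05 σ below the true surface, the sensor noise
σ is estimated robustly from lag-1 differences (MAD/0.6745/√2) and the
corresponding offset added back; this leaves noise-free drifts and
constant offsets exactly removed and noisy surfaces unbiased.

Dives are maximal excursions above a 0.1 m surface band (≈2 σ of a
5 mBar sensor) whose maximum depth strictly exceeds 0.55 m (one body
length). Boundaries are refined to the interpolated zero crossing; with
≥2 samples on the descent leg the crossing is extrapolated from the
leg's fitted line, since the bracketing surface sample is noise rather
than a point on the leg. Descent duration runs from the refined start to
the time of maximum depth; the fleet descent rate is the zero-intercept
least-squares slope of maximum depth on descent duration across dives.
In repeated synthetic recovery this estimator carries a small (~1–2%)
downward bias from the residual start-time uncertainty at 1 Hz sampling,
well inside the 5% recovery tolerance used in the tests.

The duration-to-depth estimator for pressure-less loggers assumes a
symmetric V-shaped dive, so depth = rate × duration / 2. The halving is
an inference: it reproduces the reference mean duration/depth pair
(3.1 s, 1.3 m) exactly at the 0.84 m s⁻¹ rate, but a direct use of
descent duration cannot be ruled out from the published description.

Cross-validation counts a pressure dive as detected when any
acceleration-derived foraging event overlaps it within ±2 s.

## Effort grid and environment

Grid cells are half-open squares [k·0.04°, (k+1)·0.04°) anchored at 0°
(the anchoring is this package's convention). Foraging seconds on the
1 s interpolated track are summed per cell and standardised to percent
of the trip's foraging total. Environmental layers are matched by
nearest spatial neighbour (tolerance one grid step) of the temporally
nearest slice to the cell's mean foraging timestamp; cells outside a
layer's extent get a missing value, never a silent zero. A Spearman
rank-correlation table between covariates is reported for the user, but
no variables are dropped automatically.

## Dimorphism and isotopic niche

Storer's index is 100 (m♂ − m♀) / (0.5 (m♂ + m♀)), rounded to one
decimal only at reporting. SEA is π√(λ₁λ₂) from the n−1 sample
covariance; SEA_C multiplies by (n−1)/(n−2). SEA_B places a vague
normal-inverse-Wishart prior on the covariance with df = dim + 1 and a
near-zero scale matrix (10⁻⁶·I, a numerical stabiliser): at per-mil²
covariance scales (~0.03–0.05 ‰²) an identity-scale prior would dominate
the posterior and roughly double the area, whereas the near-Jeffreys
choice is data-dominated, matches the analytic π σx σy on large Gaussian
samples within Monte Carlo error, and keeps the point SEA_C inside the
95% credible interval on well-behaved data.

## The synthetic biologger

Defaults encode the study conditions of the reference population: a 48 h
trip within 150 km of the colony at ~18 km h⁻¹ flight speed; behaviour
fractions 51.4% flapping, 13.7% gliding, 34.9% rafting; 2.7 foraging
events h⁻¹ of mean duration 1.2 s, 25% of them dives; dives descending at
0.84 m s⁻¹ to 0.7–2.0 m; a 0.3 s wingbeat cycle of 0.4 g amplitude on
the heave axis; a 0.15 g air/water static-heave offset with 0.2 Hz,
0.05 g wave modulation on water; 5 mBar pressure noise at 1 Hz; GPS
fixes every 3 min. Foraging seconds impose a −40° static pitch and
elevated surge/sway dynamics (so foraging has the highest VeDBA,
followed by flapping, then gliding ≈ rafting), while their heave
dynamics stay water-like so the rule-based classifier can recognise the
second as on-water.

Two generator choices matter for estimator recovery. Dive start times
and descent durations are aligned to the 1 Hz pressure grid
(duration rounded to whole seconds, depth = rate × half-duration), so
the V apex is always sampled; without this, 1 Hz sampling under-reads
the apex by up to rate × 0.5 s (~15% at 1.3 m depth) and no descent-rate
estimator on the sampled maxima could recover the configured rate.
Second, dives are strictly V-shaped with equal descent and ascent rates,
making the duration-to-depth estimator exactly recoverable by design.

What the generator does **not** emulate: wind and wave fields, prey
patches, logger orientation drift and attachment artefacts, GPS fix
loss, irregular sampling, or behaviours outside the five modelled
states. Passing tests therefore demonstrate that the pipeline's
estimators are correct and self-consistent under the stated signal
model, not that the classifier would reach the same accuracy on real
loggers, where thresholds (water band, τ_water, surface band) would
need calibration against visualised data.

## Problem sizes and determinism

The test suite analyses ten full 48 h deployments (seeds 1–10) for the
end-to-end recovery checks and shorter 2–6 h deployments for unit-level
checks; large-sample analytic limits use 2×10⁴–10⁵ draws. Every source
of randomness (simulator, K-means, mixture fits, posterior draws) is
seeded; identical configs and seeds give byte-identical outputs, and the
pipeline writes a manifest with config hash, input checksums and seeds.

## Known limitations

- Gliding and rafting are separated only by the static-heave band; a
  logger mounted at an unusual angle would need the band re-calibrated
  (the axis map is configurable).
- The duration-to-depth halving rule is an inference (above).
- Trip segmentation by colony radius cannot distinguish on-land rest
  from near-colony rafting; an optional land polygon is out of scope.
- Mixture-based mode estimation fits at most two components, matching
  the short/long dual-strategy question it serves.
- The zero-intercept fleet regression assumes a common descent rate;
  heterogeneous fleets are summarised but not modelled.
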