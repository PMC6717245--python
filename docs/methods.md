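# Methods

## Model and assumptions

The estimator treats a migration corridor monitored by three co-located
sensor systems: a four-hydrophone array recording low-frequency calls,
a narrow-field infrared camera detecting blows, and daytime visual
observers. Whales are assumed to transit the corridor on straight,
shore-parallel paths at constant speed (default 1.6 m/s), so the time a
whale spends in a sensor's search area is path length over speed: for
the array, the 2,280 m along-migration extent gives t̄ = 23.75 min; for
the camera, the arc subtended by the 6.2° horizontal field of view at
offshore range r is 2π·(6.2/360)·r, averaged over the sighting-derived
offshore distribution (≈1.7 min for ranges near 1.5 km).

The cue rate is r̂ = N̂_C / (N̂_W · P̂_SA · t̄_SA). The estimator takes
N̂_W (daily abundance with a 95% credibility interval) as an external
input and propagates only that interval into the rate bounds; P̂_SA,
t̄_SA, and the counts are treated as known. Seasonal averages count each
whale twice (a southbound and a northbound pass), because calls
accumulate over both passes while the abundance model counts southbound
passage once; daily rates use southbound passes only, with the
(1 − ĉ_N) factor removing calls attributable to northbound or milling
whales.

## Detection corrections

**Probability of localization.** A call is localizable if its
received SNR — source level minus transmission loss minus noise —
clears a 0.5 dB threshold on the *weakest* of the four hydrophones.
P̂_L(cell, minute) is the fraction of source-level realizations (100 by
default) that clear it; the per-minute value is the unweighted mean
over grid cells in the search area. Transmission loss is pluggable and
defaults to spherical spreading, 20·log₁₀(range); the machinery, not
ocean acoustics, is the point. Minutes with P̂_L < 0.5 are declared
no-effort: their detections are dropped and they accrue to P_NE. The
effort quantum is the minute, following the per-minute noise series.

**Effective camera range.** Cumulative blow detections and cumulative
sightings are evaluated on a common range grid; their ratio is constant
while the camera sees everything and falls once it does not. The
change-point maximizes the improvement of a two-segment weighted
least-squares line fit over a single line, with weights equal to the
cumulative sighting count (the ratio's sampling variance shrinks
roughly as one over that count; unweighted fits let the noisy
small-count head of the curve dominate and misplace the break). If the
two-segment fit improves relative SSE by less than 2%, the curves are
deemed proportional and the maximum observed detection range is
returned with a degenerate flag. The blow analysis window is half-open,
(500 m, 2100 m]: inside it P_D = 1 and the false-cue proportion is
zero, so the blow correction reduces to scaling by video coverage,
1/(1 − P_NE).

**Day/night comparison.** The share of detections inside the daily
watch window (default 07:30–16:30, i.e. 9/24 of the day) plus a
two-sided Wilcoxon rank-sum test on per-hour counts, exact by full
enumeration when both groups have ≤ 20 untied values, otherwise the
normal approximation with tie correction. All-identical counts return
p = 1 directly, since the rank statistic is then degenerate.

**Visibility.** Frame contrast is the population variance of per-row
mean grey intensities; translation-invariant, zero for a featureless
frame.

## Camera geometry

Ranges come from the elevated-observer geometry on a sphere: pixel rows
below the calibrated horizon row map linearly to depression angles
within the 5° vertical field of view; adding the horizon dip
arccos(R/(R+h)) gives the depression β below the horizontal, and the
geocentric angle to the target is γ = β + arcsin(((R+h)/R)·cos β) − π/2,
so range = R·γ. This matches the flat-earth h/tan β to ~0.3% at 1 km;
the curvature correction grows as d³/(2Rh) and reaches ~1% near 1.9 km
for a 28 m camera. No refraction correction is applied by default; an
effective-earth-radius multiplier (k ≈ 7/6 for standard refraction) is
exposed. Azimuths interpolate linearly between the calibrated true
bearings of the image edges. Positions use spherical forward/inverse
geodesics (sub-metre consistency below 10 km, verified by round trip);
the spherical model was chosen over an ellipsoid because every range in
play is under 10 km, where the difference is far below the sighting
bearing error of ±1°.

## Calling-rate extrapolation

A two-term power model f(x) = a·x^b + c (x = day index, x = 1 on
1 December) is fit to daily calling rates by Levenberg–Marquardt least
squares. Initialization is deterministic: c₀ = min(rate), and (a₀, b₀)
from a log-log regression of rate − c₀ + ε on day; exactly constant
input short-circuits to (a, b, c) = (0, 1, mean) with zero covariance,
since b is then unidentifiable. The 95% non-simultaneous (pointwise)
prediction interval uses the delta method: f(x) ± t_{dof,0.975} ·
√(σ̂² + gᵀVg), with g the coefficient gradient, V the coefficient
covariance, σ̂² = SSE/dof, floored at zero. In the linear special case
(b = 1) this reduces to the textbook regression prediction interval,
which the tests verify against the closed form.

Back-estimation divides each acoustic-only day's corrected call count
by the extrapolated rate, P̂_SA, and t̄_SA; the period minimum uses the
upper prediction bound per day. Because abundance diverges as the rate
approaches zero, rates at or below a configurable floor (default 1e-6
cues/whale/day) are refused for the point estimate, and a lower
prediction bound below the floor caps the whale upper bound at the
floor-based value with a warning rather than returning infinity. For
December back-estimation the non-southbound proportion ĉ_N is taken as
zero (no sightings exist then to estimate it).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the ocean: straight constant-speed tracks (configured count per
day, southbound with probability 0.9 by default, entry times uniform in
the day); offshore distances from a piecewise-uniform distribution on
(185 m, 9.4 km) with band weights 0.08 / 0.53 / 0.24 / 0.15 over the
cuts at 500 m, 2.1 km, and 3 km — placing 53% of whales in the camera's
analysis band and most of the rest inside 3 km, as the sighting record
shows; calls as a per-whale Poisson process at the configured daily
rate over corridor residence (default rate curve 1.22e-6·x^3.79 + 3.39
calls/whale/day); blows as a renewal process of bouts of 2–4 blows
20–30 s apart separated by 180–240 s dives, every quantity drawn
uniformly and independently within its range (the midpoint cycle's
long-run rate, ≈42 blows/hour, sits inside the observed 27–67
blows/whale/hour span). Sensor thinning retains a cue iff it is inside
the sensor's range window, its minute is on effort, and a Bernoulli
detection draw succeeds; camera records get pixel rows by inverting the
range mapping. One global seed drives per-stage generators derived via
stable hashes, so every stage is reproducible independently.

What the simulator does *not* carry: curved or milling tracks, pod
structure, diel calling patterns (none is defaulted; the daily rate
function is the only time structure), source-level variation coupled to
behaviour, or weather-driven detectability. Passing tests therefore
demonstrate the estimators are self-consistent under the model's own
assumptions — unbiased recovery of configured rates, correct interval
coverage, correct change-point recovery — not that those assumptions
hold at sea.

## Numerical and design choices

- Problem sizes in tests: end-to-end rate recovery uses ~10,000
  whale-hours (25,000 simulated transits, 3-sigma Monte-Carlo
  tolerance); interval coverage and change-point recovery use 100
  replicates each.
- Offshore proportions are group-size weighted (each whale counts, not
  each pod); a pod's offshore range is the mean over its sightings and
  its size and direction are the last values recorded.
- Condition cutoffs are strict: Beaufort and visibility must be < 5.
- Range intervals are half-open (min, max] throughout.
- Per-day corrected counts are computed by correcting within the day
  and summing, not by applying a daily-mean probability.
- The rank-sum exact/asymptotic crossover is n = 20 per group.
- Rates are reported in calls/whale/day and blows/whale/hour; transit
  times are stored in minutes and converted explicitly.

## Known limitations

- The effective-range change-point assumes a single break; a gradually
  degrading sensor yields a flat-ish improvement curve and may trip the
  degeneracy guard.
- The prediction interval is first-order (linearized); strongly curved
  likelihood surfaces (tiny a with large b) can make its coverage
  approximate, which the coverage test bounds empirically.
- Uncertainty in P̂_SA, t̄_SA, and the counts themselves is not
  propagated, mirroring the estimator's design; rate bounds reflect
  abundance uncertainty only.
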