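# Methods

## Coordinate and unit conventions

Tracking tables arrive in image coordinates (pixels, y growing downward) and
are converted to millimetres by a single scalar ruler calibration
(`mm_per_px`); the unit state is explicit on every trajectory and feature
extraction refuses uncalibrated input.  Frame indices are 0-based and
contiguous, the time of frame *i* is *i*/fps seconds (default fps 294.1),
and all ethogram segments are half-open frame intervals `[start, end)` that
tile the annotated span with strictly alternating phases.  Angles are
reported in degrees in (−180°, 180°], always measured against the image
horizontal with the vertical flipped to up-positive.  The inter-D3 angle θ
is the orientation of the left→right D3 vector; only *changes* in θ enter
any downstream statistic, and those are invariant to the reference-axis
choice.  The head angle Θ uses the same y-up convention on the eye-minus-
circle-centre displacement, with an optional horizontal flip for mirrored
camera setups.

## Quality masking

Tracking quality in the source studies was curated by manual refinement and
exclusion of visibly bad sections, not by confidence thresholding.  The
masking operation therefore defaults to a likelihood floor of 0.0 (no
masking) and accepts explicit exclusion intervals; both mechanisms are
idempotent and commute.  Masked samples keep their raw values under the mask
and propagate as missing (NaN) through every derived feature — no
interpolation or imputation is performed by default, mirroring the exclusion
approach.  Detectors split traces at missing samples and evaluate peak
prominence within each finite run.

## Phase statistics

The switch rate is the number of segment boundaries interior to the
annotated span divided by the total annotated duration; bout-duration
distributions use interior segments only, because the first and last
segments are truncated by the video with unknown true durations.  The duty
cycle (oromanual time over total time) uses *all* segments: truncation
biases a time-fraction far less than a duration distribution, and the
exclusion rule in the source protocol names durations and switching
frequency only.  Whether the switch-rate denominator should be annotated
time or full video time is ambiguous; annotated time is used.

## Mode clustering

k-means runs on the raw (L, D) millimetre pairs without standardisation
(both axes are commensurate distances), for k = 1..10 with 10 random
restarts per k keeping the lowest-SSE solution, seeded by the caller and
echoed in the result for reproducibility.  The cluster count is chosen by
the L-method: for every candidate knee c, straight lines are fit to SSE
points 1..c and c..k_max (sharing the knee point) and the candidate
minimising the point-count-weighted sum of the two residual RMSEs wins,
ties breaking toward fewer clusters.  With two clusters, the one with the
smaller L centroid (hands at the mouth) is labelled oromanual.  An
all-identical input short-circuits to a degenerate single cluster.

Density maps are smoothed 2D histograms on a 128×128 grid over the fixed
[0, 20]² mm support: counts are binned, then convolved with a Gaussian
kernel using a per-dimension normal-reference (Scott) bandwidth
σ·n^(−1/6), truncated at the support boundary (zero padding) rather than
boundary-corrected.  Each map is normalised to a maximum of 1, the
cross-animal average is the mean of the normalised maps, and contours are
traced at 10 % of each map's maximum by marching squares.  Truncation
instead of a boundary transform slightly depresses density within a
bandwidth of the support edge; the 10 % contour of data a few millimetres
from the boundary is insensitive to this.

## Maneuver detection and measurement

Regrips are local maxima of D with topographic prominence ≥ 0.75 mm whose
rising and falling flanks each contain a single-frame slope exceeding
88 mm·s⁻¹ in magnitude.  "Steep in either direction" is read as *both*
flanks steep (regrips are symmetric transients); a config switch
(`both_flanks=False`) implements the one-flank reading.  The slope
estimator is the maximum absolute one-frame finite difference times fps,
evaluated between the peak and its prominence base — the simplest estimator
at ~3.4 ms frame spacing.  No pre-smoothing is applied by default.

Sniffs are maxima of −L_ventral with raw value ≥ −2.5 mm (dips reaching
2.5 mm), prominence ≥ 1 mm (freely moving) or ≥ 2.5 mm with half-prominence
width ≤ 600 ms (head-fixed), and pairwise separation ≥ 250 ms, conflicts
resolving to the more prominent peak and then the earlier one.  The height
criterion applies to the raw trace value, not a baseline-referenced height.
The manual post-hoc curation used on real videos is replaced by an optional
exclusion list; nothing is auto-curated.

Event amplitude is |series(peak) − baseline| with the baseline the mean of
the pooled samples 300–100 ms before and 100–300 ms after the peak; events
whose windows leave the trace are flagged invalid and left unmeasured.
FWHM is the time between the linear-interpolated crossings of
(baseline + peak)/2 adjacent to the peak; if no crossing exists before the
neighbouring event, the prominence base stands in and the event is flagged.
Because the baseline windows extend across phase boundaries at 250–300 ms
bout durations, the measured baseline sits slightly below the local D level
around a regrip, which widens measured FWHM a few milliseconds beyond the
2.3548 σ width of an isolated Gaussian pulse — an inherent property of the
windowed definition, reproduced faithfully.

## Regrip microstructure

Burst periodicity: regrips with inter-event intervals ≤ 300 ms form groups;
each group's D segment (padded 300 ms on both sides) is mean-subtracted and
autocorrelated to ±300 ms lag, normalised by its zero-lag value, averaged
across groups, and the mean is min-max normalised to [0, 1].  Mean
subtraction and per-segment normalisation before averaging are necessary
choices: a raw-offset autocorrelation is DC-dominated and has no interior
peaks.  The central peak's extent is defined as reaching the first
positive-lag local minimum; the periodicity is the reciprocal of the lag of
the largest local maximum beyond it.

The asymmetry index integrates each hand's 2D path length (D3 as the
per-hand proxy point — the only consistently tracked bilateral landmark)
over the 40 ms window centred on the regrip peak and reports
(right − left)/(right + left): 0 for equal travel, ±1 for unimanual events,
missing if neither hand moves.  The rolling CV is std/mean over a centred
40 ms window, missing where the window mean is non-positive; windows whose
centres fall within 20 ms of a regrip peak form the regrip-adjacent
partition.  Grip-angle change takes the median θ over −60..−20 ms as
baseline and reports median |θ − baseline| over that epoch and over
+20..+60 ms.

## Head angle

Pratt's algebraic circle fit minimises the algebraic distance of
a(x²+y²)+bx+cy+d under the constraint b²+c²−4ad = 1, solved as a
generalised eigenproblem of the design scatter matrix against the
constraint matrix, keeping the eigenvector of the smallest non-negative
eigenvalue.  Points are centred and scaled before solving for conditioning
and the fit mapped back, so it is exactly translation-equivariant and exact
(residual ≤ 1e−9·r) on noiseless circle samples; collinear input raises a
fit error.  The residual is reported geometrically (RMS radial deviation).

## Rise time of phase transitions

The transition baseline is the mean of L over 750–250 ms before the
transition; a line is fit through the last pre-transition crossings
(linear-interpolated) of baseline + 0.1 Δ and baseline + 0.9 Δ, where Δ is
the excursion from baseline to the transition-time value, and the rise time
is how long before the transition the line meets the baseline.  A pure
linear ramp of any slope and offset is recovered exactly; a zero excursion
or collapsed crossings (a step) signal an undefined result rather than
returning a number.

## Statistics

Group values are reported as median ± unscaled m.a.d.
(median(|x − median|), no 1.4826 consistency factor), aggregated first
within each animal (per video, then per animal, when nested) and then
across animals.  The signed-rank statistic W is the smaller of the two
signed-rank sums (zeros dropped, tied magnitudes mid-ranked); its two-sided
p-value is exact for n ≤ 25, computed by convolving the null distribution
over all 2ⁿ sign assignments on doubled (integer) ranks, and a
tie-corrected normal approximation above.  Mann-Whitney U and Spearman ρ
use exact small-sample methods where available with documented fallbacks.
The FDR procedure is Benjamini–Hochberg at α = 0.05 (the variant is a
declared choice); Bonferroni flags are always a subset of BH flags.
Per-D1 grip fractions count two instances per hold and keep indeterminate
instances in the denominator, which is why thumb and pincer fractions need
not sum to 100 %.

## The synthetic generator

The generator emulates exactly the structure the analysis assumes:
lognormal alternating bout durations (medians 0.30 s holding / 0.25 s
oromanual, log-σ 0.4 — right-skewed and positive, matching the reported
skewed spreads), state-dependent levels joined by 50 ms logistic ramps
*centred on each boundary* (so the nearest-level assignment flips at the
annotated transition), slow smoothed jitter (0.1 mm, 150 ms correlation
time), Gaussian regrip pulses (amplitude 1.5 mm, σ 7.2 ms) in bursts with
65 ± 5 ms intra-burst intervals during oromanual phases, Gaussian sniff
dips (depth 3 mm, σ 34 ms) placed 120 ms before holding-phase ends with
probability 0.15, isotropic 0.02 mm tracking noise and random dropouts
(rate 0.001 per part-sample), written with likelihood < 0.1 so a 0.5
likelihood floor recovers the generator's mask exactly.  L levels are 5.1
and 2.7 mm (holding/oromanual); D levels are 4.8 and 5.5 mm — the modes are
separated mainly along L, with the oromanual grip slightly wider, which is
also what keeps the windowed baseline of a regrip close to its local D
level.  Each pulse's motion is split between the hands with shares
(1 ± a)/2 for a drawn asymmetry a ~ U(−1, 1), so the path-integral
asymmetry index recovers a exactly in the noiseless limit.  The front view
embeds the latent series exactly (snout fixed, D3 midpoint L below it, D3s
on the θ axis); the ventral view is an independent projection carrying
L_ventral, with no attempt at cross-view geometric consistency (views are
analysed independently).  A fixed seed reproduces every array and file
bit-for-bit.

What the generator does *not* emulate: occlusions with structured (non-
independent) dropout, pro/supination-induced tracking bias, seed-size
effects, inter-animal variability within one session, or any coupling
between views.  Passing recovery tests therefore demonstrates correctness
of the measurement pipeline under the stated noise model, not robustness to
every artefact of real video tracking.

## Problem sizes and tolerances in the test suite

Recovery tests run on 120 s sessions (~35,000 frames) over 10 seeds for the
full-pipeline property (duty cycle within 0.05, centroid L within 0.3 mm,
median regrip FWHM within 2 frame intervals of 2.3548 σ, periodicity within
[14, 17] Hz), and on 60–120 s single-seed sessions for detector
precision/recall (≥ 0.9 with ±10 ms regrip / ±20 ms sniff match windows).
Exactness claims (feature round-trip, Pratt fit, rise time on ramps, angle
recovery) are asserted at 1e−9 absolute or one frame interval.  Exact-test
p-values are cross-checked against full enumeration up to n = 12 (signed
rank) and n₁+n₂ = 10 (Mann-Whitney).
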