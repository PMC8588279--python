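# Methods

This note documents the models and numerical choices behind `atcurve`: what
is computed, under which assumptions, which parameters matter, and what the
synthetic validation does and does not establish about real recordings.

## Measurement model

**Tendon path.** Per motion-capture frame the Achilles tendon (AT) is
represented as an ordered polyline: calcaneus insertion marker → interior
foil markers on the skin along the tendon → skin-projected gastrocnemius
medialis myotendinous junction (GM MTJ, the origin). The *curved* length is
the polyline arc length; the *straight* length is the chord between the
endpoints. By the triangle inequality the chord bounds every subset length
from below and the all-marker reference bounds it from above, and lengths
are monotone under marker addition — these exact bounds are asserted as
tests, not tolerances.

**Strain.** `ε(t) = 100·(L(t) − L₀)/L₀` with L₀ a resting length measured
where the tendon is slack (~20° plantar flexion). Because strain is a ratio
of lengths it is invariant under rigid motion of all coordinates and under
uniform scaling when L₀ scales along.

**Units and conventions.** Millimetres, percent strain, degrees, Hz.
Frames are 0-based internally; exported tables are 1-based with time
stamps. The internal lab frame is Z-up with +X the direction of
progression; the TRC reader maps the format's Y-up convention onto it.
Missing marker frames propagate as flagged NaN, never as zeros; an optional
cubic-spline gap fill is capped at a configurable maximum gap (default 10
frames) and never extrapolates across record edges. Foil-marker
trajectories are *not* low-pass filtered before length computation (only
the joint markers used for event detection are); filtering of the length
series is left to the user.

## Ultrasound registration

The GM MTJ is tracked in B-mode images and must be expressed in the lab
frame. The chain is: (1) probe pose per frame from a rigid marker tripod via
a closed-form least-squares rigid fit (Kabsch/SVD; reflections suppressed by
forcing det = +1; the RMS point residual is reported per pose); (2) skin
surface per image as the most superficial accepted Canny edge per column
(Gaussian σ = 2 px; hysteresis thresholds at the 70th/90th percentile of
gradient magnitude), refined to the onset of the bright interface (first row
within a ±⌈2σ⌉+2 window reaching 90% of the local maximum — the Canny
maximum sits ~σ above a thin bright interface, the refinement restores the
interface row) and median-filtered over 5 columns; (3) the MTJ pixel point
projected to the nearest point on the skin polyline, segment interiors
included; (4) pixels mapped to mm along the calibrated image axes (row =
depth into tissue, column = along the transducer face, anchored at the
left-center of the digitized front layer) and rigidly transformed to the lab
frame. Streams at different rates (e.g. 146 Hz ultrasound vs 250 Hz mocap)
are aligned at a trigger with nearest-neighbour (default) or fractional
mapping.

The in-image skin projection is a 2-D operation; the scan plane is assumed
to contain the tendon line locally. Out-of-plane probe motion therefore
biases the projection by the out-of-plane offset; the simulator keeps the
probe in-plane, so this assumption is untested against violation.

## Gait events

Walking: touchdown = local minima of the filtered heel height; foot-off =
posterior→anterior zero crossing of the filtered toe anterior-posterior
velocity (central differences, one-sided at edges). Running: touchdown and
foot-off = first and second knee-extension maxima per stride; stride
windows are bootstrapped from the strongest autocorrelation peak of the
knee-angle series (the strongest, not the first — the touchdown-to-foot-off
spacing shows up as a weaker secondary peak). A trailing extension maximum
past the last full window is accepted as a final touchdown so that the
stride delimiting the last analyzed cycle is not lost. All detection runs
on series filtered with a fourth-order zero-phase Butterworth low-pass at
12 Hz (forward–backward, squaring the single-pass magnitude). Peak picking
uses a prominence of 20% of the series range and a minimum separation of
0.4 s; detection is invariant to constant offsets. Stance = [touchdown,
foot-off), swing = [foot-off, next touchdown); incomplete strides at record
edges are trimmed with a warning.

## Marker reduction

For a participant with `n` interior foil markers and subset size `r`, all
`C(n, r)` order-preserving combinations are enumerated (lexicographically;
anatomical order is never permuted). Each subset's length series over the
whole-stride frames is compared to the all-marker reference by RMSE; the
argmin is the optimal marker-set of that size, ties broken by the
lexicographically smallest (most distal) subset for determinism. Reported
per size: whole-stride RMSE, per-frame absolute error, stance/swing/stride
mean absolute errors, and the maximum-strain error
`|max ε_subset − max ε_reference|`. Optimal RMSE is provably non-increasing
in `r` (adding a marker moves every frame's length toward the reference),
which the tests assert on every simulated trial.

### Saturation analysis

Each individual contributes stride-mean errors at marker percentages
`{0, 100·r/n, …, 100}` (0% = straight length, 100% = reference, error 0 by
construction), linearly interpolated onto a common 100-point grid. At each
integer percentage `p` a simple linear regression is fitted to the pooled
points, in two window modes:

* **cumulative** (points with pct ≤ p): the reported R² curve; for
  realistic error shapes it rises and saturates as the pooled decline
  dominates the early inter-individual scatter.
* **tail** (points with pct ≥ p): the plateau detector's default; once all
  remaining errors are (near) zero the fit is exact and R² = 1, so the
  percentage beyond which markers stop mattering is localized sharply.

Conventions: zero variance in the response = perfect constant fit, R² = 1;
zero variance in the predictor (or < 3 points) = undefined, NaN; a cohort
whose error is identically zero (no curvature) is flagged degenerate with
NaN R² and plateau rather than an error. The plateau is the smallest `p` at
which the detector sequence reaches the threshold (default R² ≥ 0.99) and
*maintains* it over the next 10 grid points; requiring it to hold through
100% (available via `sustain=None`) is brittle exactly when the curve
saturates at the threshold and hovers within numerical noise of it. The two
window modes exist because "a regression fitted in 1% intervals" admits
both cumulative and windowed readings; both are computed and exported so
users can report either.

### Placement table

Optimal marker positions are expressed as percentages of the standing AT
length from the calcaneus (0%), taken from a standing frame's polyline arc
length. Across trials and individuals the positions of each marker-set size
are averaged **rank-matched** (most distal with most distal, and so on) —
the only order-consistent choice. The cost of imposing the averaged
positions instead of the individual optimum is the whole-stride RMSE of a
virtual marker-set interpolated at those arc-length fractions (uniform
skin-stretch assumption: a marker at fraction f of the standing length
stays at fraction f of the instantaneous length). A reference placement
table for marker-sets 2–4 (22/56; 15/35/65; 10/31/47/66% of standing
length) ships as a constant for display and comparison; the pipeline always
recomputes cohort-specific placements.

Statistical hypothesis testing (mixed models, signed-rank tests) is out of
scope by design; `errors_long.csv` is a tidy participant × speed × phase ×
marker-set table for external statistics packages.

## Synthetic data generator

The generator supplies every module with analytic ground truth. The tendon
is a circular arc in the sagittal plane between insertion and MTJ: chord
`c(t)`, sagitta `d(t)`, radius `R = (c²/4 + d²)/(2d)`, exact length
`2R·asin(c/2R)`. The chord follows a raised-cosine elongation profile
peaking in mid-stance (amplitude = `mtj_excursion`, default 8 mm, matching
in-vivo AT length changes of ~8 mm over the cycle); the sagitta oscillates
between `curvature_baseline` (35%) and 100% of `curvature_amplitude`
(default 4.5 mm, configurable 3–6 mm), peaking just after foot-off where
plantar flexion bends the tendon most. Foil markers sit at 20 mm standing
intervals, ride the skin at fixed arc-length fractions (uniform stretch),
and receive isotropic Gaussian mocap noise (σ = 0.2 mm). The resting length
L₀ is the trial minimum of the true length — a proxy for the slack length
at 20° plantar flexion. Cohorts default to 11 individuals clustered at 5–9
foil markers (2/2/4/2/1), chord lengths chosen so the 20 mm spacing yields
exactly the requested count, and the MTJ excursion scales with the chord so
peak strain stays in the physiological 4–5% band across tendon sizes.

Joint-marker trajectories plant events exactly: the heel height is a
raised cosine with a sharp Gaussian impact dip (width 0.03 cycle) at
touchdown — without the dip, filtered mocap noise can shift the shallow
cosine minimum by several frames, which is a property of blunt minima, not
of the detector; the toe AP position crosses velocity zero at foot-off; the
knee angle carries two extension bumps per stride at the planted events.
The synthetic ultrasound stream keeps the scan plane in the tendon's
sagittal plane, anchors the image so the skin sits at row 20 and the MTJ
4 mm deeper, and renders B-mode frames (bright interface band, speckle,
MTJ blob) on demand.

**What passing tests show — and don't.** The simulator validates the
geometry, combinatorics, detection and registration chains against exact
ground truth. It does *not* emulate soft-tissue artifact, non-uniform skin
stretch, marker occlusion/mislabeling, out-of-plane probe motion, real
speckle statistics, or inter-individual curvature shape differences beyond
amplitude/size scaling. Quantities driven by the curvature magnitude (e.g.
the absolute curved-vs-straight difference) are as large as the configured
sagitta makes them; with the default 3–6 mm sagitta the shallow-arc
difference `≈ 8d²/3c` is a few tenths of a millimetre, so conclusions about
absolute error magnitudes on real tendons require measured curvature, not
this generator.

## Problem sizes and determinism

Default analyses use 10 strides per condition at 250 Hz (~2 900 frames) and
evaluate all `2ⁿ − 1 ≤ 511` subsets per individual, a few seconds per
cohort on one core. All randomness flows from a single integer seed through
`numpy`'s `default_rng` (per-individual seeds spawned via `SeedSequence`);
identical seeds give bit-identical trials and byte-identical output CSVs
(floats formatted to 6 decimals, provenance header with version, config
hash and seed).

## Known limitations

* The MTJ tracking itself is out of scope; MTJ pixel coordinates are an
  input (from the synthetic stream or an external tracker's CSV).
* C3D input is not implemented; TRC is the supported mocap format.
* The skin-projection plane assumption (above) is untested against
  out-of-plane motion.
* Plateau detection on noisy cohorts is sensitive near the R² threshold by
  nature; both window modes and the sustain window are exposed so the
  sensitivity is visible rather than hidden.
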