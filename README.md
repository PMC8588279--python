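# atcurve

Measuring in-vivo **Achilles tendon (AT) length and strain during gait under
consideration of tendon curvature** — and finding out how few skin markers
you can get away with.

## The problem

The AT runs from the gastrocnemius medialis myotendinous junction (GM MTJ,
its origin) to the calcaneus (its insertion). The common "straight-length"
method treats it as the Euclidean chord between those two landmarks, but the
tendon follows a concave curve that changes with contraction and ankle
rotation, so the chord systematically underestimates length — and therefore
strain, the quantity that matters for loading, injury risk and training
prescription. The curvature can be sampled with a line of small reflective
foil markers on the skin along the tendon, combined with ultrasound tracking
of the GM MTJ. Placing and post-processing many markers is costly, so the
practical question is: *which reduced marker-set reproduces the
full-curvature length within a tolerable error?*

`atcurve` implements the whole measurement chain and the marker-reduction
analysis for movement-science labs:

* **Geometry** — per-frame tendon path `insertion → foil markers → origin`;
  curved length `L = Σ‖p_{k+1} − p_k‖`, straight length `‖origin − insertion‖`,
  strain `ε = 100·(L − L₀)/L₀` with L₀ the resting length (tendon slack at
  ~20° plantar flexion).
* **Ultrasound registration** — probe pose from a rigid marker tripod
  (least-squares Kabsch fit), skin-line detection in B-mode frames (Canny),
  shortest-distance projection of the MTJ to the skin, pixel→mm→global
  mapping, and 146 Hz↔250 Hz stream synchronization.
* **Gait events** — touchdown/foot-off from 12 Hz zero-phase Butterworth
  filtered marker kinematics: heel-height minima and toe-velocity reversals
  (walking), first/second knee-extension maxima per stride (running);
  stance/swing segmentation and 100-point cycle normalization.
* **Marker reduction** — for each subset size `r` of the `n` foil markers,
  all `C(n, r) = n!/((n−r)!·r!)` combinations are evaluated against the
  all-marker reference length; the minimum-RMSE combination per size, its
  stance/swing phase-averaged absolute length error and its maximum-strain
  error quantify the reduction cost. Pooled over a cohort, the error as a
  function of the percentage of retained markers yields an R² saturation
  curve whose plateau marks the sufficient marker count, and rank-matched
  averaging of optimal positions gives a placement recommendation table.
* **Synthetic data** — gait trials with a circular-arc tendon model
  (closed-form length `2R·asin(c/2R)`), planted gait events, mocap noise and
  a synthetic ultrasound stream, so every processing step can be validated
  against analytic ground truth.

## Worked example

```python
from atcurve import SimulationParams, simulate_trial, length_series
from atcurve.pipeline import analyze_trial, detect_trial_events

trial = simulate_trial(SimulationParams(mode="walking", n_strides=10, seed=1))
events = detect_trial_events(trial.markers, "walking")
ana = analyze_trial(trial.path, events, trial.resting_length, "walking")

print(f"n_foil = {trial.n_foil}, resting length = {trial.resting_length:.1f} mm")
print(f"max curved-straight difference = {ana.curved_minus_straight_max:.3f} mm")
print(f"max strain = {ana.max_strain:.2f} %")
for r in (1, 3, 5):
    ev = ana.reduction.by_r[r]
    print(f"MS{r}: subset {ev.subset}, RMSE {ev.rmse:.4f} mm, "
          f"stance {ev.stance_error:.4f} / swing {ev.swing_error:.4f} mm")
```

prints

```
n_foil = 9, resting length = 192.3 mm
max curved-straight difference = 0.413 mm
max strain = 4.47 %
MS1: subset (4,), RMSE 0.0783 mm, stance 0.0588 / swing 0.0940 mm
MS3: subset (2, 4, 7), RMSE 0.0455 mm, stance 0.0383 / swing 0.0473 mm
MS5: subset (0, 2, 3, 5, 7), RMSE 0.0306 mm, stance 0.0260 / swing 0.0295 mm
```

i.e. with nine foil markers on a ~192 mm tendon whose simulated sagitta
peaks at 4.5 mm, ignoring curvature costs up to ~0.4 mm of length here, the
single best-placed (mid-tendon) marker already brings the whole-stride RMSE
below 0.1 mm, and at small marker counts errors are larger in swing (where
plantar flexion bends the tendon most) than in stance.

The command line mirrors the library
(`atcurve simulate`, `events`, `length`, `reduce`, `saturate`, `placement`,
`run`); `atcurve run --seed 1 --out-dir out/` writes `events.csv`,
`lengths.csv`, `reduction_results.csv`, `errors_long.csv` (tidy table for
external statistics), `saturation.csv` and `placement_table.csv`, each with
a provenance header (version, config hash, seed).

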