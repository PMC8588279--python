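"""Synthetic gait trials with analytically known Achilles tendon geometry.

The tendon path is modelled per frame as a circular arc in the sagittal
plane between the calcaneus insertion (fixed at the local origin, chord
along +Z) and the moving MTJ origin.  The chord length follows a smooth
elongation profile peaking in mid-stance (the tendon is loaded and longest
under the stance-phase muscle forces) and the arc sagitta follows a
curvature profile peaking just after foot-off, where plantar flexion bends
the tendon most.  Because the arc is circular its length has the closed form
``2 R asin(c / 2R)`` with ``R = (c^2/4 + d^2) / (2 d)``, so every
length-pipeline tolerance can be asserted against an exact target.

Foil markers sit at fixed fractions of the instantaneous arc length
(uniform skin stretch), at 20 mm intervals in the standing posture, and are
perturbed with isotropic Gaussian mocap noise.  Joint-marker trajectories
carry planted heel-height minima, toe-velocity reversals and double-peaked
knee-extension maxima at known frames, and an optional synthetic ultrasound
stream (probe poses, tripod markers, MTJ pixel coordinates, renderable
B-mode frames) exercises the registration chain end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidParameterError, TooFewMarkersError
from .geometry import MarkerTrajectories, TendonPath
from .ultrasound import ProbeCalibration, ProbePose, UltrasoundFrame, global_to_image

__all__ = [
    "SimulationParams",
    "SyntheticTrial",
    "UltrasoundStream",
    "arc_radius",
    "arc_length",
    "arc_points",
    "simulate_trial",
    "synth_ultrasound_frame",
    "make_cohort",
    "COHORT_FOIL_COUNTS",
]

# Gait-mode presets: stride duration (s) and stance fraction of the cycle.
_MODE_PRESETS = {
    "walking": (1.10, 0.62),
    "slow_run": (0.74, 0.40),
    "fast_run": (0.66, 0.36),
}

# Default cohort: 11 individuals clustered by foil-marker count
# (two with 5, two with 6, four with 7, two with 8, one with 9).
COHORT_FOIL_COUNTS: Tuple[int, ...] = (5, 5, 6, 6, 7, 7, 7, 7, 8, 8, 9)


def arc_radius(chord: float, sagitta: float) -> float:
    """Radius of the circular arc with the given chord and sagitta (mm)."""
    if chord <= 0 or sagitta <= 0:
        raise InvalidParameterError("chord and sagitta must be > 0")
    return (chord * chord / 4.0 + sagitta * sagitta) / (2.0 * sagitta)


def arc_length(chord, sagitta) -> np.ndarray:
    """Closed-form circular-arc length ``2 R asin(c / 2R)``; equals the chord
    when the sagitta is zero."""
    c = np.asarray(chord, dtype=float)
    d = np.asarray(sagitta, dtype=float)
    R = np.where(d > 0, (c * c / 4.0 + d * d) / (2.0 * np.where(d > 0, d, 1.0)), np.inf)
    with np.errstate(invalid="ignore"):
        s = np.where(d > 0, 2.0 * R * np.arcsin(np.clip(c / (2.0 * R), -1.0, 1.0)), c)
    return s if s.ndim else float(s)


def arc_points(chord: float, sagitta: float, fractions) -> np.ndarray:
    """Points on the sagittal-plane arc at the given arc-length fractions.

    The arc runs from the insertion at (0, 0, 0) to the origin at
    (0, 0, chord), bulging toward +X with the given sagitta at midpoint; a
    zero sagitta degenerates to the straight chord.
    """
    f = np.asarray(fractions, dtype=float)
    if sagitta == 0:
        pts = np.zeros((f.size, 3))
        pts[:, 2] = f * chord
        return pts
    R = arc_radius(chord, sagitta)
    alpha = np.arcsin(chord / (2.0 * R))
    center = np.array([-(R - sagitta), 0.0, chord / 2.0])
    theta = -alpha + 2.0 * alpha * f
    pts = np.empty((f.size, 3))
    pts[:, 0] = center[0] + R * np.cos(theta)
    pts[:, 1] = 0.0
    pts[:, 2] = center[2] + R * np.sin(theta)
    return pts


def _arc_tangent_at_origin(chord: float, sagitta: float) -> np.ndarray:
    """Unit tangent of the arc at the origin end, pointing distal -> proximal."""
    if sagitta == 0:
        return np.array([0.0, 0.0, 1.0])
    R = arc_radius(chord, sagitta)
    alpha = np.arcsin(chord / (2.0 * R))
    # derivative of arc_points w.r.t. theta at theta = +alpha
    t = np.array([-np.sin(alpha), 0.0, np.cos(alpha)])
    return t / np.linalg.norm(t)


def _arc_inward_normal_at_origin(chord: float, sagitta: float) -> np.ndarray:
    """Unit normal at the origin end pointing from the skin into the tissue
    (toward the arc center)."""
    if sagitta == 0:
        return np.array([-1.0, 0.0, 0.0])
    R = arc_radius(chord, sagitta)
    center = np.array([-(R - sagitta), 0.0, chord / 2.0])
    p = arc_points(chord, sagitta, np.array([1.0]))[0]
    n = center - p
    return n / np.linalg.norm(n)


def _raised_cosine(phase: np.ndarray, center: float) -> np.ndarray:
    """Smooth periodic weight in [0, 1], maximal at ``center`` (cycle units)."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (phase - center)))


def _wrapped(phase: np.ndarray, center: float) -> np.ndarray:
    return (phase - center + 0.5) % 1.0 - 0.5


@dataclass
class SimulationParams:
    """Synthetic-trial settings (lengths in mm, rates in Hz, durations in s).

    Defaults emulate treadmill gait captured at 250 Hz with foil markers at
    20 mm intervals and 0.2 mm mocap noise: a ~200 mm tendon whose chord
    shortens/lengthens by ~8 mm over the cycle (matching reported in-vivo AT
    length changes of about 8 mm) and whose sagittal sagitta oscillates
    between ~35% and 100% of ``curvature_amplitude``, peaking just after
    foot-off.  ``curvature_phase_profile`` may override the sagitta weighting
    (a callable of cycle fraction returning values in [0, 1]).
    """

    mode: str = "walking"
    stride_duration: Optional[float] = None
    stance_fraction: Optional[float] = None
    rate: float = 250.0
    n_strides: int = 10
    chord_length: float = 200.0
    curvature_amplitude: float = 4.5
    curvature_baseline: float = 0.35
    curvature_phase_profile: Optional[Callable[[np.ndarray], np.ndarray]] = None
    marker_spacing: float = 20.0
    noise_sigma: float = 0.2
    mtj_excursion: float = 8.0
    mtj_depth: float = 4.0
    pixel_spacing: float = 0.1
    pixel_noise: float = 0.5
    include_ultrasound: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODE_PRESETS:
            raise InvalidParameterError(
                f"mode must be one of {sorted(_MODE_PRESETS)}, got {self.mode!r}"
            )
        preset = _MODE_PRESETS[self.mode]
        if self.stride_duration is None:
            self.stride_duration = preset[0]
        if self.stance_fraction is None:
            self.stance_fraction = preset[1]
        for name in ("stride_duration", "rate", "chord_length", "marker_spacing",
                     "mtj_excursion", "pixel_spacing"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.n_strides < 1:
            raise InvalidParameterError("need at least one stride")
        if self.noise_sigma < 0 or self.pixel_noise < 0:
            raise InvalidParameterError("noise levels must be >= 0")
        if not 0 <= self.curvature_baseline <= 1:
            raise InvalidParameterError("curvature_baseline must lie in [0, 1]")
        if self.curvature_amplitude < 0:
            raise InvalidParameterError("curvature_amplitude must be >= 0")

    @property
    def event_mode(self) -> str:
        """Event-detection rule family: walking uses heel/toe, running the knee."""
        return "walking" if self.mode == "walking" else "running"


@dataclass
class UltrasoundStream:
    """Per-frame synthetic ultrasound bookkeeping for the registration chain."""

    calibration: ProbeCalibration
    tripod_source: np.ndarray
    poses: List[ProbePose]
    mtj_px: np.ndarray
    mtj_px_true: np.ndarray
    mtj_world_true: np.ndarray
    skin_point_world_true: np.ndarray
    pixel_spacing: float
    skin_row: float
    mtj_depth_mm: float
    rate: float

    def frame(self, i: int, shape: Tuple[int, int] = (128, 600)) -> UltrasoundFrame:
        """Render the i-th B-mode frame (deterministic per frame index)."""
        rng = np.random.default_rng(10_000 + i)
        profile = np.full(shape[1], self.skin_row)
        pixels = synth_ultrasound_frame(
            profile, self.mtj_px_true[i], spacing=self.pixel_spacing,
            noise=0.05, shape=shape, rng=rng,
        ).pixels
        return UltrasoundFrame(pixels=pixels, spacing=(self.pixel_spacing,) * 2, index=i)


@dataclass
class SyntheticTrial:
    """One simulated gait trial with its analytic ground truth."""

    params: SimulationParams
    markers: MarkerTrajectories
    path: TendonPath
    true_length: np.ndarray
    true_chord: np.ndarray
    true_sagitta: np.ndarray
    true_touchdowns: np.ndarray
    true_footoffs: np.ndarray
    resting_length: float
    marker_fractions: np.ndarray
    ultrasound: Optional[UltrasoundStream] = None
    individual: object = 0

    @property
    def n_foil(self) -> int:
        return self.path.n_foil

    @property
    def standing_pcts(self) -> np.ndarray:
        """Foil-marker positions as % of the standing AT length from the calcaneus."""
        return 100.0 * self.marker_fractions


def _knee_angle_profile(phase: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Running knee angle (deg): extension maxima exactly at touchdown (phase 0)
    and foot-off (phase = stance fraction)."""
    width = 0.22
    td_bump = np.where(
        np.abs(_wrapped(phase, 0.0)) < width / 2,
        np.cos(np.pi * _wrapped(phase, 0.0) / width) ** 2,
        0.0,
    )
    fo_bump = np.where(
        np.abs(_wrapped(phase, stance_fraction)) < width / 2,
        np.cos(np.pi * _wrapped(phase, stance_fraction) / width) ** 2,
        0.0,
    )
    return 148.0 + 14.0 * td_bump + 22.0 * fo_bump


def _probe_geometry() -> Tuple[ProbeCalibration, np.ndarray]:
    """Fixed synthetic probe: 60 x 10 mm front layer and a 4-marker tripod,
    both expressed in the tripod frame."""
    corners = np.array(
        [[0.0, -5.0, 0.0], [60.0, -5.0, 0.0], [60.0, 5.0, 0.0], [0.0, 5.0, 0.0]]
    )
    calib = ProbeCalibration(corners=corners, depth_sign=1.0)
    tripod = np.array(
        [[0.0, 0.0, -20.0], [80.0, 0.0, -20.0], [40.0, 60.0, -25.0], [40.0, 25.0, -80.0]]
    )
    return calib, tripod


def simulate_trial(params: SimulationParams, individual: object = 0) -> SyntheticTrial:
    """Generate one gait trial; see the module docstring for the model."""
    p = params
    rng = np.random.default_rng(p.seed)
    spf = int(round(p.stride_duration * p.rate))  # samples per stride
    offset = spf // 4
    n_frames = offset + p.n_strides * spf + spf // 4
    frames = np.arange(n_frames)
    phase = ((frames - offset) / spf) % 1.0

    touchdowns = offset + spf * np.arange(p.n_strides + 1)
    footoffs = touchdowns[:-1] + int(round(p.stance_fraction * spf))

    # tendon geometry (analytic)
    elong_peak = 0.45 * p.stance_fraction
    chord = p.chord_length - p.mtj_excursion * (1.0 - _raised_cosine(phase, elong_peak))
    curv_peak = p.stance_fraction + 0.12
    if p.curvature_phase_profile is not None:
        weight = np.asarray(p.curvature_phase_profile(phase), dtype=float)
    else:
        weight = _raised_cosine(phase, curv_peak)
    sagitta = p.curvature_amplitude * (
        p.curvature_baseline + (1.0 - p.curvature_baseline) * weight
    )
    true_length = arc_length(chord, np.where(sagitta > 0, sagitta, 0.0))
    true_length = np.asarray(true_length, dtype=float)

    # foil-marker count and fractions from the standing posture
    standing_sagitta = p.curvature_amplitude * p.curvature_baseline
    s_stand = float(arc_length(p.chord_length, standing_sagitta))
    n_foil = int(np.floor((s_stand - p.marker_spacing / 2.0) / p.marker_spacing))
    if n_foil < 1:
        raise TooFewMarkersError(
            f"marker spacing {p.marker_spacing} mm leaves no interior marker on a "
            f"{s_stand:.1f} mm tendon"
        )
    fractions = np.arange(1, n_foil + 1) * p.marker_spacing / s_stand

    # per-frame path points on the arc (insertion, foils, origin)
    all_fracs = np.concatenate([[0.0], fractions, [1.0]])
    pts = np.empty((n_frames, n_foil + 2, 3))
    for i in range(n_frames):
        if sagitta[i] > 0:
            pts[i] = arc_points(chord[i], sagitta[i], all_fracs)
        else:
            pts[i] = _straight_pts(chord[i], all_fracs)
    origin_true = pts[:, -1, :].copy()
    noisy = pts + rng.normal(0.0, p.noise_sigma, size=pts.shape) if p.noise_sigma > 0 else pts.copy()
    path = TendonPath(points=noisy, rate=p.rate)

    # joint markers with planted events
    markers: Dict[str, np.ndarray] = {}
    heel_z = 30.0 + 12.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    heel_z = heel_z - 8.0 * np.exp(-(_wrapped(phase, 0.0) / 0.03) ** 2)
    markers["heel"] = np.column_stack([np.full(n_frames, -60.0), np.zeros(n_frames), heel_z])
    toe_x = -60.0 * np.cos(2.0 * np.pi * _wrapped(phase, p.stance_fraction))
    markers["toe"] = np.column_stack([toe_x - 180.0, np.zeros(n_frames), np.full(n_frames, 20.0)])

    knee_deg = _knee_angle_profile(phase, p.stance_fraction)
    hip = np.array([0.0, 100.0, 900.0])
    knee = hip + np.array([0.0, 0.0, -420.0])
    psi = np.pi - np.radians(knee_deg)
    shank = 400.0 * np.column_stack([np.sin(psi), np.zeros(n_frames), -np.cos(psi)])
    ankle = knee + shank
    markers["gtroch"] = np.tile(hip, (n_frames, 1))
    markers["med_epi"] = np.tile(knee + [0.0, 45.0, 0.0], (n_frames, 1))
    markers["lat_epi"] = np.tile(knee - [0.0, 45.0, 0.0], (n_frames, 1))
    markers["med_mal"] = ankle + [0.0, 35.0, 0.0]
    markers["lat_mal"] = ankle - [0.0, 35.0, 0.0]
    markers["calcaneus"] = noisy[:, 0, :]
    for k in range(n_foil):
        markers[f"foil_{k + 1}"] = noisy[:, k + 1, :]
    if p.noise_sigma > 0:
        for label in ("heel", "toe", "gtroch", "med_epi", "lat_epi", "med_mal", "lat_mal"):
            markers[label] = markers[label] + rng.normal(0.0, p.noise_sigma, (n_frames, 3))

    # ultrasound stream: probe follows the MTJ, image plane = sagittal plane
    us = None
    if p.include_ultrasound:
        calib, tripod_src = _probe_geometry()
        poses, mtj_px_true, mtj_world, skin_world = [], [], [], []
        ref_frame = UltrasoundFrame(np.zeros((4, 4)), spacing=(p.pixel_spacing,) * 2)
        skin_row, skin_col = 20.0, 300.0
        tripod_world = np.empty((n_frames, 4, 3))
        for i in range(n_frames):
            tau = _arc_tangent_at_origin(chord[i], sagitta[i])
            nrm = _arc_inward_normal_at_origin(chord[i], sagitta[i])
            R = np.column_stack([tau, np.cross(nrm, tau), nrm])
            anchor = (
                origin_true[i]
                - skin_col * p.pixel_spacing * tau
                - skin_row * p.pixel_spacing * nrm
            )
            pose = ProbePose(rotation=R, translation=anchor)
            poses.append(pose)
            mtj_w = origin_true[i] + p.mtj_depth * nrm
            mtj_world.append(mtj_w)
            skin_world.append(origin_true[i])
            mtj_px_true.append(global_to_image(mtj_w, ref_frame, calib, pose))
            tripod_world[i] = pose.apply(tripod_src)
        mtj_px_true = np.asarray(mtj_px_true)
        mtj_px = mtj_px_true + (
            rng.normal(0.0, p.pixel_noise, mtj_px_true.shape) if p.pixel_noise > 0 else 0.0
        )
        if p.noise_sigma > 0:
            tripod_world = tripod_world + rng.normal(0.0, p.noise_sigma, tripod_world.shape)
        for k in range(4):
            markers[f"tripod_{k + 1}"] = tripod_world[:, k, :]
        us = UltrasoundStream(
            calibration=calib,
            tripod_source=tripod_src,
            poses=poses,
            mtj_px=mtj_px,
            mtj_px_true=mtj_px_true,
            mtj_world_true=np.asarray(mtj_world),
            skin_point_world_true=np.asarray(skin_world),
            pixel_spacing=p.pixel_spacing,
            skin_row=skin_row,
            mtj_depth_mm=p.mtj_depth,
            rate=p.rate,
        )

    traj = MarkerTrajectories(labels=list(markers), positions=markers, rate=p.rate)
    return SyntheticTrial(
        params=p,
        markers=traj,
        path=path,
        true_length=true_length,
        true_chord=chord,
        true_sagitta=sagitta,
        true_touchdowns=touchdowns,
        true_footoffs=footoffs,
        resting_length=float(true_length.min()),
        marker_fractions=fractions,
        ultrasound=us,
        individual=individual,
    )


def _straight_pts(chord: float, fractions: np.ndarray) -> np.ndarray:
    pts = np.zeros((fractions.size, 3))
    pts[:, 2] = fractions * chord
    return pts


def synth_ultrasound_frame(
    skin_row_profile,
    mtj_px,
    spacing: float = 0.1,
    noise: float = 0.05,
    shape: Tuple[int, int] = (128, 600),
    rng: Optional[np.random.Generator] = None,
) -> UltrasoundFrame:
    """Render a synthetic B-mode frame: dark standoff above a bright skin
    interface at ``skin_row_profile`` (one row per column), speckle tissue
    below, and a bright blob at the MTJ landmark."""
    rng = rng or np.random.default_rng(0)
    h, w = shape
    profile = np.asarray(skin_row_profile, dtype=float)
    if profile.ndim == 0:
        profile = np.full(w, float(profile))
    if profile.size != w:
        raise InvalidParameterError(
            f"skin profile length {profile.size} != image width {w}"
        )
    if (profile < 1).any() or (profile > h - 4).any():
        raise InvalidParameterError("skin profile leaves the image bounds")
    rows = np.arange(h)[:, None]
    img = np.zeros((h, w))
    below = rows > profile[None, :] + 2
    img[below] = 0.25
    band = (rows >= profile[None, :]) & (rows <= profile[None, :] + 2)
    img[band] = 1.0
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape) * (img > 0.1) + \
            rng.normal(0.0, noise / 5.0, img.shape)
        img = np.clip(img, 0.0, 1.3)
    if mtj_px is not None:
        r0, c0 = float(mtj_px[0]), float(mtj_px[1])
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise InvalidParameterError(f"MTJ pixel {mtj_px} outside the image")
        rr, cc = np.ogrid[:h, :w]
        blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= 4.0
        img[blob] = np.maximum(img[blob], 0.8)
    return UltrasoundFrame(pixels=img, spacing=(spacing, spacing))


def make_cohort(
    n_individuals: int = 11,
    foil_counts: Optional[Sequence[int]] = None,
    mode: str = "walking",
    seed: int = 0,
    **overrides,
) -> List[SyntheticTrial]:
    """Simulate a cohort with varying foil-marker counts (default: the
    11-individual clustering two P5, two P6, four P7, two P8, one P9).

    Foil counts must lie in [2, 15]; the chord length of each individual is
    set so the 20 mm standing spacing yields exactly the requested count.
    Per-individual seeds derive deterministically from ``seed``.
    """
    if foil_counts is None:
        base = COHORT_FOIL_COUNTS
        foil_counts = tuple(base[i % len(base)] for i in range(n_individuals))
    foil_counts = tuple(int(n) for n in foil_counts)
    if len(foil_counts) != n_individuals:
        raise InvalidParameterError(
            f"{len(foil_counts)} foil counts for {n_individuals} individuals"
        )
    for n in foil_counts:
        if not 2 <= n <= 15:
            raise InvalidParameterError(f"foil count {n} outside [2, 15]")
    spacing = float(overrides.get("marker_spacing", 20.0))
    child_seeds = np.random.SeedSequence(seed).generate_state(n_individuals)
    trials = []
    for i, n in enumerate(foil_counts):
        chord = spacing * (n + 1) - 1.0
        kwargs = {k: v for k, v in overrides.items() if k != "chord_length"}
        # keep peak strain comparable across tendon sizes: the MTJ excursion
        # scales with the chord unless explicitly overridden
        if "mtj_excursion" not in kwargs:
            kwargs["mtj_excursion"] = 8.0 * chord / 200.0
        params = SimulationParams(
            mode=mode,
            chord_length=chord,
            seed=int(child_seeds[i] % (2**31)),
            **kwargs,
        )
        trial = simulate_trial(params, individual=i)
        if trial.n_foil != n:
            raise InvalidParameterError(
                f"individual {i}: expected {n} foil markers, geometry yields {trial.n_foil}"
            )
        trials.append(trial)
    return trials
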