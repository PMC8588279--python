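"""Gait-event detection from joint-marker kinematics.

Touchdown and foot-off are detected from filtered marker trajectories using
the standard kinematic criteria for treadmill gait:

* walking touchdown: local minimum of heel-marker height;
* walking foot-off: reversal (posterior-to-anterior zero crossing) of the
  anterior-posterior toe-marker velocity;
* running touchdown / foot-off: first / second local maximum of knee
  extension within each stride.

All position series are low-pass filtered with a fourth-order zero-phase
(forward-backward) Butterworth filter at 12 Hz before event detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal

from .errors import (
    AmbiguousEventsError,
    DegenerateConfigurationError,
    InvalidInputError,
    InvalidParameterError,
    InvalidSegmentationError,
    NoEventsError,
)

__all__ = [
    "FilterSpec",
    "GaitEvents",
    "lowpass_zero_phase",
    "knee_angle",
    "detect_touchdown_walking",
    "detect_footoff_walking",
    "detect_events_running",
    "segment_phases",
    "normalize_stride",
]

# Peak-picking defaults: prominence as a fraction of the series range, and
# minimum event separation in seconds.  The kinematic criteria themselves fix
# *what* an event is; these only reject jitter.
DEFAULT_PROMINENCE_FRAC = 0.2
DEFAULT_MIN_SEPARATION_S = 0.4


@dataclass
class FilterSpec:
    """Low-pass Butterworth filter specification.

    ``order`` is the design order of the single-pass filter; zero-phase
    filtering runs it forward and backward, squaring the magnitude response.
    """

    order: int = 4
    cutoff: float = 12.0
    kind: str = "lowpass"
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        if self.order < 1:
            raise InvalidParameterError(f"filter order must be >= 1, got {self.order}")
        if not 0 < self.cutoff < rate / 2:
            raise InvalidParameterError(
                f"cutoff must lie in (0, rate/2) = (0, {rate / 2} Hz), got {self.cutoff}"
            )


@dataclass
class GaitEvents:
    """Touchdown / foot-off frame indices and the stance/swing segmentation."""

    touchdowns: np.ndarray
    footoffs: np.ndarray
    mode: str
    n_frames: int
    phase_labels: np.ndarray = field(init=False)

    def __post_init__(self):
        self.touchdowns = np.asarray(self.touchdowns, dtype=int)
        self.footoffs = np.asarray(self.footoffs, dtype=int)
        if self.mode not in ("walking", "running"):
            raise InvalidParameterError(f"mode must be walking|running, got {self.mode!r}")
        for name, ev in (("touchdowns", self.touchdowns), ("footoffs", self.footoffs)):
            if len(ev) and (np.diff(ev) <= 0).any():
                raise InvalidInputError(f"{name} must be strictly increasing")
        # keep only foot-offs that fall strictly inside a touchdown interval,
        # and require strict interleaving within strides
        self.phase_labels = _phase_labels(self.touchdowns, self.footoffs, self.n_frames)

    @property
    def strides(self) -> List[Tuple[int, int, int]]:
        """Complete strides as (touchdown, footoff, next_touchdown) triples."""
        out = []
        for td, nxt in zip(self.touchdowns[:-1], self.touchdowns[1:]):
            fo = self.footoffs[(self.footoffs > td) & (self.footoffs < nxt)]
            if len(fo) == 1:
                out.append((int(td), int(fo[0]), int(nxt)))
        return out

    @property
    def stride_frames(self) -> np.ndarray:
        """Frame indices covered by complete strides (first to last touchdown)."""
        if len(self.touchdowns) < 2:
            return np.array([], dtype=int)
        return np.arange(self.touchdowns[0], self.touchdowns[-1])


def _phase_labels(touchdowns, footoffs, n_frames) -> np.ndarray:
    labels = np.full(n_frames, "none", dtype=object)
    for td, nxt in zip(touchdowns[:-1], touchdowns[1:]):
        fo = footoffs[(footoffs > td) & (footoffs < nxt)]
        if len(fo) != 1:
            raise InvalidInputError(
                f"stride [{td}, {nxt}) must contain exactly one foot-off, found {len(fo)}"
            )
        labels[td : fo[0]] = "stance"
        labels[fo[0] : nxt] = "swing"
    return labels


def lowpass_zero_phase(series, rate: float, spec: Optional[FilterSpec] = None) -> np.ndarray:
    """Forward-backward (zero phase lag) low-pass Butterworth filter.

    Works on 1-D series or (n_frames, d) arrays, filtering along axis 0.
    """
    spec = spec or FilterSpec()
    spec.validate(rate)
    arr = np.asarray(series, dtype=float)
    if arr.shape[0] <= 3 * spec.order:
        raise InvalidInputError(
            f"series length {arr.shape[0]} too short for order-{spec.order} zero-phase filtering"
        )
    sos = signal.butter(spec.order, spec.cutoff, btype="low", fs=rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, arr, axis=0)
    return signal.sosfilt(sos, arr, axis=0)


def knee_angle(hip, knee, ankle) -> np.ndarray:
    """Included knee angle (degrees) between thigh and shank; 180 = full extension.

    ``knee`` should be the midpoint of the femoral epicondyle markers and
    ``ankle`` the midpoint of the malleoli markers.
    """
    hip, knee, ankle = (np.atleast_2d(np.asarray(a, dtype=float)) for a in (hip, knee, ankle))
    thigh = hip - knee
    shank = ankle - knee
    nt = np.linalg.norm(thigh, axis=1)
    ns = np.linalg.norm(shank, axis=1)
    if (nt == 0).any() or (ns == 0).any():
        raise DegenerateConfigurationError("zero-length thigh or shank segment vector")
    cosang = np.einsum("ij,ij->i", thigh, shank) / (nt * ns)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _min_distance_frames(rate: float, min_separation_s: float) -> int:
    return max(1, int(round(min_separation_s * rate)))


def detect_touchdown_walking(
    heel_vertical,
    rate: float,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> np.ndarray:
    """Touchdown frames for walking: local minima of the (filtered) heel height."""
    y = np.asarray(heel_vertical, dtype=float)
    rng = np.ptp(y)
    if rng == 0:
        raise NoEventsError("heel series is constant; no minima")
    peaks, _ = signal.find_peaks(
        -y,
        prominence=prominence_frac * rng,
        distance=_min_distance_frames(rate, min_separation_s),
    )
    if len(peaks) == 0:
        raise NoEventsError("no qualifying heel-height minima found")
    return peaks


def _central_velocity(x: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference velocity, one-sided at the edges."""
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (rate / 2.0)
    v[0] = (x[1] - x[0]) * rate
    v[-1] = (x[-1] - x[-2]) * rate
    return v


def detect_footoff_walking(
    toe_ap_position,
    rate: float,
    direction: str = "posterior_to_anterior",
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> np.ndarray:
    """Foot-off frames for walking: reversal of the anterior-posterior toe velocity.

    On a treadmill the toe travels posteriorly during stance; foot-off is the
    zero crossing of AP velocity from negative to positive (configurable via
    ``direction`` = ``"posterior_to_anterior"`` or ``"anterior_to_posterior"``).
    """
    x = np.asarray(toe_ap_position, dtype=float)
    v = _central_velocity(x, rate)
    if direction == "anterior_to_posterior":
        v = -v
    elif direction != "posterior_to_anterior":
        raise InvalidParameterError(f"unknown direction {direction!r}")
    sign = np.sign(v)
    crossings = np.nonzero((sign[:-1] < 0) & (sign[1:] >= 0))[0]
    if len(crossings) == 0:
        raise NoEventsError("no AP-velocity reversal found")
    # pick the sample nearer the actual zero
    events = np.where(np.abs(v[crossings]) <= np.abs(v[crossings + 1]), crossings, crossings + 1)
    # enforce minimum separation
    keep, last = [], -np.inf
    min_d = _min_distance_frames(rate, min_separation_s)
    for e in events:
        if e - last >= min_d:
            keep.append(int(e))
            last = e
    return np.asarray(keep, dtype=int)


def _dominant_period(y: np.ndarray, rate: float, min_separation_s: float) -> int:
    """Stride period (frames) from the first dominant autocorrelation peak."""
    z = y - y.mean()
    ac = signal.correlate(z, z, mode="full")[len(z) - 1 :]
    min_lag = _min_distance_frames(rate, min_separation_s)
    if len(ac) <= min_lag + 2:
        raise AmbiguousEventsError("series too short to estimate stride periodicity")
    peaks, _ = signal.find_peaks(ac[min_lag:], prominence=0.05 * ac[0])
    if len(peaks) == 0:
        raise AmbiguousEventsError("no periodicity found in knee-angle series")
    # strongest (not first) peak: intra-stride event spacing shows up as a
    # weaker secondary peak and must not masquerade as the stride period
    return int(peaks[np.argmax(ac[min_lag:][peaks])] + min_lag)


def detect_events_running(
    knee_angle_series,
    rate: float,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> Tuple[np.ndarray, np.ndarray]:
    """Running events from the knee angle: per stride, touchdown is the first
    and foot-off the second local maximum of knee extension.

    Stride windows are bootstrapped from the dominant periodicity of the
    knee-angle series (autocorrelation), then each window must contain exactly
    two extension maxima.
    """
    y = np.asarray(knee_angle_series, dtype=float)
    rng = np.ptp(y)
    if rng == 0:
        raise NoEventsError("knee-angle series is constant")
    period = _dominant_period(y, rate, min_separation_s)
    peaks, _ = signal.find_peaks(y, prominence=prominence_frac * rng)
    if len(peaks) < 2:
        raise AmbiguousEventsError(
            f"need at least two knee-extension maxima, found {len(peaks)}"
        )
    touchdowns, footoffs = [], []
    start = peaks[0] - period // 4
    while start + period <= len(y) + period // 4:
        inwin = peaks[(peaks >= start) & (peaks < start + period)]
        if len(inwin) == 0:
            break
        if len(inwin) != 2:
            raise AmbiguousEventsError(
                f"stride window [{start}, {start + period}) holds {len(inwin)} "
                "extension maxima, expected 2 (touchdown, foot-off)"
            )
        touchdowns.append(int(inwin[0]))
        footoffs.append(int(inwin[1]))
        start += period
    # a trailing touchdown may open an incomplete stride at the record edge
    trailing = peaks[peaks >= start]
    if len(trailing) >= 1 and (not touchdowns or trailing[0] > touchdowns[-1]):
        touchdowns.append(int(trailing[0]))
        if len(trailing) >= 2:
            footoffs.append(int(trailing[1]))
    if not touchdowns:
        raise AmbiguousEventsError("no complete stride window found")
    return np.asarray(touchdowns), np.asarray(footoffs)


def segment_phases(events: GaitEvents) -> Tuple[np.ndarray, List[dict]]:
    """Per-frame phase labels and per-stride cycle-normalized time.

    Returns the label array (``stance`` / ``swing`` / ``none``) and one record
    per complete stride with the frame span, stance fraction, and a 100-point
    percent-of-gait-cycle grid mapped to frame positions.  Incomplete strides
    at the record edges are trimmed with a warning.
    """
    strides = events.strides
    if not strides:
        raise InvalidSegmentationError("no complete stride (touchdown to touchdown)")
    n_trimmed_front = int((events.footoffs < events.touchdowns[0]).sum())
    n_trimmed_back = int((events.footoffs > events.touchdowns[-1]).sum())
    if n_trimmed_front or n_trimmed_back:
        warnings.warn(
            f"trimmed {n_trimmed_front + n_trimmed_back} incomplete stride(s) at record edges",
            stacklevel=2,
        )
    records = []
    for td, fo, nxt in strides:
        pct = np.linspace(0.0, 100.0, 100, endpoint=False)
        frame_pos = td + pct / 100.0 * (nxt - td)
        records.append(
            {
                "touchdown": td,
                "footoff": fo,
                "next_touchdown": nxt,
                "stance_fraction": (fo - td) / (nxt - td),
                "cycle_pct": pct,
                "cycle_frames": frame_pos,
            }
        )
    return events.phase_labels, records


def normalize_stride(series, td: int, next_td: int, n_points: int = 100) -> np.ndarray:
    """Resample ``series[td:next_td]`` onto ``n_points`` equally spaced cycle points."""
    y = np.asarray(series, dtype=float)
    if not 0 <= td < next_td <= len(y):
        raise InvalidInputError(f"stride [{td}, {next_td}) outside series of length {len(y)}")
    grid = td + np.linspace(0.0, 100.0, n_points, endpoint=False) / 100.0 * (next_td - td)
    return np.interp(grid, np.arange(len(y)), y)
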