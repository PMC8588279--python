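"""Core tendon geometry: curved and straight Achilles tendon (AT) length and strain.

The AT path per motion-capture frame is an ordered polyline from the insertion
(calcaneus marker) through the interior foil markers placed on the skin along
the tendon, to the origin (skin-projected gastrocnemius medialis myotendinous
junction).  The *curved* length is the polyline arc length; the *straight*
length is the Euclidean chord between insertion and origin; strain is the
length change relative to a resting length measured where the tendon is slack.

Units are millimetres and percent strain throughout; frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    DataGapError,
    InvalidInputError,
    InvalidParameterError,
    InvalidSubsetError,
)

__all__ = [
    "MarkerTrajectories",
    "TendonPath",
    "LengthSeries",
    "StrainSeries",
    "polyline_length",
    "straight_length",
    "length_series",
    "strain_series",
]


def _as_points(points, name="points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError(f"{name} must be an (N, 3) array, got shape {pts.shape}")
    return pts


@dataclass
class MarkerTrajectories:
    """Frame-indexed labelled 3D marker positions.

    Parameters
    ----------
    labels : list of str
        Marker names.
    positions : dict of str -> (n_frames, 3) float array
        Positions in millimetres.  Gaps (missing frames) are NaN, never zero.
    rate : float
        Sampling frequency in Hz.
    """

    labels: Sequence[str]
    positions: Dict[str, np.ndarray]
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise InvalidParameterError(f"sampling rate must be > 0, got {self.rate}")
        self.labels = list(self.labels)
        missing = [l for l in self.labels if l not in self.positions]
        if missing:
            raise InvalidInputError(f"labels without position data: {missing}")
        n = None
        for label in self.labels:
            arr = _as_points(self.positions[label], name=f"positions[{label!r}]")
            self.positions[label] = arr
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise InvalidInputError(
                    f"marker {label!r} has {arr.shape[0]} frames, expected {n}"
                )
        self._n_frames = int(n) if n is not None else 0

    @property
    def n_frames(self) -> int:
        return self._n_frames

    @property
    def times(self) -> np.ndarray:
        """Frame time stamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.rate

    def gap_frames(self, label: str) -> np.ndarray:
        """Frame indices with any non-finite coordinate for ``label``."""
        return np.nonzero(~np.isfinite(self.positions[label]).all(axis=1))[0]

    def fill_gaps(self, max_gap: int = 10) -> "MarkerTrajectories":
        """Return a copy with gaps up to ``max_gap`` consecutive frames spline-filled.

        Longer gaps (and gaps touching the record edges) are left as NaN.
        """
        filled = {}
        for label in self.labels:
            arr = self.positions[label].copy()
            good = np.isfinite(arr).all(axis=1)
            if good.all() or good.sum() < 4:
                filled[label] = arr
                continue
            idx = np.arange(arr.shape[0])
            spline = CubicSpline(idx[good], arr[good])
            # fill only interior runs of length <= max_gap
            bad = np.nonzero(~good)[0]
            runs = np.split(bad, np.nonzero(np.diff(bad) > 1)[0] + 1)
            for run in runs:
                if len(run) == 0 or len(run) > max_gap:
                    continue
                if run[0] == 0 or run[-1] == arr.shape[0] - 1:
                    continue
                arr[run] = spline(run)
            filled[label] = arr
        return MarkerTrajectories(list(self.labels), filled, self.rate)


@dataclass
class TendonPath:
    """Per-frame ordered point sequence insertion -> foil markers -> origin.

    ``points`` has shape (n_frames, n_foil + 2, 3) in mm.  Index 0 is the
    calcaneus insertion marker, the last index the skin-projected MTJ origin;
    the ordering is anatomical (distal to proximal) and fixed across frames.
    """

    points: np.ndarray
    rate: float = 250.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 3 or pts.shape[2] != 3 or pts.shape[1] < 2:
            raise InvalidInputError(
                "TendonPath points must be (n_frames, n_points >= 2, 3), "
                f"got shape {pts.shape}"
            )
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")
        self.points = pts

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_foil(self) -> int:
        """Number of interior foil markers (total points minus the two endpoints)."""
        return self.points.shape[1] - 2

    @property
    def insertion(self) -> np.ndarray:
        return self.points[:, 0, :]

    @property
    def origin(self) -> np.ndarray:
        return self.points[:, -1, :]

    def validate_subset(self, subset: Sequence[int]) -> Tuple[int, ...]:
        sub = tuple(int(i) for i in subset)
        if any(b <= a for a, b in zip(sub, sub[1:])):
            raise InvalidSubsetError(
                f"subset indices must be strictly increasing, got {sub}"
            )
        if sub and (sub[0] < 0 or sub[-1] >= self.n_foil):
            raise InvalidSubsetError(
                f"subset indices must lie in [0, {self.n_foil}), got {sub}"
            )
        return sub


@dataclass
class LengthSeries:
    """Per-frame AT length in mm, tagged with the method that produced it.

    ``method`` is ``"straight"``, ``"reference"`` or ``"subset"``; for subsets
    ``subset`` records the ordered foil-marker indices used.
    """

    values: np.ndarray
    method: str
    rate: float
    subset: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("LengthSeries values must be 1-D")
        if self.method not in ("straight", "reference", "subset"):
            raise InvalidParameterError(f"unknown method tag {self.method!r}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def tag(self) -> str:
        if self.method == "subset":
            return "subset(" + ",".join(map(str, self.subset or ())) + ")"
        return self.method


@dataclass
class StrainSeries:
    """Per-frame strain in percent relative to a resting length ``resting_length`` (mm)."""

    values: np.ndarray
    resting_length: float
    rate: float

    def __post_init__(self):
        if self.resting_length <= 0:
            raise InvalidParameterError(
                f"resting length must be > 0 mm, got {self.resting_length}"
            )
        self.values = np.asarray(self.values, dtype=float)

    @property
    def max_strain(self) -> float:
        """Maximum strain over the series (%), ignoring flagged gaps."""
        return float(np.nanmax(self.values))


def polyline_length(points) -> float:
    """Arc length of an ordered 3D polyline: sum of consecutive Euclidean distances.

    Raises
    ------
    InvalidInputError
        If fewer than two points are given.
    DataGapError
        If any coordinate is non-finite; the message names the offending rows.
    """
    pts = _as_points(points)
    if pts.shape[0] < 2:
        raise InvalidInputError(
            f"polyline needs at least 2 points, got {pts.shape[0]}"
        )
    finite = np.isfinite(pts).all(axis=1)
    if not finite.all():
        bad = np.nonzero(~finite)[0]
        raise DataGapError(
            f"non-finite coordinates at point index(es) {bad.tolist()}", frames=bad
        )
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def straight_length(origin, insertion) -> float:
    """Euclidean chord between AT origin and insertion (mm)."""
    o = np.asarray(origin, dtype=float)
    i = np.asarray(insertion, dtype=float)
    if o.shape != (3,) or i.shape != (3,):
        raise InvalidInputError("origin and insertion must each be a single 3D point")
    if not (np.isfinite(o).all() and np.isfinite(i).all()):
        raise DataGapError("non-finite coordinate in origin/insertion")
    return float(np.linalg.norm(o - i))


def _subset_column_indices(path: TendonPath, subset) -> np.ndarray:
    """Column indices into ``path.points`` for insertion + subset foil markers + origin."""
    sub = path.validate_subset(subset)
    return np.array([0, *[s + 1 for s in sub], path.points.shape[1] - 1])


def length_series(path: TendonPath, subset: Optional[Sequence[int]] = None) -> LengthSeries:
    """Per-frame AT length through a foil-marker subset (mm).

    ``subset`` holds strictly increasing foil-marker indices in
    ``[0, n_foil)``; ``None`` uses all foil markers (the curved *reference*
    length) and an empty subset yields the *straight* length.  Frames with a
    gap in any used marker yield NaN (flagged, never silently zero).
    """
    if subset is None:
        cols = np.arange(path.points.shape[1])
        method, sub = "reference", None
    else:
        cols = _subset_column_indices(path, subset)
        sub = path.validate_subset(subset)
        method = "straight" if len(sub) == 0 else "subset"
    pts = path.points[:, cols, :]
    seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)
    values = seg.sum(axis=1)
    values[~np.isfinite(pts).all(axis=(1, 2))] = np.nan
    return LengthSeries(values=values, method=method, rate=path.rate, subset=sub)


def strain_series(lengths: LengthSeries, resting_length: float) -> StrainSeries:
    """Strain (%) relative to resting length: ``100 * (L - L0) / L0``."""
    if resting_length <= 0:
        raise InvalidParameterError(
            f"resting length must be > 0 mm, got {resting_length}"
        )
    values = 100.0 * (lengths.values - resting_length) / resting_length
    return StrainSeries(values=values, resting_length=resting_length, rate=lengths.rate)
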