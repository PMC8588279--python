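"""Foil-marker reduction analysis for curved Achilles tendon length.

Given a tendon path with ``n`` interior foil markers, every subset of size
``r`` defines a candidate marker-set (MS``r``).  For each size the subset
whose length series has the lowest whole-stride RMSE against the all-marker
*reference* length is the optimal combination; its per-frame absolute length
error, stance/swing phase-averaged errors and maximum-strain error quantify
the cost of the reduction.  Pooling stride-mean errors across a cohort as a
function of the percentage of retained markers yields a saturation curve
whose R-squared plateau marks the point where additional markers no longer
improve accuracy, and rank-matched averaging of the optimal marker positions
produces a placement recommendation table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    InvalidSegmentationError,
)
from .gait import GaitEvents
from .geometry import LengthSeries, TendonPath, length_series, strain_series

__all__ = [
    "RECOMMENDED_PLACEMENTS_PCT",
    "ReductionConfig",
    "SubsetEvaluation",
    "ReductionResult",
    "SaturationCurve",
    "MarkerPlacementTable",
    "count_combinations",
    "enumerate_subsets",
    "subset_rmse",
    "optimal_subset",
    "phase_averaged_error",
    "max_strain_error",
    "evaluate_reduction",
    "saturation_analysis",
    "standing_marker_percentages",
    "average_marker_positions",
    "path_points_at_fractions",
    "apply_marker_positions",
]

# Reference placements for reduced marker-sets: foil-marker locations as a
# percentage of the standing Achilles tendon length measured from the
# calcaneus insertion marker (0%).  Shipped for display/comparison; the
# pipeline recomputes cohort-specific placements.
RECOMMENDED_PLACEMENTS_PCT: Dict[int, Tuple[float, ...]] = {
    2: (22.0, 56.0),
    3: (15.0, 35.0, 65.0),
    4: (10.0, 31.0, 47.0, 66.0),
}


@dataclass
class ReductionConfig:
    """Marker-reduction settings for one participant.

    ``n`` is the participant's total foil-marker count and ``r_values`` the
    subset sizes to evaluate (defaults to every size from 1 to ``n``).
    """

    n: int
    r_values: Optional[Sequence[int]] = None

    def __post_init__(self):
        if self.n < 1:
            raise InvalidParameterError(f"need at least one foil marker, got n={self.n}")
        if self.r_values is None:
            self.r_values = tuple(range(1, self.n + 1))
        else:
            self.r_values = tuple(int(r) for r in self.r_values)
            for r in self.r_values:
                if not 1 <= r <= self.n:
                    raise InvalidParameterError(
                        f"subset size r={r} outside [1, n={self.n}]"
                    )


def count_combinations(n: int, r: int) -> int:
    """Number of foil-marker combinations C(n, r) = n! / ((n-r)! r!)."""
    if r < 0 or n < 0:
        raise InvalidParameterError(f"n and r must be non-negative, got n={n}, r={r}")
    if r > n:
        raise InvalidParameterError(f"cannot choose r={r} markers out of n={n}")
    return math.comb(n, r)


def enumerate_subsets(n: int, r: int) -> List[Tuple[int, ...]]:
    """All strictly increasing index subsets of size ``r`` from ``range(n)``,
    in lexicographic order (anatomical marker order preserved)."""
    count_combinations(n, r)  # validates
    return list(itertools.combinations(range(n), r))


def _pairwise_distances(path: TendonPath, frames: Optional[np.ndarray] = None) -> np.ndarray:
    pts = path.points if frames is None else path.points[frames]
    diff = pts[:, :, None, :] - pts[:, None, :, :]
    return np.linalg.norm(diff, axis=3)


def _subset_lengths_from_D(D: np.ndarray, subset: Sequence[int], n_cols: int) -> np.ndarray:
    idx = np.array([0, *[s + 1 for s in subset], n_cols - 1])
    return D[:, idx[:-1], idx[1:]].sum(axis=1)


def subset_rmse(
    path: TendonPath,
    subset: Sequence[int],
    reference: LengthSeries,
    frames: Optional[np.ndarray] = None,
) -> float:
    """Whole-stride RMSE (mm) of the subset length against the reference length."""
    if reference.n_frames != path.n_frames:
        raise InvalidInputError(
            f"reference has {reference.n_frames} frames, path has {path.n_frames}"
        )
    sub = length_series(path, subset).values
    ref = reference.values
    if frames is not None:
        sub, ref = sub[frames], ref[frames]
    return float(np.sqrt(np.mean((sub - ref) ** 2)))


@dataclass
class SubsetEvaluation:
    """Optimal marker-set of one size: the subset, its RMSE and error series."""

    r: int
    subset: Tuple[int, ...]
    rmse: float
    abs_error: np.ndarray  # per-frame |L_subset - L_ref| (mm), full record, NaN outside
    stance_error: float
    swing_error: float
    stride_error: float
    max_strain_error: float


@dataclass
class ReductionResult:
    """Per-size optimal marker-sets for one trial."""

    n: int
    by_r: Dict[int, SubsetEvaluation]
    n_combinations_evaluated: int

    def rmse_by_r(self) -> Dict[int, float]:
        return {r: e.rmse for r, e in sorted(self.by_r.items())}


def optimal_subset(
    path: TendonPath,
    r: int,
    events: Optional[GaitEvents] = None,
    frames: Optional[np.ndarray] = None,
) -> Tuple[Tuple[int, ...], float, np.ndarray]:
    """RMSE-optimal size-``r`` marker combination over the whole stride.

    Frames default to the complete strides delimited by ``events``.  Ties in
    RMSE are broken lexicographically (the most distal markers win).  Returns
    ``(subset, rmse, per_frame_abs_error)``; the error covers the full record
    with NaN outside the analyzed frames.
    """
    if frames is None:
        if events is not None:
            frames = events.stride_frames
            if len(frames) == 0:
                raise InvalidSegmentationError("events delimit no complete stride")
        else:
            frames = np.arange(path.n_frames)
    n = path.n_foil
    m = n + 2
    D = _pairwise_distances(path, frames)
    ref = _subset_lengths_from_D(D, tuple(range(n)), m)
    best: Optional[Tuple[Tuple[int, ...], float, np.ndarray]] = None
    for subset in enumerate_subsets(n, r):
        lengths = _subset_lengths_from_D(D, subset, m)
        rmse = float(np.sqrt(np.mean((lengths - ref) ** 2)))
        if best is None or rmse < best[1]:
            best = (subset, rmse, lengths)
    subset, rmse, lengths = best
    abs_error = np.full(path.n_frames, np.nan)
    abs_error[frames] = np.abs(lengths - ref)
    return subset, rmse, abs_error


def phase_averaged_error(
    abs_error: np.ndarray, events: GaitEvents
) -> Tuple[float, float, float]:
    """Mean absolute error (mm) over stance, swing and the whole stride."""
    err = np.asarray(abs_error, dtype=float)
    if err.shape[0] != events.n_frames:
        raise InvalidInputError(
            f"error series has {err.shape[0]} frames, events cover {events.n_frames}"
        )
    labels = events.phase_labels
    means = []
    for phase in ("stance", "swing"):
        mask = (labels == phase) & np.isfinite(err)
        if not mask.any():
            raise InvalidSegmentationError(f"no frames labelled {phase!r} with valid error")
        means.append(float(err[mask].mean()))
    stride_mask = (labels != "none") & np.isfinite(err)
    means.append(float(err[stride_mask].mean()))
    return tuple(means)


def max_strain_error(
    path: TendonPath,
    subset: Sequence[int],
    resting_length: float,
    frames: Optional[np.ndarray] = None,
) -> float:
    """Absolute difference (% strain) between the subset's and the reference's
    maximum strain over the analyzed frames."""
    ref = length_series(path)
    sub = length_series(path, subset)
    if frames is not None:
        ref = LengthSeries(ref.values[frames], "reference", path.rate)
        sub_vals = sub.values[frames]
        sub = LengthSeries(sub_vals, sub.method, path.rate, sub.subset)
    s_ref = strain_series(ref, resting_length).max_strain
    s_sub = strain_series(sub, resting_length).max_strain
    return abs(s_sub - s_ref)


def evaluate_reduction(
    path: TendonPath,
    events: GaitEvents,
    resting_length: float,
    config: Optional[ReductionConfig] = None,
) -> ReductionResult:
    """Run the full per-trial reduction: optimal subset, RMSE, phase errors
    and maximum-strain error for every requested marker-set size."""
    config = config or ReductionConfig(n=path.n_foil)
    if config.n != path.n_foil:
        raise InvalidParameterError(
            f"config.n={config.n} does not match path.n_foil={path.n_foil}"
        )
    frames = events.stride_frames
    if len(frames) == 0:
        raise InvalidSegmentationError("events delimit no complete stride")
    by_r: Dict[int, SubsetEvaluation] = {}
    n_eval = 0
    for r in config.r_values:
        subset, rmse, abs_error = optimal_subset(path, r, frames=frames)
        n_eval += count_combinations(config.n, r)
        stance, swing, stride = phase_averaged_error(abs_error, events)
        strain_err = max_strain_error(path, subset, resting_length, frames=frames)
        by_r[r] = SubsetEvaluation(
            r=r,
            subset=subset,
            rmse=rmse,
            abs_error=abs_error,
            stance_error=stance,
            swing_error=swing,
            stride_error=stride,
            max_strain_error=strain_err,
        )
    return ReductionResult(n=config.n, by_r=by_r, n_combinations_evaluated=n_eval)


# --------------------------------------------------------------------------
# saturation analysis


@dataclass
class SaturationCurve:
    """Error-vs-marker-percentage curve with its R-squared saturation profile.

    ``percentages`` is the common 100-point interpolation grid (0-100% of
    retained markers), ``errors_by_individual`` each individual's error
    interpolated onto it, ``r_squared`` the cumulative-window sequence at
    integer percentages 1..100 (regression over pooled points with pct <= p)
    and ``r_squared_tail`` the tail-window sequence (points with pct >= p)
    used by the plateau detector.  ``plateau_pct`` is the smallest integer p
    for which the detector sequence stays at or above ``threshold`` for all
    q >= p (NaN when undefined or when the cohort error is identically zero).
    """

    percentages: np.ndarray
    errors_by_individual: Dict[object, np.ndarray]
    r_squared: np.ndarray
    r_squared_tail: np.ndarray
    plateau_pct: float
    threshold: float
    degenerate: bool = False

    @property
    def mean_error(self) -> np.ndarray:
        return np.mean(list(self.errors_by_individual.values()), axis=0)

    def mean_error_at(self, pct: float) -> float:
        return float(np.interp(pct, self.percentages, self.mean_error))


def _simple_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R-squared of a simple linear regression of y on x.

    Conventions for degenerate windows: zero variance in y means the constant
    line fits exactly (R^2 = 1); zero variance in x (or fewer than 3 points)
    leaves the regression undefined (NaN).
    """
    if y.size and np.ptp(y) == 0:
        return 1.0
    if x.size < 3 or np.ptp(x) == 0:
        return float("nan")
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return float(sxy * sxy / (sxx * syy))


def saturation_analysis(
    errors_by_r: Mapping[object, Mapping[int, float]],
    n_by_individual: Mapping[object, int],
    threshold: float = 0.99,
    n_grid: int = 100,
    plateau_window: str = "tail",
    sustain: Optional[int] = 10,
) -> SaturationCurve:
    """Pool per-individual stride-mean errors by marker percentage and locate
    the accuracy-saturation plateau.

    Each individual contributes the straight-length error at 0% (``r = 0``
    key), errors at ``100 * r / n`` for every evaluated subset size, and 0 mm
    at 100% (the reference against itself), linearly interpolated onto a
    common ``n_grid``-point percentage grid.  At every integer percentage p a
    simple linear regression is fitted to the pooled interpolated points —
    both over the cumulative window (pct <= p, the reported ``r_squared``
    curve) and over the tail window (pct >= p) — and the plateau is the
    smallest p at which the ``plateau_window`` R-squared sequence reaches
    ``threshold`` and maintains it over the next ``sustain`` grid points
    (``sustain=None`` demands it hold through 100%; the default window of 10
    tolerates later dips within numerical noise of the threshold, which occur
    whenever the curve saturates right at it).

    Raises
    ------
    InsufficientDataError
        For a single individual contributing fewer than two evaluated sizes.
    """
    if plateau_window not in ("tail", "cumulative"):
        raise InvalidParameterError(f"unknown plateau window {plateau_window!r}")
    if not errors_by_r:
        raise InsufficientDataError("no individuals supplied")
    if len(errors_by_r) == 1:
        (only,) = errors_by_r.values()
        if len([r for r in only if r > 0]) < 2:
            raise InsufficientDataError(
                "a single individual with a single subset size cannot define a curve"
            )
    grid = np.linspace(0.0, 100.0, n_grid)
    interp: Dict[object, np.ndarray] = {}
    for ind, errs in errors_by_r.items():
        n = n_by_individual[ind]
        pts = {0.0: float(errs.get(0, errs.get(0.0, np.nan)))}
        if not np.isfinite(pts[0.0]):
            raise InvalidInputError(
                f"individual {ind!r} must supply the straight-length error at r=0"
            )
        for r, e in errs.items():
            if r == 0:
                continue
            if not 1 <= r <= n:
                raise InvalidParameterError(f"individual {ind!r}: r={r} outside [1, {n}]")
            pts[100.0 * r / n] = float(e)
        pts[100.0] = pts.get(100.0, 0.0)
        xs = np.array(sorted(pts))
        ys = np.array([pts[x] for x in xs])
        interp[ind] = np.interp(grid, xs, ys)
    pooled_x = np.tile(grid, len(interp))
    pooled_y = np.concatenate(list(interp.values()))
    degenerate = bool(np.allclose(pooled_y, 0.0))
    pcts = np.arange(1, 101)
    if degenerate:
        r2_cum = np.full(100, np.nan)
        r2_tail = np.full(100, np.nan)
        plateau = float("nan")
    else:
        r2_cum = np.array(
            [_simple_r2(pooled_x[pooled_x <= p], pooled_y[pooled_x <= p]) for p in pcts]
        )
        r2_tail = np.array(
            [_simple_r2(pooled_x[pooled_x >= p], pooled_y[pooled_x >= p]) for p in pcts]
        )
        seq = r2_tail if plateau_window == "tail" else r2_cum
        ok = seq >= threshold  # NaN compares False
        plateau = float("nan")
        for i in range(len(pcts)):
            stop = len(pcts) if sustain is None else min(len(pcts), i + sustain)
            if ok[i:stop].all():
                plateau = float(pcts[i])
                break
    return SaturationCurve(
        percentages=grid,
        errors_by_individual=interp,
        r_squared=r2_cum,
        r_squared_tail=r2_tail,
        plateau_pct=plateau,
        threshold=threshold,
        degenerate=degenerate,
    )


# --------------------------------------------------------------------------
# average marker positions (placement table)


@dataclass
class MarkerPlacementTable:
    """Rank-matched average optimal marker locations per marker-set size.

    Locations are percentages of the standing AT length from the calcaneus
    marker (0%); ``application_error`` maps individual -> whole-stride RMSE
    (mm) of imposing the averaged positions instead of the individual optimum.
    """

    positions_pct: Dict[int, np.ndarray]
    n_records: Dict[int, int]
    application_error: Dict[int, Dict[object, float]] = field(default_factory=dict)

    def __post_init__(self):
        for r, pos in self.positions_pct.items():
            pos = np.asarray(pos, dtype=float)
            if (np.diff(pos) <= 0).any() or (pos <= 0).any() or (pos >= 100).any():
                raise InvalidInputError(
                    f"marker-set {r}: positions must be strictly increasing in (0, 100), got {pos}"
                )
            self.positions_pct[r] = pos


def standing_marker_percentages(standing_path: TendonPath, frame: int = 0) -> np.ndarray:
    """Each foil marker's arc-length position as % of the standing AT length.

    Measured along the full marker polyline of the standing trial from the
    calcaneus marker (0%) to the MTJ origin (100%).
    """
    pts = standing_path.points[frame]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return 100.0 * cum[1:-1] / cum[-1]


def average_marker_positions(
    records: Iterable[Mapping],
    standing_pcts: Mapping[object, np.ndarray],
) -> MarkerPlacementTable:
    """Rank-matched average of optimal marker positions across trials/individuals.

    ``records`` holds mappings with keys ``individual``, ``r`` and ``subset``
    (the optimal foil-marker indices); ``standing_pcts`` maps each individual
    to its per-marker standing-percentage positions.  Within each marker-set
    size the most distal selected markers are averaged together, the second
    most distal together, and so on.
    """
    by_r: Dict[int, List[np.ndarray]] = {}
    for rec in records:
        ind, r, subset = rec["individual"], int(rec["r"]), rec["subset"]
        pcts = np.asarray(standing_pcts[ind], dtype=float)
        sel = pcts[list(subset)]
        by_r.setdefault(r, []).append(sel)
    if not by_r:
        raise InsufficientDataError("no records to average")
    positions = {r: np.mean(sels, axis=0) for r, sels in sorted(by_r.items())}
    counts = {r: len(sels) for r, sels in by_r.items()}
    return MarkerPlacementTable(positions_pct=positions, n_records=counts)


def path_points_at_fractions(path: TendonPath, fractions: Sequence[float]) -> np.ndarray:
    """Interpolate points at given arc-length fractions of the per-frame polyline.

    Returns an array of shape (n_frames, len(fractions), 3): for each frame
    the point at fraction ``f`` of that frame's total polyline arc length,
    interpolated linearly along the full marker polyline.
    """
    frac = np.asarray(fractions, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise InvalidParameterError(f"fractions must lie in [0, 1], got {frac}")
    pts = path.points
    seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)
    cum = np.concatenate([np.zeros((pts.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1)
    total = cum[:, -1:]
    out = np.empty((pts.shape[0], frac.size, 3))
    for f_idx in range(pts.shape[0]):
        s = frac * total[f_idx, 0]
        for d in range(3):
            out[f_idx, :, d] = np.interp(s, cum[f_idx], pts[f_idx, :, d])
    return out


def apply_marker_positions(
    path: TendonPath,
    positions_pct: Sequence[float],
    frames: Optional[np.ndarray] = None,
) -> float:
    """Whole-stride RMSE (mm) of the AT length measured with virtual markers at
    the given standing-percentage positions, against the all-marker reference.

    The virtual markers ride the skin: each stays at a fixed fraction of the
    instantaneous full-polyline arc length (uniform skin-stretch assumption).
    """
    fracs = np.asarray(positions_pct, dtype=float) / 100.0
    virtual = path_points_at_fractions(path, fracs)
    pts = np.concatenate(
        [path.points[:, :1, :], virtual, path.points[:, -1:, :]], axis=1
    )
    vlen = np.linalg.norm(np.diff(pts, axis=1), axis=2).sum(axis=1)
    ref = length_series(path).values
    if frames is not None:
        vlen, ref = vlen[frames], ref[frames]
    return float(np.sqrt(np.mean((vlen - ref) ** 2)))
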