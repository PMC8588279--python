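"""Ultrasound-to-global registration of the gastrocnemius medialis MTJ.

The MTJ (the Achilles tendon origin) is tracked in B-mode ultrasound images.
To express it in the motion-capture (global) frame the probe pose is
recovered from a rigid marker tripod mounted on the transducer, a probe
calibration maps image pixels to millimetres in the tripod frame, the skin
surface is detected in the image (Canny), the MTJ is projected to the skin by
shortest distance, and the projected point is transformed to the lab frame.

Image convention: row = depth (increasing away from the skin surface),
column = position along the transducer face; the image coordinate anchor is
the left-center of the transducer's front protective layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import feature

from .errors import (
    DegenerateConfigurationError,
    DetectionFailureError,
    InvalidInputError,
    InvalidParameterError,
    InvalidSyncError,
)

__all__ = [
    "UltrasoundFrame",
    "ProbePose",
    "ProbeCalibration",
    "fit_rigid_transform",
    "detect_skin_line",
    "project_mtj_to_skin",
    "image_to_global",
    "global_to_image",
    "synchronize_streams",
]


@dataclass
class UltrasoundFrame:
    """A grayscale B-mode frame with its pixel spacing in mm (row, col)."""

    pixels: np.ndarray
    spacing: Tuple[float, float] = (0.1, 0.1)
    index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise InvalidInputError("ultrasound frame must be a 2-D grayscale grid")
        if not np.isfinite(self.pixels).all():
            raise InvalidInputError("ultrasound frame contains non-finite intensities")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise InvalidParameterError(f"pixel spacing must be > 0, got {self.spacing}")


@dataclass
class ProbePose:
    """Rigid transform tripod -> global: ``x_global = rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise InvalidInputError("pose needs a 3x3 rotation and a 3-vector translation")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidInputError("rotation is not orthonormal (R'R != I within 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InvalidInputError("rotation determinant is not +1 (reflection?)")
        self.rotation, self.translation = R, t

    def apply(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse_apply(self, points) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.translation) @ self.rotation


@dataclass
class ProbeCalibration:
    """Digitized transducer front-layer geometry in the tripod frame.

    ``corners`` holds the four digitized corners of the protective front
    layer, ordered left-near, right-near, right-far, left-far (near/far along
    the layer's short side).  The image coordinate system is anchored at the
    left-center of the layer: columns run along the face toward the right
    edge, rows run along the scan plane into the tissue (the face normal,
    whose sign is set by ``depth_sign``).
    """

    corners: np.ndarray
    depth_sign: float = 1.0
    max_out_of_plane: float = 0.5

    image_origin: np.ndarray = field(init=False)
    col_axis: np.ndarray = field(init=False)
    row_axis: np.ndarray = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.corners, dtype=float)
        if c.shape != (4, 3):
            raise InvalidInputError("calibration needs exactly four 3D corner points")
        centroid = c.mean(axis=0)
        # coplanarity check: smallest singular value = max out-of-plane extent scale
        _, s, vt = np.linalg.svd(c - centroid)
        if s[-1] > self.max_out_of_plane:
            raise InvalidParameterError(
                f"corners deviate from a plane by {s[-1]:.3f} mm "
                f"(max allowed {self.max_out_of_plane} mm)"
            )
        left_mid = 0.5 * (c[0] + c[3])
        right_mid = 0.5 * (c[1] + c[2])
        u = right_mid - left_mid
        nu = np.linalg.norm(u)
        if nu == 0:
            raise DegenerateConfigurationError("left and right edge midpoints coincide")
        self.col_axis = u / nu
        normal = np.cross(c[1] - c[0], c[3] - c[0])
        nn = np.linalg.norm(normal)
        if nn == 0:
            raise DegenerateConfigurationError("degenerate corner configuration")
        self.row_axis = float(np.sign(self.depth_sign)) * normal / nn
        self.image_origin = left_mid


def fit_rigid_transform(source, target) -> ProbePose:
    """Least-squares rigid transform (Kabsch): min over R (det +1), t of
    ``sum ||R s_i + t - g_i||^2``.

    Returns the pose with its RMS point-mapping residual in mm.
    """
    s = np.asarray(source, dtype=float)
    g = np.asarray(target, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3 or s.shape != g.shape:
        raise InvalidInputError(
            f"source/target must be matched (N, 3) arrays, got {s.shape} and {g.shape}"
        )
    if s.shape[0] < 3:
        raise InvalidInputError(f"need at least 3 point pairs, got {s.shape[0]}")
    sc, gc = s.mean(axis=0), g.mean(axis=0)
    s0, g0 = s - sc, g - gc
    # collinearity: rank of centred source must be >= 2
    if np.linalg.matrix_rank(s0, tol=1e-9 * max(1.0, np.abs(s0).max())) < 2:
        raise DegenerateConfigurationError("source points are collinear")
    H = s0.T @ g0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = gc - R @ sc
    resid = float(np.sqrt(np.mean(np.sum((s @ R.T + t - g) ** 2, axis=1))))
    return ProbePose(rotation=R, translation=t, residual=resid)


def detect_skin_line(
    frame: UltrasoundFrame,
    sigma: float = 2.0,
    low_quantile: float = 0.70,
    high_quantile: float = 0.90,
    smooth_width: int = 5,
    max_missing_frac: float = 0.5,
) -> np.ndarray:
    """Detect the superficial skin interface as one row per image column.

    Canny edges (Gaussian ``sigma``, hysteresis thresholds at the given
    gradient-magnitude quantiles) are computed, the most superficial edge per
    column is taken, and the row is refined to the onset of the bright
    interface (first row within a small window reaching 90% of the local
    intensity maximum).  Single-column outliers are suppressed with a median
    filter of ``smooth_width`` columns.

    Returns an (M, 2) array of (row, col) points, one per column with an
    accepted edge, single-valued in the column coordinate.

    Raises
    ------
    DetectionFailureError
        If more than ``max_missing_frac`` of the columns have no edge.
    """
    img = frame.pixels
    span = img.max() - img.min()
    if span == 0:
        raise DetectionFailureError("flat image: no edges detectable")
    edges = feature.canny(
        img / span,
        sigma=sigma,
        low_threshold=low_quantile,
        high_threshold=high_quantile,
        use_quantiles=True,
    )
    n_rows, n_cols = img.shape
    rows = np.full(n_cols, np.nan)
    half = int(np.ceil(2 * sigma)) + 2
    for col in range(n_cols):
        hits = np.nonzero(edges[:, col])[0]
        if len(hits) == 0:
            continue
        top = hits[0]
        lo, hi = max(0, top - half), min(n_rows, top + half + 1)
        window = img[lo:hi, col]
        wmax = window.max()
        if wmax <= img[:, col].min():
            continue
        onset = lo + int(np.argmax(window >= 0.9 * wmax))
        rows[col] = onset
    valid = np.isfinite(rows)
    if valid.sum() < (1 - max_missing_frac) * n_cols:
        raise DetectionFailureError(
            f"skin edge found in only {int(valid.sum())}/{n_cols} columns"
        )
    if smooth_width > 1 and valid.sum() >= smooth_width:
        rows[valid] = ndimage.median_filter(rows[valid], size=smooth_width, mode="nearest")
    cols = np.nonzero(valid)[0]
    return np.column_stack([rows[cols], cols.astype(float)])


def project_mtj_to_skin(mtj_px, skin: np.ndarray) -> np.ndarray:
    """Closest point on the skin polyline (vertices and segment interiors) to the MTJ.

    ``mtj_px`` and the returned point are (row, col) pixel coordinates.
    """
    p = np.asarray(mtj_px, dtype=float)
    line = np.asarray(skin, dtype=float)
    if line.ndim != 2 or line.shape[1] != 2 or line.shape[0] == 0:
        raise InvalidInputError("skin polyline must be a non-empty (M, 2) array")
    if line.shape[0] == 1:
        return line[0].copy()
    a, b = line[:-1], line[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, np.einsum("ij,ij->i", p - a, ab) / denom, 0.0)
    t = np.clip(t, 0.0, 1.0)
    cand = a + t[:, None] * ab
    d2 = np.sum((cand - p) ** 2, axis=1)
    return cand[int(np.argmin(d2))].copy()


def image_to_global(
    point_px,
    frame: UltrasoundFrame,
    calib: ProbeCalibration,
    pose: ProbePose,
) -> np.ndarray:
    """Map an in-image (row, col) pixel point to a 3D global point in mm.

    Pixels scale to mm via the frame spacing, anchor at the calibrated image
    origin (left-center of the front layer) along the calibrated column/row
    axes in the tripod frame, then transform rigidly into the global frame.
    """
    row, col = (float(v) for v in np.asarray(point_px, dtype=float))
    p_tripod = (
        calib.image_origin
        + col * frame.spacing[1] * calib.col_axis
        + row * frame.spacing[0] * calib.row_axis
    )
    return pose.apply(p_tripod[None, :])[0]


def global_to_image(
    point_global,
    frame: UltrasoundFrame,
    calib: ProbeCalibration,
    pose: ProbePose,
) -> np.ndarray:
    """Inverse of :func:`image_to_global` for in-plane points: global mm -> (row, col).

    The out-of-plane component is dropped (the scan plane is assumed to
    contain the point; see the module docstring).
    """
    p_tripod = pose.inverse_apply(np.asarray(point_global, dtype=float)[None, :])[0]
    rel = p_tripod - calib.image_origin
    col = float(rel @ calib.col_axis) / frame.spacing[1]
    row = float(rel @ calib.row_axis) / frame.spacing[0]
    return np.array([row, col])


def synchronize_streams(
    us_rate: float,
    mocap_rate: float,
    trigger_frame_us: int,
    trigger_frame_mocap: int,
    n_mocap_frames: int,
    n_us_frames: Optional[int] = None,
    mode: str = "nearest",
) -> np.ndarray:
    """Map each mocap frame to an ultrasound sample index, anchored at the trigger.

    ``mode="nearest"`` returns integer indices (nearest neighbour);
    ``mode="linear"`` returns fractional indices for interpolation.
    """
    if us_rate <= 0 or mocap_rate <= 0:
        raise InvalidParameterError("rates must be > 0")
    if trigger_frame_mocap < 0 or trigger_frame_mocap >= n_mocap_frames:
        raise InvalidSyncError(
            f"mocap trigger frame {trigger_frame_mocap} outside [0, {n_mocap_frames})"
        )
    if n_us_frames is not None and not 0 <= trigger_frame_us < n_us_frames:
        raise InvalidSyncError(
            f"ultrasound trigger frame {trigger_frame_us} outside [0, {n_us_frames})"
        )
    k = np.arange(n_mocap_frames)
    us_index = trigger_frame_us + (k - trigger_frame_mocap) * us_rate / mocap_rate
    if mode == "linear":
        mapped = us_index
    elif mode == "nearest":
        mapped = np.round(us_index).astype(int)
    else:
        raise InvalidParameterError(f"unknown sync mode {mode!r}")
    if n_us_frames is not None:
        mapped = np.clip(mapped, 0, n_us_frames - 1)
    return mapped
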