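"""File readers and writers: TRC marker files, MTJ pixel CSVs, probe
calibration JSON, and the tidy CSV outputs of the pipeline.

Internal coordinates are millimetres in a Z-up lab frame (+X direction of
progression).  TRC files are Y-up by convention; the reader maps file axes
(fx, fy, fz) onto internal (fx, -fz, fy) and the writer inverts the mapping.
CSV outputs use UTF-8, a period decimal separator, a header row, and one
leading ``#`` comment line carrying the package version, config hash and
seed so that runs are traceable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError, ParseError, UnitError
from .gait import FilterSpec
from .geometry import MarkerTrajectories
from .ultrasound import ProbeCalibration

__all__ = [
    "read_trc",
    "write_trc",
    "read_mtj_csv",
    "write_mtj_csv",
    "read_calibration_json",
    "write_calibration_json",
    "PipelineConfig",
    "config_hash",
    "write_output_csv",
    "read_output_csv",
]

_TRC_DECIMALS = 5
# Y-up TRC file frame -> Z-up internal frame
_TRC_TO_INTERNAL = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


def read_trc(path, to_internal: bool = True) -> MarkerTrajectories:
    """Read a TRC marker-trajectory file into millimetre positions.

    Handles ``Units`` of mm or m (metre files are scaled by 1000) and keeps
    gaps (empty fields) as NaN.  With ``to_internal`` the Y-up TRC axes are
    mapped onto the package's Z-up convention.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise ParseError(f"{path}: fewer than 5 header lines")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed TRC header at line 3: {exc}") from exc
    if units not in ("mm", "m"):
        raise UnitError(f"{path}: unsupported units {units!r} (expected mm or m)")
    scale = 1000.0 if units == "m" else 1.0
    labels = [l for l in lines[3].split("\t")[2:] if l.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}: header declares {n_markers} markers, label row has {len(labels)}"
        )
    data_lines = [l for l in lines[5:] if l.strip()]
    if len(data_lines) != n_frames:
        raise ParseError(
            f"{path}: header declares {n_frames} frames, found {len(data_lines)} data rows"
        )
    positions = {label: np.full((n_frames, 3), np.nan) for label in labels}
    for i, line in enumerate(data_lines):
        fields = line.split("\t")
        expected = 2 + 3 * n_markers
        if len(fields) < expected:
            raise ParseError(
                f"{path}: truncated data row for frame {i + 1} "
                f"({len(fields)} fields, expected {expected})"
            )
        for m, label in enumerate(labels):
            triple = fields[2 + 3 * m : 5 + 3 * m]
            if any(f.strip() == "" for f in triple):
                continue  # gap stays NaN
            try:
                positions[label][i] = [float(f) for f in triple]
            except ValueError as exc:
                raise ParseError(f"{path}: bad number in frame {i + 1}: {exc}") from exc
    for label in labels:
        positions[label] *= scale
        if to_internal:
            positions[label] = positions[label] @ _TRC_TO_INTERNAL.T
    return MarkerTrajectories(labels=labels, positions=positions, rate=rate)


def write_trc(traj: MarkerTrajectories, path, from_internal: bool = True) -> None:
    """Write a TRC file (mm, Y-up on disk) from internal Z-up trajectories."""
    path = Path(path)
    n = traj.n_frames
    labels = list(traj.labels)
    rows: List[str] = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{traj.rate:g}\t{traj.rate:g}\t{n}\t{len(labels)}\tmm\t{traj.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t",
        "\t\t" + "\t".join(f"X{m + 1}\tY{m + 1}\tZ{m + 1}" for m in range(len(labels))),
    ]
    inv = _TRC_TO_INTERNAL.T if from_internal else np.eye(3)
    data = {l: traj.positions[l] @ inv.T for l in labels} if from_internal else traj.positions
    for i in range(n):
        fields = [str(i + 1), f"{i / traj.rate:.{_TRC_DECIMALS}f}"]
        for label in labels:
            p = data[label][i]
            if np.isfinite(p).all():
                fields.extend(f"{v:.{_TRC_DECIMALS}f}" for v in p)
            else:
                fields.extend(["", "", ""])
        rows.append("\t".join(fields))
    path.write_text("\n".join(rows) + "\n")


def read_mtj_csv(path) -> pd.DataFrame:
    """Read pre-tracked MTJ pixel coordinates: columns frame, row_px, col_px."""
    df = pd.read_csv(path, comment="#")
    missing = {"frame", "row_px", "col_px"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: MTJ CSV missing columns {sorted(missing)}")
    return df


def write_mtj_csv(mtj_px: np.ndarray, path, skin_row: Optional[float] = None) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(1, len(mtj_px) + 1),
            "row_px": mtj_px[:, 0],
            "col_px": mtj_px[:, 1],
        }
    )
    if skin_row is not None:
        df["skin_row_px"] = skin_row
    df.to_csv(path, index=False, float_format="%.4f")


def read_calibration_json(path) -> Tuple[ProbeCalibration, dict]:
    """Read a probe calibration: corners, depth sign, pixel spacing, extras."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        calib = ProbeCalibration(
            corners=np.asarray(doc["corners_mm"], dtype=float),
            depth_sign=float(doc.get("depth_sign", 1.0)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: calibration JSON missing {exc}") from exc
    return calib, doc


def write_calibration_json(
    calib: ProbeCalibration,
    path,
    pixel_spacing: float,
    tripod_source: Optional[np.ndarray] = None,
    **extra,
) -> None:
    doc = {
        "corners_mm": np.asarray(calib.corners, dtype=float).tolist(),
        "depth_sign": float(calib.depth_sign),
        "pixel_spacing_mm": float(pixel_spacing),
    }
    if tripod_source is not None:
        doc["tripod_source_mm"] = np.asarray(tripod_source, dtype=float).tolist()
    doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineConfig:
    """Full-pipeline configuration.

    In simulate mode (default) a cohort is generated from ``seed``; in file
    mode ``trc_path``/``mtj_path``/``calibration_path``/``resting_length``
    describe a single recorded trial.  ``mode`` labels the gait condition and
    selects the event-detection rules (walking rules for "walking", knee-angle
    rules for the running modes).
    """

    out_dir: str = "atcurve_out"
    seed: int = 0
    mode: str = "walking"
    simulate: bool = True
    n_individuals: int = 11
    foil_counts: Optional[Sequence[int]] = None
    n_strides: int = 10
    r_values: Optional[Sequence[int]] = None
    sim_overrides: Dict[str, float] = field(default_factory=dict)
    trc_path: Optional[str] = None
    mtj_path: Optional[str] = None
    calibration_path: Optional[str] = None
    resting_length: Optional[float] = None
    filter_order: int = 4
    filter_cutoff: float = 12.0
    plateau_threshold: float = 0.99
    plateau_window: str = "tail"
    placement_sizes: Sequence[int] = (2, 3, 4)
    calcaneus_label: str = "calcaneus"
    foil_prefix: str = "foil_"
    verbosity: int = 1

    def __post_init__(self):
        if self.mode not in ("walking", "slow_run", "fast_run"):
            raise InvalidParameterError(f"unknown gait mode {self.mode!r}")
        if not self.simulate:
            for name in ("trc_path", "mtj_path", "calibration_path", "resting_length"):
                if getattr(self, name) is None:
                    raise InvalidParameterError(f"file mode requires {name}")

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.filter_order, cutoff=self.filter_cutoff)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("foil_counts", "r_values", "placement_sizes"):
            if out[key] is not None:
                out[key] = list(out[key])
        return out


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific configuration (run location and chattiness
    excluded, so reruns of the same analysis hash identically)."""
    doc = config.to_dict()
    doc.pop("out_dir", None)
    doc.pop("verbosity", None)
    blob = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_line(config: PipelineConfig, version: str) -> str:
    return f"# atcurve {version} config_sha={config_hash(config)} seed={config.seed}"


def write_output_csv(df: pd.DataFrame, path, config: PipelineConfig, version: str) -> None:
    """Write a tidy output CSV with the provenance comment line; floats are
    formatted to 6 decimals so repeated runs are byte-identical."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(_provenance_line(config, version) + "\n")
        df.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")


def read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
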