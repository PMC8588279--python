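"""End-to-end pipeline: events -> lengths -> strain -> reduction ->
saturation -> placement table, with tidy CSV outputs.

The pipeline runs either on a simulated cohort (default; the synthetic
trials carry analytic ground truth) or on recorded files (TRC markers, MTJ
pixel CSV, probe calibration JSON).  Every output CSV carries a provenance
comment line with the package version, config hash and seed; a failed stage
removes partial outputs and re-raises with the stage name.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ATCurveError, InvalidParameterError
from .gait import (
    FilterSpec,
    GaitEvents,
    detect_events_running,
    detect_footoff_walking,
    detect_touchdown_walking,
    knee_angle,
    lowpass_zero_phase,
)
from .geometry import MarkerTrajectories, TendonPath, length_series, strain_series
from .io import (
    PipelineConfig,
    read_calibration_json,
    read_mtj_csv,
    read_trc,
    write_calibration_json,
    write_mtj_csv,
    write_output_csv,
    write_trc,
)
from .reduction import (
    ReductionConfig,
    ReductionResult,
    SaturationCurve,
    apply_marker_positions,
    average_marker_positions,
    evaluate_reduction,
    saturation_analysis,
    standing_marker_percentages,
)
from .simulate import SyntheticTrial, make_cohort
from .ultrasound import (
    UltrasoundFrame,
    fit_rigid_transform,
    image_to_global,
    project_mtj_to_skin,
    synchronize_streams,
)

__all__ = [
    "TrialAnalysis",
    "PipelineResult",
    "detect_trial_events",
    "analyze_trial",
    "load_trial_from_files",
    "export_trial",
    "run_pipeline",
]


def detect_trial_events(
    markers: MarkerTrajectories,
    mode: str,
    spec: Optional[FilterSpec] = None,
) -> GaitEvents:
    """Detect gait events from the joint markers of a trial.

    Walking: heel-height minima (touchdown) and toe AP-velocity reversals
    (foot-off).  Running modes: first/second knee-extension maxima per
    stride.  Marker positions are low-pass filtered (4th-order zero-phase
    Butterworth, 12 Hz) before detection.
    """
    spec = spec or FilterSpec()
    rate = markers.rate
    if mode == "walking":
        heel = lowpass_zero_phase(markers.positions["heel"][:, 2], rate, spec)
        toe = lowpass_zero_phase(markers.positions["toe"][:, 0], rate, spec)
        touchdowns = detect_touchdown_walking(heel, rate)
        footoffs = detect_footoff_walking(toe, rate)
        event_mode = "walking"
    else:
        hip = lowpass_zero_phase(markers.positions["gtroch"], rate, spec)
        knee = lowpass_zero_phase(
            0.5 * (markers.positions["med_epi"] + markers.positions["lat_epi"]), rate, spec
        )
        ankle = lowpass_zero_phase(
            0.5 * (markers.positions["med_mal"] + markers.positions["lat_mal"]), rate, spec
        )
        angle = knee_angle(hip, knee, ankle)
        touchdowns, footoffs = detect_events_running(angle, rate)
        event_mode = "running"
    if len(touchdowns) >= 2:
        footoffs = footoffs[(footoffs > touchdowns[0]) & (footoffs < touchdowns[-1])]
    return GaitEvents(
        touchdowns=touchdowns,
        footoffs=footoffs,
        mode=event_mode,
        n_frames=markers.n_frames,
    )


@dataclass
class TrialAnalysis:
    """Per-trial results: events, lengths, strain and the reduction table."""

    individual: object
    mode: str
    events: GaitEvents
    reference: np.ndarray
    straight: np.ndarray
    strain_reference: np.ndarray
    resting_length: float
    reduction: ReductionResult
    straight_stride_error: float
    standing_pcts: np.ndarray
    rate: float = 250.0

    @property
    def curved_minus_straight_max(self) -> float:
        frames = self.events.stride_frames
        return float(np.nanmax(self.reference[frames] - self.straight[frames]))

    @property
    def max_strain(self) -> float:
        frames = self.events.stride_frames
        return float(np.nanmax(self.strain_reference[frames]))

    def errors_by_pct_key(self) -> Dict[int, float]:
        """Stride-mean errors keyed by subset size (0 = straight) for saturation."""
        out = {0: self.straight_stride_error}
        for r, ev in self.reduction.by_r.items():
            out[r] = ev.stride_error
        return out


def analyze_trial(
    path: TendonPath,
    events: GaitEvents,
    resting_length: float,
    mode: str,
    individual: object = 0,
    r_values: Optional[Sequence[int]] = None,
    standing_pcts: Optional[np.ndarray] = None,
) -> TrialAnalysis:
    """Lengths, strain and the full marker-reduction table for one trial."""
    frames = events.stride_frames
    ref = length_series(path)
    straight = length_series(path, [])
    strain_ref = strain_series(ref, resting_length)
    config = ReductionConfig(n=path.n_foil, r_values=r_values)
    reduction = evaluate_reduction(path, events, resting_length, config)
    straight_err = float(np.nanmean(np.abs(straight.values[frames] - ref.values[frames])))
    if standing_pcts is None:
        standing_pcts = standing_marker_percentages(path, frame=int(frames[0]))
    return TrialAnalysis(
        individual=individual,
        mode=mode,
        events=events,
        reference=ref.values,
        straight=straight.values,
        strain_reference=strain_ref.values,
        resting_length=resting_length,
        reduction=reduction,
        straight_stride_error=straight_err,
        standing_pcts=np.asarray(standing_pcts, dtype=float),
        rate=path.rate,
    )


def export_trial(trial: SyntheticTrial, out_dir, n_png_frames: int = 0) -> Dict[str, Path]:
    """Write a synthetic trial to standard interchange files (TRC markers,
    MTJ pixel CSV, probe-calibration JSON, optionally the first
    ``n_png_frames`` rendered ultrasound frames as 8-bit PNGs) so the file
    readers can be exercised end to end on data with known ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trc": out / "markers.trc",
        "mtj": out / "mtj.csv",
        "calibration": out / "calibration.json",
    }
    write_trc(trial.markers, paths["trc"])
    us = trial.ultrasound
    if us is None:
        raise InvalidParameterError("trial has no ultrasound stream to export")
    write_mtj_csv(us.mtj_px, paths["mtj"], skin_row=us.skin_row)
    write_calibration_json(
        us.calibration,
        paths["calibration"],
        pixel_spacing=us.pixel_spacing,
        tripod_source=us.tripod_source,
        us_rate=us.rate,
    )
    if n_png_frames:
        import imageio.v3 as iio

        for i in range(min(n_png_frames, trial.path.n_frames)):
            img = us.frame(i).pixels
            png = out / f"us_{i:05d}.png"
            iio.imwrite(png, np.clip(img / img.max() * 255, 0, 255).astype(np.uint8))
            paths[f"us_{i:05d}"] = png
    return paths


def load_trial_from_files(
    trc_path,
    mtj_path,
    calibration_path,
    foil_prefix: str = "foil_",
    calcaneus_label: str = "calcaneus",
) -> tuple:
    """Rebuild (markers, TendonPath) from interchange files.

    The MTJ origin is recovered through the registration chain: per-frame
    probe pose from the tripod markers, MTJ pixel point projected to the
    skin line (constant-row skin from the CSV when present), then mapped to
    the global frame.  Ultrasound samples are synchronized to mocap frames
    by nearest neighbour, anchored at frame 0.
    """
    markers = read_trc(trc_path)
    calib, doc = read_calibration_json(calibration_path)
    mtj = read_mtj_csv(mtj_path)
    spacing = float(doc.get("pixel_spacing_mm", 0.1))
    tripod_src = np.asarray(doc["tripod_source_mm"], dtype=float)
    us_rate = float(doc.get("us_rate", markers.rate))
    n_frames = markers.n_frames
    mapping = synchronize_streams(
        us_rate, markers.rate, 0, 0, n_frames, n_us_frames=len(mtj), mode="nearest"
    )
    tripod_labels = sorted(
        (l for l in markers.labels if l.startswith("tripod_")),
        key=lambda l: int(l.split("_")[1]),
    )
    frame = UltrasoundFrame(np.zeros((4, 4)), spacing=(spacing, spacing))
    mtj_rows = mtj["row_px"].to_numpy()
    mtj_cols = mtj["col_px"].to_numpy()
    skin_rows = mtj["skin_row_px"].to_numpy() if "skin_row_px" in mtj else None
    origin = np.empty((n_frames, 3))
    for i in range(n_frames):
        target = np.stack([markers.positions[l][i] for l in tripod_labels])
        pose = fit_rigid_transform(tripod_src[: len(tripod_labels)], target)
        j = int(mapping[i])
        px = np.array([mtj_rows[j], mtj_cols[j]])
        if skin_rows is not None:
            cols = np.arange(max(0.0, px[1] - 100), px[1] + 101)
            skin = np.column_stack([np.full(cols.shape, skin_rows[j]), cols])
            px = project_mtj_to_skin(px, skin)
        origin[i] = image_to_global(px, frame, calib, pose)
    foil_labels = sorted(
        (l for l in markers.labels if l.startswith(foil_prefix)),
        key=lambda l: int(l[len(foil_prefix):]),
    )
    pts = np.stack(
        [markers.positions[calcaneus_label]]
        + [markers.positions[l] for l in foil_labels]
        + [origin],
        axis=1,
    )
    return markers, TendonPath(points=pts, rate=markers.rate)


@dataclass
class PipelineResult:
    """In-memory pipeline outputs plus the paths of the CSVs written."""

    config: PipelineConfig
    analyses: List[TrialAnalysis]
    saturation: SaturationCurve
    placement: object
    summary: Dict[str, float]
    files: Dict[str, Path]


def _closest_r(n: int, pct: float) -> int:
    return max(1, min(n, int(round(pct / 100.0 * n))))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config`` and write outputs.

    Stages: trial acquisition (simulate or load) -> event detection ->
    length/strain series -> marker reduction -> cohort saturation analysis ->
    placement table.  Any stage failure removes partial outputs and raises
    the original error prefixed with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    try:
        stage = "acquire"
        trials: List[SyntheticTrial] = []
        paths: List[TendonPath] = []
        if config.simulate:
            trials = make_cohort(
                n_individuals=config.n_individuals,
                foil_counts=config.foil_counts,
                mode=config.mode,
                seed=config.seed,
                n_strides=config.n_strides,
                **config.sim_overrides,
            )
            paths = [t.path for t in trials]
        else:
            markers, path = load_trial_from_files(
                config.trc_path,
                config.mtj_path,
                config.calibration_path,
                foil_prefix=config.foil_prefix,
                calcaneus_label=config.calcaneus_label,
            )
            paths = [path]

        stage = "events+reduction"
        analyses: List[TrialAnalysis] = []
        for i, path in enumerate(paths):
            if config.simulate:
                trial = trials[i]
                markers_i, resting = trial.markers, trial.resting_length
                standing = trial.standing_pcts
                ind = trial.individual
            else:
                markers_i, resting = markers, float(config.resting_length)
                standing, ind = None, 0
            events = detect_trial_events(markers_i, config.mode, config.filter_spec)
            r_values = config.r_values
            if r_values is not None:
                r_values = [r for r in r_values if r <= path.n_foil]
                if not r_values:
                    raise InvalidParameterError(
                        f"individual {ind}: no requested r value fits n={path.n_foil}"
                    )
            analyses.append(
                analyze_trial(
                    path,
                    events,
                    resting,
                    config.mode,
                    individual=ind,
                    r_values=r_values,
                    standing_pcts=standing,
                )
            )

        stage = "saturation"
        errors_by_r = {a.individual: a.errors_by_pct_key() for a in analyses}
        n_by_ind = {a.individual: a.reduction.n for a in analyses}
        saturation = saturation_analysis(
            errors_by_r,
            n_by_ind,
            threshold=config.plateau_threshold,
            plateau_window=config.plateau_window,
        )

        stage = "placement"
        records = []
        for a in analyses:
            for r in config.placement_sizes:
                if r in a.reduction.by_r:
                    records.append(
                        {
                            "individual": a.individual,
                            "r": r,
                            "subset": a.reduction.by_r[r].subset,
                        }
                    )
        standing_pcts = {a.individual: a.standing_pcts for a in analyses}
        placement = average_marker_positions(records, standing_pcts)
        for r, pos in placement.positions_pct.items():
            placement.application_error[r] = {}
            for a in analyses:
                if r in a.reduction.by_r:
                    placement.application_error[r][a.individual] = apply_marker_positions(
                        paths[[x.individual for x in analyses].index(a.individual)],
                        pos,
                        frames=a.events.stride_frames,
                    )

        stage = "summary"
        halfway = [a.reduction.by_r[_closest_r(a.reduction.n, 50.0)] for a in analyses]
        summary = {
            "mode": config.mode,
            "n_individuals": len(analyses),
            "n_strides": config.n_strides,
            "max_curved_minus_straight_mm": float(
                np.mean([a.curved_minus_straight_max for a in analyses])
            ),
            "max_strain_pct": float(np.mean([a.max_strain for a in analyses])),
            "mean_error_at_30pct_mm": saturation.mean_error_at(30.0),
            "mean_error_at_50pct_mm": saturation.mean_error_at(50.0),
            "max_strain_error_at_50pct": float(
                np.mean([ev.max_strain_error for ev in halfway])
            ),
            "plateau_pct": saturation.plateau_pct,
            "n_subsets_evaluated": int(
                sum(a.reduction.n_combinations_evaluated for a in analyses)
            ),
        }

        stage = "write"
        written.extend(_write_outputs(out_dir, config, analyses, saturation, placement))
    except ATCurveError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    if config.verbosity:
        n_strides_detected = sum(len(a.events.strides) for a in analyses)
        print(
            f"atcurve: {len(analyses)} trial(s), {n_strides_detected} strides, "
            f"{summary['n_subsets_evaluated']} subsets evaluated -> {out_dir}"
        )
    files = {p.stem: p for p in written}
    return PipelineResult(
        config=config,
        analyses=analyses,
        saturation=saturation,
        placement=placement,
        summary=summary,
        files=files,
    )


def _write_outputs(out_dir, config, analyses, saturation, placement) -> List[Path]:
    written = []

    rows = []
    for a in analyses:
        for td, fo, nxt in a.events.strides:
            rows.append(
                {
                    "individual": a.individual,
                    "mode": config.mode,
                    "touchdown_frame": td + 1,
                    "footoff_frame": fo + 1,
                    "next_touchdown_frame": nxt + 1,
                }
            )
    p = out_dir / "events.csv"
    write_output_csv(pd.DataFrame(rows), p, config, __version__)
    written.append(p)

    rows = []
    for a in analyses:
        frames = a.events.stride_frames
        for method, values in (("reference", a.reference), ("straight", a.straight)):
            strain = 100.0 * (values - a.resting_length) / a.resting_length
            rows.append(
                pd.DataFrame(
                    {
                        "individual": a.individual,
                        "frame": frames + 1,
                        "time_s": frames / a.rate,
                        "method": method,
                        "length_mm": values[frames],
                        "strain_pct": strain[frames],
                    }
                )
            )
    p = out_dir / "lengths.csv"
    write_output_csv(pd.concat(rows, ignore_index=True), p, config, __version__)
    written.append(p)

    rows = []
    for a in analyses:
        for r, ev in sorted(a.reduction.by_r.items()):
            rows.append(
                {
                    "individual": a.individual,
                    "mode": config.mode,
                    "n_foil": a.reduction.n,
                    "marker_set": r,
                    "subset": ";".join(str(s) for s in ev.subset),
                    "rmse_mm": ev.rmse,
                    "stance_error_mm": ev.stance_error,
                    "swing_error_mm": ev.swing_error,
                    "stride_error_mm": ev.stride_error,
                    "max_strain_error_pct": ev.max_strain_error,
                }
            )
    p = out_dir / "reduction_results.csv"
    write_output_csv(pd.DataFrame(rows), p, config, __version__)
    written.append(p)

    rows = []
    for a in analyses:
        for r, ev in sorted(a.reduction.by_r.items()):
            for phase, err in (("stance", ev.stance_error), ("swing", ev.swing_error)):
                rows.append(
                    {
                        "participant": a.individual,
                        "speed": config.mode,
                        "phase": phase,
                        "marker_set": r,
                        "error_mm": err,
                    }
                )
    p = out_dir / "errors_long.csv"
    write_output_csv(pd.DataFrame(rows), p, config, __version__)
    written.append(p)

    df = pd.DataFrame(
        {
            "pct": np.arange(1, 101),
            "r_squared_cumulative": saturation.r_squared,
            "r_squared_tail": saturation.r_squared_tail,
        }
    )
    df["plateau_pct"] = saturation.plateau_pct
    p = out_dir / "saturation.csv"
    write_output_csv(df, p, config, __version__)
    written.append(p)

    rows = []
    for r, pos in sorted(placement.positions_pct.items()):
        row = {"marker_set": r, "n_records": placement.n_records[r]}
        for k, v in enumerate(pos, start=1):
            row[f"marker_{k}_pct"] = v
        errs = placement.application_error.get(r, {})
        if errs:
            row["application_error_mm"] = float(np.mean(list(errs.values())))
        rows.append(row)
    p = out_dir / "placement_table.csv"
    write_output_csv(pd.DataFrame(rows), p, config, __version__)
    written.append(p)
    return written
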