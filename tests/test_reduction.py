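import itertools
import math

import numpy as np
import pytest

from atcurve.errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidSegmentationError,
)
from atcurve.gait import GaitEvents
from atcurve.geometry import TendonPath, length_series
from atcurve.pipeline import analyze_trial, detect_trial_events
from atcurve.reduction import (
    RECOMMENDED_PLACEMENTS_PCT,
    apply_marker_positions,
    average_marker_positions,
    count_combinations,
    enumerate_subsets,
    evaluate_reduction,
    max_strain_error,
    optimal_subset,
    phase_averaged_error,
    saturation_analysis,
    standing_marker_percentages,
    subset_rmse,
)


def _pascal(n, r, _cache={}):
    if r in (0, n):
        return 1
    if (n, r) not in _cache:
        _cache[(n, r)] = _pascal(n - 1, r - 1) + _pascal(n - 1, r)
    return _cache[(n, r)]


class TestCombinatorics:
    def test_known_counts(self):
        assert count_combinations(8, 4) == 70
        assert count_combinations(5, 5) == 1

    def test_r_exceeding_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            count_combinations(3, 4)

    def test_matches_pascal_triangle_for_all_small_n(self):
        for n in range(13):
            for r in range(n + 1):
                assert count_combinations(n, r) == _pascal(n, r)

    def test_enumeration_small_case(self):
        assert enumerate_subsets(3, 2) == [(0, 1), (0, 2), (1, 2)]

    def test_enumeration_matches_bitmask_brute_force(self):
        for n in range(1, 13):
            for r in {x for x in (1, 2, n // 2, n - 1, n) if 0 <= x <= n}:
                subs = enumerate_subsets(n, r)
                assert len(subs) == count_combinations(n, r)
                brute = {
                    tuple(i for i in range(n) if mask >> i & 1)
                    for mask in range(1 << n)
                    if bin(mask).count("1") == r
                }
                assert set(subs) == brute
                assert subs == sorted(subs)


class TestSubsetRmse:
    def test_full_subset_is_zero(self, walking_trial):
        path = walking_trial.path
        ref = length_series(path)
        assert subset_rmse(path, tuple(range(path.n_foil)), ref) == 0.0

    def test_constant_offset_gives_that_rmse(self):
        # two-point path shifted by a known amount in one "subset"
        pts = np.zeros((10, 4, 3))
        pts[:, :, 2] = np.array([0.0, 50.0, 100.0, 150.0])
        pts[:, 1, 0] = 30.0  # marker 0 off-axis: reference detours, subsets differ
        path = TendonPath(points=pts)
        ref = length_series(path)
        d = ref.values[0] - length_series(path, [1]).values[0]
        assert subset_rmse(path, (1,), ref) == pytest.approx(abs(d), rel=1e-12)

    def test_matches_two_pass_recomputation(self, walking_trial, rng):
        path = walking_trial.path
        ref = length_series(path)
        for _ in range(10):
            r = int(rng.integers(1, path.n_foil))
            sub = tuple(sorted(rng.choice(path.n_foil, r, replace=False).tolist()))
            vals = length_series(path, sub).values
            expected = math.sqrt(float(np.mean((vals - ref.values) ** 2)))
            assert subset_rmse(path, sub, ref) == pytest.approx(expected, rel=1e-12)


class TestOptimalSubset:
    def test_full_set_has_zero_rmse(self, walking_trial, walking_events):
        path = walking_trial.path
        sub, rmse, err = optimal_subset(path, path.n_foil, events=walking_events)
        assert sub == tuple(range(path.n_foil))
        assert rmse == 0.0
        assert np.nanmax(err) == 0.0

    def test_rmse_non_increasing_in_r(self, walking_trial, walking_events):
        path = walking_trial.path
        rmses = [
            optimal_subset(path, r, events=walking_events)[1]
            for r in range(1, path.n_foil + 1)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_single_informative_marker_is_selected(self):
        # straight path except marker 3 carries all the curvature
        n_frames, n_foil = 40, 6
        pts = np.zeros((n_frames, n_foil + 2, 3))
        pts[:, :, 2] = np.linspace(0, 200, n_foil + 2)
        pts[:, 4, 0] = 8.0 * np.sin(np.linspace(0, np.pi, n_frames)) + 2.0
        path = TendonPath(points=pts)
        sub, rmse, _ = optimal_subset(path, 1)
        assert sub == (3,)

    def test_matches_exhaustive_bitmask_argmin(self, walking_trial, walking_events):
        path = walking_trial.path
        frames = walking_events.stride_frames
        ref = length_series(path)
        r = 3
        best, best_rmse = None, np.inf
        for mask in range(1 << path.n_foil):
            if bin(mask).count("1") != r:
                continue
            sub = tuple(i for i in range(path.n_foil) if mask >> i & 1)
            e = subset_rmse(path, sub, ref, frames=frames)
            if e < best_rmse:
                best, best_rmse = sub, e
        got_sub, got_rmse, _ = optimal_subset(path, r, events=walking_events)
        assert got_sub == best and got_rmse == pytest.approx(best_rmse, rel=1e-12)


class TestPhaseAveragedError:
    def test_constant_error(self):
        ev = GaitEvents([0, 100], [60], mode="walking", n_frames=100)
        st, sw, stride = phase_averaged_error(np.full(100, 2.5), ev)
        assert st == sw == stride == 2.5

    def test_weighted_mean(self):
        ev = GaitEvents([0, 100], [60], mode="walking", n_frames=100)
        err = np.where(np.arange(100) < 60, 1.0, 2.0)
        st, sw, stride = phase_averaged_error(err, ev)
        assert (st, sw) == (1.0, 2.0)
        assert stride == pytest.approx(1.4)

    def test_empty_phase_rejected(self):
        ev = GaitEvents([0, 100], [60], mode="walking", n_frames=100)
        err = np.full(100, np.nan)
        err[:60] = 1.0  # swing all-NaN
        with pytest.raises(InvalidSegmentationError):
            phase_averaged_error(err, ev)

    def test_swing_error_exceeds_stance_at_small_r(self, walking_trial, walking_events):
        """Curvature peaks after foot-off (plantar flexion), so sparse
        marker-sets err more in swing than in stance."""
        res = evaluate_reduction(
            walking_trial.path, walking_events, walking_trial.resting_length
        )
        assert res.by_r[1].swing_error > res.by_r[1].stance_error


class TestMaxStrainError:
    def test_full_subset_zero(self, walking_trial, walking_events):
        path = walking_trial.path
        err = max_strain_error(
            path, tuple(range(path.n_foil)), 200.0, frames=walking_events.stride_frames
        )
        assert err == 0.0

    def test_scale_invariance(self, clean_walking_trial):
        t = clean_walking_trial
        scaled = TendonPath(points=t.path.points * 3.0, rate=t.path.rate)
        e1 = max_strain_error(t.path, (0, 2), t.resting_length)
        e2 = max_strain_error(scaled, (0, 2), 3.0 * t.resting_length)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_algebraic_identity_with_length_maxima(self, clean_walking_trial):
        t = clean_walking_trial
        sub = (0, 2)
        l_ref = length_series(t.path).values
        l_sub = length_series(t.path, sub).values
        expected = abs(l_sub.max() - l_ref.max()) / t.resting_length * 100.0
        assert max_strain_error(t.path, sub, t.resting_length) == pytest.approx(
            expected, abs=1e-12
        )


def _closed_form_r2(x, y):
    if np.ptp(y) == 0:
        return 1.0
    if len(x) < 3 or np.ptp(x) == 0:
        return float("nan")
    n = len(x)
    sxy = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    sxx = n * np.sum(x * x) - np.sum(x) ** 2
    syy = n * np.sum(y * y) - np.sum(y) ** 2
    return float(sxy**2 / (sxx * syy))


class TestSaturation:
    @staticmethod
    def _vanishing_cohort(p_star=50.0, slopes=(2, 3, 4, 5, 6)):
        errors, ns = {}, {}
        n = 10
        for i, a in enumerate(slopes):
            pts = {0: a}
            for r in range(1, n + 1):
                pct = 100.0 * r / n
                pts[r] = a * max(0.0, 1.0 - pct / p_star)
            errors[i] = pts
            ns[i] = n
        return errors, ns

    def test_identical_linear_decay_is_everywhere_linear(self):
        n = 10
        errors = {i: {r: 5.0 * (1 - r / n) for r in range(n + 1)} for i in range(4)}
        curve = saturation_analysis(errors, {i: n for i in range(4)})
        valid = np.isfinite(curve.r_squared)
        np.testing.assert_allclose(curve.r_squared[valid], 1.0, atol=1e-12)
        assert curve.plateau_pct == 1.0

    def test_plateau_localizes_planted_knee(self):
        errors, ns = self._vanishing_cohort(p_star=50.0)
        curve = saturation_analysis(errors, ns)
        assert abs(curve.plateau_pct - 50.0) <= 1.0

    def test_r2_sequences_match_closed_form_recomputation(self):
        errors, ns = self._vanishing_cohort()
        curve = saturation_analysis(errors, ns)
        grid = curve.percentages
        x = np.tile(grid, len(curve.errors_by_individual))
        y = np.concatenate(list(curve.errors_by_individual.values()))
        for j, p in enumerate(range(1, 101)):
            for seq, mask in (
                (curve.r_squared, x <= p),
                (curve.r_squared_tail, x >= p),
            ):
                expected = _closed_form_r2(x[mask], y[mask])
                if np.isnan(expected):
                    assert np.isnan(seq[j])
                else:
                    assert seq[j] == pytest.approx(expected, abs=1e-12)

    def test_zero_error_cohort_flagged_not_crashed(self):
        errors = {i: {r: 0.0 for r in range(6)} for i in range(3)}
        curve = saturation_analysis(errors, {i: 5 for i in range(3)})
        assert curve.degenerate
        assert np.isnan(curve.plateau_pct)
        assert np.isnan(curve.r_squared).all()

    def test_single_individual_single_size_rejected(self):
        with pytest.raises(InsufficientDataError):
            saturation_analysis({0: {0: 2.0, 3: 0.5}}, {0: 5})


class TestPlacement:
    def test_single_individual_table_equals_own_positions(self):
        standing = {0: np.array([15.0, 40.0, 70.0, 90.0])}
        records = [{"individual": 0, "r": 2, "subset": (1, 3)}]
        table = average_marker_positions(records, standing)
        np.testing.assert_allclose(table.positions_pct[2], [40.0, 90.0])

    def test_rank_matched_average(self):
        standing = {0: np.array([10.0, 50.0]), 1: np.array([30.0, 70.0])}
        records = [
            {"individual": 0, "r": 2, "subset": (0, 1)},
            {"individual": 1, "r": 2, "subset": (0, 1)},
        ]
        table = average_marker_positions(records, standing)
        np.testing.assert_allclose(table.positions_pct[2], [20.0, 60.0])

    def test_reference_placements_are_increasing(self):
        for r, pos in RECOMMENDED_PLACEMENTS_PCT.items():
            assert len(pos) == r
            assert all(a < b for a, b in zip(pos, pos[1:]))

    def test_identical_cohort_application_error_equals_optimal(
        self, clean_walking_trial, clean_walking_events
    ):
        """When the averaged positions are an individual's own optimum, the
        application error must equal that individual's optimal RMSE."""
        path = clean_walking_trial.path
        frames = clean_walking_events.stride_frames
        standing = standing_marker_percentages(path, frame=int(frames[0]))
        sub, rmse, _ = optimal_subset(path, 3, events=clean_walking_events)
        err = apply_marker_positions(path, standing[list(sub)], frames=frames)
        assert err == pytest.approx(rmse, rel=1e-6, abs=1e-9)


class TestAnalyzeTrial:
    def test_strain_error_consistent_with_reduction(self, walking_trial):
        events = detect_trial_events(walking_trial.markers, "walking")
        ana = analyze_trial(
            walking_trial.path, events, walking_trial.resting_length, "walking"
        )
        for r, ev in ana.reduction.by_r.items():
            assert ev.max_strain_error >= 0
            assert ev.rmse >= ev.stride_error - 1e-12 or r == ana.reduction.n
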