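"""Standing mixture, stay points, locomotion, entropy, aggregation."""

import math

import numpy as np
import pytest

from depthherd import (
    BehaviourParams,
    StandingModel,
    Track,
    aggregate_intervals,
    classify_standing,
    count_standing,
    detect_stay_points,
    fit_standing_model,
    measure_area_visits,
    measure_locomotion,
    spatial_entropy,
    validate_standing_model,
)
from depthherd.behaviour import _split_over_intervals


def _mk_track(xy, times=None, z=1.3, track_id=0):
    tr = Track(track_id=track_id)
    xy = np.asarray(xy, dtype=float)
    times = np.asarray(times if times is not None else np.arange(len(xy)) / 7.0)
    zs = np.full(len(xy), z) if np.isscalar(z) else np.asarray(z)
    for t, p, zz in zip(times, xy, zs):
        tr.append(float(t), np.array([p[0], p[1], zz]), "c")
    return tr


SMALL = BehaviourParams(train_sample=100)


class TestStandingModel:
    def test_two_delta_clusters_recovered(self, rng):
        z = np.concatenate(
            [rng.normal(1.30, 1e-4, 400), rng.normal(1.85, 1e-4, 600)]
        )
        m = fit_standing_model(z, SMALL, seed=0)
        assert m.mu_stand == pytest.approx(1.30, abs=1e-3)
        assert m.mu_other == pytest.approx(1.85, abs=1e-3)
        assert m.weights[0] == pytest.approx(0.4, abs=0.05)

    def test_parameter_recovery_within_standard_error(self, rng):
        n = 10_000
        w = 0.4
        lab = rng.random(n) < w
        z = np.where(
            lab, rng.normal(1.30, 0.05, n), rng.normal(1.85, 0.03, n)
        )
        params = BehaviourParams(train_sample=10_000)
        m = fit_standing_model(z, params, seed=1)
        assert abs(m.mu_stand - 1.30) < 3 * 0.05 / math.sqrt(w * n)
        assert abs(m.mu_other - 1.85) < 3 * 0.03 / math.sqrt((1 - w) * n)
        assert abs(m.weights[0] - w) < 3 * math.sqrt(w * (1 - w) / n)

    def test_low_activity_day_small_standing_weight(self, rng):
        z = np.concatenate(
            [rng.normal(1.30, 0.03, 300), rng.normal(1.85, 0.03, 2700)]
        )
        m = fit_standing_model(z, SMALL, seed=2)
        assert m.weights[0] < 0.2
        assert m.mu_other == pytest.approx(1.85, abs=0.01)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_standing_model(np.full(500, 1.5), SMALL, seed=0)

    def test_deterministic_given_seed(self, rng):
        z = np.concatenate([rng.normal(1.3, 0.05, 2000), rng.normal(1.85, 0.03, 2000)])
        m1 = fit_standing_model(z, SMALL, seed=9)
        m2 = fit_standing_model(z, SMALL, seed=9)
        assert m1.means == m2.means
        assert m1.weights == m2.weights


class TestValidation:
    def _model(self):
        return StandingModel(
            weights=(0.4, 0.6),
            means=(1.30, 1.85),
            variances=(0.05**2, 0.03**2),
            n_train=10_000,
            seed=0,
        )

    def test_holdout_from_model_passes_under_null(self):
        """A holdout actually drawn from the mixture passes the K-S check in
        at least 95% of seeded replicates at alpha = 0.01."""
        m = self._model()
        passes = 0
        n_rep = 40
        for rep in range(n_rep):
            holdout = m.sample(3000, seed=10_000 + rep)
            _, _, ok = validate_standing_model(m, holdout, alpha=0.01, seed=rep)
            passes += ok
        assert passes >= int(0.95 * n_rep)

    def test_shifted_holdout_fails(self, rng):
        m = self._model()
        holdout = m.sample(3000, seed=1) + 0.5
        stat, p, ok = validate_standing_model(m, holdout, alpha=0.01, seed=2)
        assert not ok
        assert stat > 0.3

    def test_statistic_equals_ecdf_max_gap(self):
        """The reported statistic equals a direct empirical-CDF max-gap
        computation between holdout and the seeded model sample."""
        m = self._model()
        holdout = m.sample(500, seed=3) + 0.02
        stat, _, _ = validate_standing_model(m, holdout, alpha=0.01, seed=4)
        synth = m.sample(500, seed=4)
        grid = np.sort(np.concatenate([holdout, synth]))
        ecdf_h = np.searchsorted(np.sort(holdout), grid, side="right") / 500
        ecdf_s = np.searchsorted(np.sort(synth), grid, side="right") / 500
        assert stat == pytest.approx(np.abs(ecdf_h - ecdf_s).max(), abs=1e-12)

    def test_empty_holdout_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            validate_standing_model(self._model(), np.empty(0))


class TestClassification:
    def _model(self):
        return StandingModel(
            weights=(0.45, 0.55),
            means=(1.32, 1.84),
            variances=(0.04**2, 0.05**2),
            n_train=1000,
            seed=0,
        )

    def test_component_means_classified_correctly(self):
        m = self._model()
        assert classify_standing(m, m.mu_stand)
        assert not classify_standing(m, m.mu_other)

    def test_boundary_matches_bisection(self):
        """The 0.5-posterior flip point located by bisection sits between
        the means and classification flips exactly there."""
        m = self._model()
        lo, hi = m.mu_stand, m.mu_other
        for _ in range(60):
            mid = (lo + hi) / 2
            if m.posterior_standing(mid) >= 0.5:
                lo = mid
            else:
                hi = mid
        zstar = (lo + hi) / 2
        assert m.mu_stand < zstar < m.mu_other
        assert classify_standing(m, zstar - 1e-6)
        assert not classify_standing(m, zstar + 1e-6)


class TestStayPoints:
    def test_stationary_track(self):
        tr = _mk_track([[1.0, 1.0]] * 15)  # 2 s at 7 fps
        sps = detect_stay_points(tr, radius=0.05, min_duration=1.0)
        assert len(sps) == 1
        assert sps[0].duration == pytest.approx(2.0)

    def test_straight_walk_has_none(self):
        xy = np.column_stack([np.arange(35) * 0.5 / 7.0, np.zeros(35)])
        tr = _mk_track(xy)
        assert detect_stay_points(tr, 0.05, 1.0) == []

    def test_matches_brute_force_scan(self):
        """Jitter-then-jump trajectories give the same stay points as an
        exhaustive O(n^2) anchor scan, over 100 seeded instances."""
        for trial in range(100):
            r = np.random.default_rng(trial)
            segs = []
            pos = np.zeros(2)
            for _ in range(r.integers(2, 5)):
                n = r.integers(4, 15)
                segs.append(pos + r.uniform(-0.028, 0.028, size=(n, 2)))
                pos = pos + r.uniform(0.2, 0.5, size=2)
            xy = np.vstack(segs)
            tr = _mk_track(xy)
            got = detect_stay_points(tr, 0.05, 1.0)
            # independent scan
            times = np.asarray(tr.times)
            expected = []
            i, n = 0, len(xy)
            while i < n:
                j = i + 1
                while j < n and np.hypot(*(xy[j] - xy[i])) <= 0.05:
                    j += 1
                if times[j - 1] - times[i] >= 1.0:
                    expected.append((times[i], times[j - 1]))
                    i = j
                else:
                    i += 1
            assert [(s.start, s.end) for s in got] == expected

    def test_stay_points_never_overlap(self, rng):
        xy = np.cumsum(rng.normal(0, 0.01, size=(200, 2)), axis=0)
        sps = detect_stay_points(_mk_track(xy), 0.05, 1.0)
        for a, b in zip(sps, sps[1:]):
            assert a.end < b.start


class TestAreaVisits:
    def test_feeder_stay_with_dropped_frame_measures_full_second(self, pen):
        """Five frames spanning one second with the middle frame dropped
        still register one second of feeding."""
        x, y = 0.5, 0.15  # inside the first feeder area
        times = [0.0, 0.25, 0.75, 1.0]  # middle (0.5) dropped
        tr = _mk_track([[x, y]] * 4, times=times)
        flags = {0: np.ones(4, dtype=bool)}
        totals = measure_area_visits([tr], flags, pen, BehaviourParams())
        assert sum(v["feeding"] for v in totals.values()) == pytest.approx(1.0)

    def test_lying_in_feeder_not_feeding(self, pen):
        tr = _mk_track([[0.5, 0.15]] * 70, z=1.87)  # 10 s lying at the trough
        flags = {0: np.zeros(70, dtype=bool)}
        totals = measure_area_visits([tr], flags, pen, BehaviourParams())
        assert sum(v["feeding"] for v in totals.values()) == 0.0

    def test_standing_outside_area_not_feeding(self, pen):
        tr = _mk_track([[2.0, 1.2]] * 70)
        flags = {0: np.ones(70, dtype=bool)}
        totals = measure_area_visits([tr], flags, pen, BehaviourParams())
        assert sum(v["feeding"] for v in totals.values()) == 0.0

    def test_scripted_bout_recovered_within_one_frame_period(self, pen):
        """A 10 s scripted feeder stay is measured within one frame period."""
        n = 70
        tr = _mk_track([[0.5, 0.15]] * n)
        flags = {0: np.ones(n, dtype=bool)}
        totals = measure_area_visits([tr], flags, pen, BehaviourParams())
        got = sum(v["feeding"] for v in totals.values())
        scripted = (n - 1) / 7.0
        assert abs(got - scripted) <= 1 / 7.0 + 1e-9


class TestLocomotion:
    def test_stationary_zero(self):
        tr = _mk_track([[1.0, 1.0]] * 20)
        out = measure_locomotion(tr)
        assert sum(d["distance"] for d in out.values()) == 0.0

    def test_collinear_walk_with_dropped_frame_keeps_distance(self):
        """A 1 m straight walk over 5 frames loses nothing when the middle
        frame is dropped."""
        xy = [[0.0, 0.0], [0.25, 0.0], [0.75, 0.0], [1.0, 0.0]]
        tr = _mk_track(xy, times=[0.0, 0.25, 0.75, 1.0])
        out = measure_locomotion(tr)
        assert sum(d["distance"] for d in out.values()) == pytest.approx(1.0)

    def test_vertical_movement_ignored(self):
        z = np.linspace(1.3, 1.9, 20)
        tr = _mk_track([[1.0, 1.0]] * 20, z=z)
        out = measure_locomotion(tr)
        assert sum(d["distance"] for d in out.values()) == 0.0

    def test_circle_distance_matches_chord_sum(self):
        """Distance along a sampled circle equals the closed-form chord sum
        2 n r sin(pi / n) per lap."""
        r_c, n = 0.8, 140
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        xy = np.column_stack([2 + r_c * np.cos(th), 1.2 + r_c * np.sin(th)])
        xy = np.vstack([xy, xy[0]])
        tr = _mk_track(xy)
        total = sum(d["distance"] for d in measure_locomotion(tr).values())
        chord = 2 * n * r_c * math.sin(math.pi / n)
        assert total == pytest.approx(chord, abs=1e-9)


class TestSpatialEntropy:
    def test_uniform_layout_zero(self, pen):
        xs, ys = np.meshgrid(
            (np.arange(6) + 0.5) * pen.length / 6,
            (np.arange(3) + 0.5) * pen.width / 3,
        )
        pos = np.column_stack([xs.ravel(), ys.ravel()])
        assert spatial_entropy(pos, pen) == pytest.approx(0.0, abs=1e-12)

    def test_full_concentration_minus_ln18(self, pen):
        pos = np.tile([[0.1, 0.1]], (50, 1))
        assert spatial_entropy(pos, pen) == pytest.approx(-math.log(18))

    def test_matches_direct_summation(self, pen, rng):
        pos = np.column_stack(
            [rng.uniform(0, pen.length, 500), rng.uniform(0, pen.width, 500)]
        )
        h = spatial_entropy(pos, pen)
        counts = np.zeros((3, 6))
        for x, y in pos:
            cx = min(int(x / pen.length * 6), 5)
            ry = min(int(y / pen.width * 3), 2)
            counts[ry, cx] += 1
        p = counts.ravel() / counts.sum()
        expected = -sum(pi * math.log(pi / (1 / 18)) for pi in p if pi > 0)
        assert h == pytest.approx(expected, abs=1e-12)

    def test_empty_positions_rejected(self, pen):
        with pytest.raises(ValueError, match="undefined"):
            spatial_entropy(np.empty((0, 2)), pen)


class TestCountStanding:
    def test_all_lying_zero(self):
        tr = _mk_track([[1.0, 1.0]] * 70, z=1.87)
        flags = {0: np.zeros(70, dtype=bool)}
        assert count_standing([tr], flags) == {}

    def test_total_time_convention_two_animals(self):
        """Two animals standing a whole 5-minute interval count 600 s."""
        n = 2100  # 300 s at 7 fps
        times = np.arange(n) / 7.0
        tracks = [
            _mk_track([[1.0, 1.0]] * n, times=times, track_id=0),
            _mk_track([[2.0, 1.5]] * n, times=times, track_id=1),
        ]
        flags = {0: np.ones(n, bool), 1: np.ones(n, bool)}
        totals = count_standing(tracks, flags, interval=300.0)
        assert totals == {0.0: pytest.approx(600.0)}

    def test_scripted_posture_schedule_recovered(self):
        """Standing 10 s then lying 10 s recovers the scripted total within
        two frame periods."""
        n = 140
        times = np.arange(n) / 7.0
        z = np.where(times < 10.0, 1.35, 1.87)
        tr = _mk_track([[1.0, 1.0]] * n, times=times, z=z)
        flags = {0: z < 1.5}
        totals = count_standing([tr], flags, interval=300.0)
        assert abs(totals[0.0] - 10.0) <= 2 / 7.0 + 1e-9


class TestAggregation:
    def _tracks(self, n=2100):
        times = np.arange(n) / 7.0
        return [_mk_track([[1.0, 1.0]] * n, times=times)], {
            0: np.ones(n, dtype=bool)
        }

    def test_qc_window_marks_interval_missing(self, pen):
        tracks, flags = self._tracks(4200)  # 600 s
        out = aggregate_intervals(
            tracks, flags, pen, qc_windows=[(300.0, 600.0)], t_origin=0.0
        )
        assert len(out) == 2
        assert not out[0].qc_excluded
        assert out[1].qc_excluded
        assert math.isnan(out[1].standing_s)

    def test_no_qc_keeps_totals(self, pen):
        tracks, flags = self._tracks()
        with_qc = aggregate_intervals(tracks, flags, pen, t_origin=0.0)
        assert with_qc[0].standing_s == pytest.approx(300.0)

    def test_retained_plus_excluded_conserves_time(self, pen, rng):
        """Randomised QC windows: retained + excluded standing time always
        equals the no-QC total."""
        tracks, flags = self._tracks(4200)
        total = sum(
            iv.standing_s
            for iv in aggregate_intervals(tracks, flags, pen, t_origin=0.0)
        )
        for trial in range(10):
            r = np.random.default_rng(trial)
            # window edges on the frame grid so no sample span straddles one
            a = round(r.uniform(0, 500) * 7) / 7
            qc = [(a, a + round(r.uniform(10, 80) * 7) / 7)]
            kept = sum(
                iv.standing_s
                for iv in aggregate_intervals(
                    tracks, flags, pen, qc_windows=qc, t_origin=0.0
                )
                if not iv.qc_excluded
            )
            # excluded samples are those whose timestamps fall in the window
            times = np.asarray(tracks[0].times)
            covers = np.empty(len(times))
            covers[:-1] = np.diff(times)
            covers[-1] = 1 / 7.0
            excluded = covers[(times >= qc[0][0]) & (times < qc[0][1])].sum()
            assert kept + excluded == pytest.approx(total, abs=1e-6)

    def test_overlapping_qc_windows_merge(self, pen):
        tracks, flags = self._tracks(4200)
        out = aggregate_intervals(
            tracks,
            flags,
            pen,
            qc_windows=[(300.0, 450.0), (400.0, 600.0)],
            t_origin=0.0,
        )
        assert out[1].qc_excluded


class TestIntervalSplitting:
    def test_span_splits_exactly(self):
        pieces = _split_over_intervals(250.0, 400.0, 300.0, 0.0)
        assert pieces == [(0.0, 50.0), (300.0, 100.0)]

    def test_zero_length_span(self):
        assert _split_over_intervals(10.0, 10.0, 300.0, 0.0) == [(0.0, 0.0)]
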