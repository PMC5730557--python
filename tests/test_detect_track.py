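"""Region-growing detection, Hungarian linking, merging, smoothing."""

import itertools

import numpy as np
import pytest

from depthherd import (
    AnimalState,
    BodyDims,
    PenGeometry,
    PointCloud,
    Track,
    TrackerParams,
    TrackManager,
    assign_detections,
    back_project,
    merge_cameras,
    minimum_area_box,
    render_depth_sequence,
    resample_to_fps,
    segment_regions,
    smooth_track,
)
from depthherd.cloud_pipeline import FilterParams, estimate_normals, preprocess
from depthherd.detect_track import Detection, camera_roi_bounds


def _detect_first_frame(pen, intr, states, camera="cam0", noise=0.005, seed=3):
    frames, gt = render_depth_sequence(states, pen, intr, noise_sd=noise, seed=seed)
    cloud = back_project(frames[camera][0], intr)
    params = FilterParams(pen_bounds=camera_roi_bounds(pen, camera))
    cloud, normals = preprocess(cloud, params)
    return segment_regions(cloud, normals, TrackerParams()), gt[0]


class TestSegmentation:
    def test_empty_cloud_no_detections(self):
        cloud = PointCloud(points=np.empty((0, 3)))
        normals = estimate_normals(cloud, 0.06)
        assert segment_regions(cloud, normals, TrackerParams()) == []

    def test_two_separated_animals(self, pen, intr):
        """Two bodies 0.5 m apart segment into two detections whose box
        centres match generator truth within 0.03 m."""
        ox, oy = pen.camera_offset("cam0")
        bd = BodyDims()
        states = [
            [AnimalState(0, 0.0, (ox - 0.3, oy - 0.38), 0.0, "standing", "none", bd)],
            [AnimalState(1, 0.0, (ox - 0.3, oy + 0.38), 0.0, "standing", "none", bd)],
        ]
        dets, gt0 = _detect_first_frame(pen, intr, states)
        assert len(dets) == 2
        truth = sorted([(b.cx - ox, b.cy - oy) for b in gt0.boxes], key=lambda p: p[1])
        got = sorted([d.box_center for d in dets], key=lambda p: p[1])
        for (tx, ty), (gx, gy) in zip(truth, got):
            assert np.hypot(tx - gx, ty - gy) < 0.03

    def test_touching_animals_split_at_normal_crease(self, pen, intr):
        """Side-by-side touching bodies stay two detections: the normal
        discontinuity in the crease blocks region growth."""
        ox, oy = pen.camera_offset("cam0")
        bd = BodyDims()
        states = [
            [AnimalState(0, 0.0, (ox, oy - 0.135), 0.0, "standing", "none", bd)],
            [AnimalState(1, 0.0, (ox, oy + 0.135), 0.0, "standing", "none", bd)],
        ]
        dets, _ = _detect_first_frame(pen, intr, states)
        assert len(dets) == 2

    def test_cluster_size_band_enforced(self, pen, intr):
        ox, oy = pen.camera_offset("cam0")
        bd = BodyDims()
        states = [
            [AnimalState(0, 0.0, (ox, oy), 0.0, "standing", "none", bd)]
        ]
        frames, _ = render_depth_sequence(states, pen, intr, noise_sd=0.0, seed=0)
        cloud = back_project(frames["cam0"][0], intr)
        params = FilterParams(pen_bounds=camera_roi_bounds(pen, "cam0"))
        cloud, normals = preprocess(cloud, params)
        dets = segment_regions(
            cloud, normals, TrackerParams(min_cluster_size=10_000)
        )
        assert dets == []

    def test_detection_centroid_is_member_mean(self, pen, intr):
        ox, oy = pen.camera_offset("cam0")
        states = [
            [AnimalState(0, 0.0, (ox, oy), 0.0, "standing", "none", BodyDims())]
        ]
        frames, _ = render_depth_sequence(states, pen, intr, noise_sd=0.0, seed=0)
        cloud = back_project(frames["cam0"][0], intr)
        params = FilterParams(pen_bounds=camera_roi_bounds(pen, "cam0"))
        cloud, normals = preprocess(cloud, params)
        dets = segment_regions(cloud, normals, TrackerParams())
        assert len(dets) == 1
        d = dets[0]
        np.testing.assert_allclose(
            d.centroid, cloud.points[d.member_indices].mean(axis=0)
        )
        assert d.point_count == len(d.member_indices)


class TestMinimumAreaBox:
    def test_axis_aligned_rectangle(self):
        pts = np.array([[0, 0], [2, 0], [2, 1], [0, 1], [1, 0.5]])
        center, (ln, wd), yaw = minimum_area_box(pts)
        assert center == pytest.approx((1.0, 0.5))
        assert (ln, wd) == pytest.approx((2.0, 1.0))
        assert yaw == pytest.approx(0.0, abs=1e-9)

    def test_rotated_rectangle_recovered(self, rng):
        for trial in range(20):
            r = np.random.default_rng(trial)
            ang = r.uniform(0, np.pi)
            c, s = np.cos(ang), np.sin(ang)
            base = np.column_stack(
                [r.uniform(-1, 1, 50) * 1.5, r.uniform(-1, 1, 50) * 0.4]
            )
            pts = base @ np.array([[c, s], [-s, c]])
            _, (ln, wd), yaw = minimum_area_box(pts)
            # derotating by -yaw aligns the long edge with +x
            cb, sb = np.cos(yaw), np.sin(yaw)
            rot = pts @ np.array([[cb, -sb], [sb, cb]])
            ext = rot.max(axis=0) - rot.min(axis=0)
            assert ext[0] == pytest.approx(ln, abs=1e-9)
            assert ext[1] == pytest.approx(wd, abs=1e-9)
            assert ln >= wd


class TestAssignment:
    def test_identity_pairing_zero_cost(self):
        a = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.5]])
        res = assign_detections(a, a.copy(), gate=0.5)
        assert sorted(res.pairs) == [(0, 0), (1, 1), (2, 2)]
        assert res.total_cost == pytest.approx(0.0)

    def test_matches_brute_force_on_random_instances(self):
        """Optimal gated matching equals exhaustive permutation search
        (4 x 4, all 24 permutations) on 100 seeded instances."""
        for trial in range(100):
            r = np.random.default_rng(trial)
            a = r.uniform(0, 1, size=(4, 2))
            b = r.uniform(0, 1, size=(4, 2))
            gate = 0.8
            cost = np.linalg.norm(a[:, None] - b[None, :], axis=2)
            best_cost, best_pairs = np.inf, None
            for perm in itertools.permutations(range(4)):
                pairs = [
                    (i, p) for i, p in enumerate(perm) if cost[i, p] <= gate
                ]
                # among matchings, maximise cardinality then minimise cost
                c = sum(cost[i, p] for i, p in pairs)
                key = (-len(pairs), c)
                if best_pairs is None or key < (-len(best_pairs), best_cost):
                    best_cost, best_pairs = c, pairs
            res = assign_detections(a, b, gate)
            assert len(res.pairs) == len(best_pairs)
            assert res.total_cost == pytest.approx(best_cost, abs=1e-9)

    def test_crossing_detections_take_cheaper_matching(self):
        prev = np.array([[0.0, 0.0], [0.3, 0.0]])
        curr = np.array([[0.28, 0.0], [0.02, 0.0]])  # swapped positions
        res = assign_detections(prev, curr, gate=0.5)
        # straight pairing costs 2*0.02, crossing costs 2*0.28
        assert sorted(res.pairs) == [(0, 1), (1, 0)]

    def test_gate_blocks_distant_pairs(self):
        prev = np.array([[0.0, 0.0]])
        curr = np.array([[2.0, 0.0]])
        res = assign_detections(prev, curr, gate=0.5)
        assert res.pairs == []
        assert res.unmatched_prev == [0]
        assert res.unmatched_curr == [0]


def _det(x, y, t=0.0, cam="c"):
    return Detection(
        t=t,
        camera_id=cam,
        centroid=np.array([x, y, 1.5]),
        box_center=(x, y),
        box_extents=(0.6, 0.25),
        box_yaw=0.0,
        point_count=100,
    )


class TestTrackLifecycle:
    def test_continuous_detection_single_track(self):
        mgr = TrackManager(TrackerParams())
        for k in range(10):
            mgr.step([_det(1.0, 1.0)], t=k / 7.0)
        tracks = mgr.finish()
        assert len(tracks) == 1
        assert len(tracks[0].times) == 10

    def test_single_missed_frame_resumes_same_track(self):
        mgr = TrackManager(TrackerParams(max_coast=2))
        times = [0, 1, 3, 4]  # frame 2 missing
        for k in times:
            mgr.step([_det(1.0, 1.0)], t=k / 7.0)
            if k == 1:
                mgr.step([], t=2 / 7.0)
        tracks = mgr.finish()
        assert len(tracks) == 1

    def test_track_dies_after_max_coast_and_ids_not_reused(self):
        mgr = TrackManager(TrackerParams(max_coast=1))
        mgr.step([_det(1.0, 1.0)], t=0.0)
        for k in range(1, 4):
            mgr.step([], t=k / 7.0)
        mgr.step([_det(1.0, 1.0)], t=4 / 7.0)
        tracks = mgr.finish()
        assert len(tracks) == 2
        assert tracks[0].track_id != tracks[1].track_id


class TestMergeCameras:
    def test_single_camera_zero_offset_identity(self):
        pen = PenGeometry(camera_offsets=[("c", (0.0, 0.0))])
        tr = Track(track_id=0)
        for k in range(5):
            tr.append(k / 7.0, np.array([1.0, 1.0, 1.5]), "c")
        merged = merge_cameras({"c": [tr]}, pen)
        assert len(merged) == 1
        np.testing.assert_allclose(merged[0].as_array(), tr.as_array())

    def test_unknown_camera_rejected(self, pen):
        tr = Track(track_id=0)
        tr.append(0.0, np.zeros(3), "ghost")
        with pytest.raises(KeyError, match="ghost"):
            merge_cameras({"ghost": [tr]}, pen)

    def test_overlapping_views_fuse_to_one_track(self, pen):
        """The same animal seen by both cameras becomes one pen-frame track
        within 0.02 m of truth."""
        truth = np.array([2.0, 1.2])  # in the overlap zone
        tr0, tr1 = Track(track_id=0), Track(track_id=0)
        o0, o1 = pen.camera_offset("cam0"), pen.camera_offset("cam1")
        r = np.random.default_rng(5)
        for k in range(10):
            n0, n1 = r.normal(0, 0.005, 2), r.normal(0, 0.005, 2)
            tr0.append(k / 7.0, np.array([*(truth - o0 + n0), 1.4]), "cam0")
            tr1.append(k / 7.0, np.array([*(truth - o1 + n1), 1.4]), "cam1")
        merged = merge_cameras({"cam0": [tr0], "cam1": [tr1]}, pen)
        assert len(merged) == 1
        xy = merged[0].as_array()[:, :2]
        assert np.linalg.norm(xy - truth, axis=1).max() < 0.02

    def test_non_overlapping_tracks_concatenate(self, pen):
        tr0, tr1 = Track(track_id=0), Track(track_id=0)
        o0, o1 = pen.camera_offset("cam0"), pen.camera_offset("cam1")
        tr0.append(0.0, np.array([0.5 - o0[0], 0.0, 1.4]), "cam0")
        tr1.append(0.0, np.array([3.5 - o1[0], 0.0, 1.4]), "cam1")
        merged = merge_cameras({"cam0": [tr0], "cam1": [tr1]}, pen)
        assert len(merged) == 2


class TestSmoothing:
    def _track(self, arr):
        tr = Track(track_id=0)
        for k, p in enumerate(arr):
            tr.append(k / 7.0, np.asarray(p, dtype=float), "c")
        return tr

    def test_constant_track_unchanged(self):
        tr = self._track([[1.0, 2.0, 1.5]] * 9)
        out = smooth_track(tr, 5)
        np.testing.assert_array_equal(out.as_array(), tr.as_array())
        assert out.times == tr.times

    def test_single_frame_spike_removed(self):
        pts = [[1.0, 1.0, 1.5]] * 9
        pts[4] = [2.0, 1.0, 1.5]
        out = smooth_track(self._track(pts), 5)
        np.testing.assert_allclose(out.as_array()[:, 0], 1.0)

    def test_matches_per_window_sort_oracle(self):
        """Running median equals a direct sorted-window computation on 100
        seeded random walks (with shrunk symmetric end windows)."""
        for trial in range(100):
            r = np.random.default_rng(trial)
            n = r.integers(5, 40)
            walk = np.cumsum(r.normal(0, 0.1, size=(n, 3)), axis=0)
            out = smooth_track(self._track(walk), 5).as_array()
            expected = np.empty_like(walk)
            for k in range(n):
                h = min(2, k, n - 1 - k)
                window = np.sort(walk[k - h : k + h + 1], axis=0)
                expected[k] = window[h]
            np.testing.assert_allclose(out, expected)

    def test_median_stays_within_window_range(self, rng):
        walk = np.cumsum(rng.normal(0, 0.2, size=(50, 3)), axis=0)
        out = smooth_track(self._track(walk), 5).as_array()
        for k in range(50):
            h = min(2, k, 49 - k)
            w = walk[k - h : k + h + 1]
            assert np.all(out[k] >= w.min(axis=0) - 1e-12)
            assert np.all(out[k] <= w.max(axis=0) + 1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_track(self._track(np.zeros((5, 3))), 4)


class _Stamp:
    def __init__(self, t):
        self.t = t


class TestResampling:
    def test_30fps_reduced_to_about_7(self):
        frames = [_Stamp(k / 30.0) for k in range(300)]  # 10 s at 30 fps
        out = resample_to_fps(frames, 7.0)
        assert 68 <= len(out) <= 72

    def test_already_at_target_identity(self):
        frames = [_Stamp(k / 7.0) for k in range(70)]
        out = resample_to_fps(frames, 7.0)
        assert [f.t for f in out] == [f.t for f in frames]

    def test_jittered_clock_gap_bounds(self, rng):
        times = np.cumsum(rng.uniform(0.8, 1.2, size=200) / 30.0)
        out = resample_to_fps([_Stamp(t) for t in times], 7.0)
        gaps = np.diff([f.t for f in out])
        assert gaps.min() >= 0.5 / 7.0
        assert gaps.max() <= 1.5 / 7.0
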