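import numpy as np
import pytest

import fruittrack as ft
from fruittrack.tracker import Tracker, TrackerConfig

from conftest import constant_velocity_stream


class TestSingleTargetLifecycle:
    def test_single_fruit_locks_once(self):
        frames = constant_velocity_stream(n_frames=5)
        report = ft.run(frames)
        assert report.total == 1
        assert all(s.detected == 1 for s in report.per_frame)
        assert {r.track_id for r in report.records} == {0}

    def test_absence_beyond_retention_double_counts(self):
        # detected 0-4, absent 5-20 (16 frames), reappears on-trajectory at 21
        frames = constant_velocity_stream(n_frames=30, absent=set(range(5, 21)))
        report = ft.run(frames)
        assert report.total == 2
        by_frame = {s.frame: s for s in report.per_frame}
        assert by_frame[20].live == 0  # pruned exactly when the window expires
        assert by_frame[21].created == 1

    def test_absence_within_retention_keeps_identity(self):
        frames = constant_velocity_stream(n_frames=30, absent=set(range(5, 15)))
        report = ft.run(frames)
        assert report.total == 1

    def test_absence_of_exactly_retention_window_still_matched(self):
        # unobserved for exactly max_unobserved frames, reappearing at +16
        frames = constant_velocity_stream(n_frames=30, absent=set(range(5, 20)))
        assert ft.run(frames).total == 1

    def test_empty_stream(self):
        assert ft.run({}).total == 0

    def test_frames_must_increase(self):
        t = Tracker(TrackerConfig())
        t.step(3, [])
        with pytest.raises(ValueError, match="increasing"):
            t.step(3, [])


class TestStepMechanics:
    def test_size_filter_applied_before_tracking(self):
        small = ft.Detection(0, 0, 0, 10, 10)  # below the 12/15 gate
        big = ft.Detection(0, 100, 100, 30, 30)
        report = ft.run({0: [small, big]})
        assert report.total == 1

    def test_new_track_ids_issued_in_detection_order(self):
        dets = [ft.Detection(0, 100 * i, 100, 30, 30) for i in range(3)]
        t = Tracker(TrackerConfig())
        records = t.step(0, dets)
        by_id = sorted(records, key=lambda r: r.track_id)
        assert [r.left for r in by_id] == [0, 100, 200]

    def test_new_track_borrows_stable_neighbour_velocity(self):
        # a stable track moving (10, 0); a new fruit appears nearby and must
        # inherit that velocity rather than the (20, 0) default
        frames = {
            k: [ft.Detection(k, 85 + 10 * k, 485, 30, 30)] for k in range(5)
        }
        frames[5] = [
            ft.Detection(5, 85 + 50, 485, 30, 30),
            ft.Detection(5, 85 + 50, 585, 30, 30),  # new fruit below
        ]
        t = Tracker(TrackerConfig())
        for k in range(6):
            t.step(k, frames[k])
        new = [tr for tr in t.state.live_tracks if tr.id == 1][0]
        donor = [tr for tr in t.state.live_tracks if tr.id == 0][0]
        assert np.allclose(new.velocity, donor.velocity)
        assert np.allclose(new.velocity, [10, 0], atol=0.5)  # not the (20, 0) default

    def test_unobserved_cap_invariant_and_monotone_count(self, field_scene):
        _, _, frames, _ = field_scene
        cfg = TrackerConfig()
        t = Tracker(cfg)
        prev_total = 0
        for k in sorted(frames)[:40]:
            t.step(k, frames[k])
            assert all(
                tr.unobserved_count <= cfg.max_unobserved for tr in t.state.live_tracks
            )
            assert t.state.total_created >= prev_total
            prev_total = t.state.total_created


class TestSimulatedCounting:
    def test_noiseless_scene_counts_exactly(self, noiseless_scene):
        _, _, frames, truth = noiseless_scene
        report = ft.run(frames)
        assert report.total == len(truth.fruit_seen()) == 50

    def test_detected_tracks_equal_visible_fruit(self, noiseless_scene):
        _, _, frames, truth = noiseless_scene
        report = ft.run(frames)
        visible = truth.visible_per_frame()
        for s in report.per_frame:
            assert s.detected == visible.get(s.frame, 0)

    def test_long_occlusion_forces_one_double_count(self, noiseless_scene):
        cfg, scene, _, _ = noiseless_scene
        scene = ft.generate_scene(cfg)
        _, truth0 = ft.render_detections(scene)
        spans = {
            f: (min(ks), max(ks))
            for f, h in truth0.fruit_frames.items()
            if (ks := [k for k, s in h.items() if s.visible])
        }
        fid, (a, b) = max(spans.items(), key=lambda kv: kv[1][1] - kv[1][0])
        mid = (a + b) // 2
        scene.occlusions[fid] = [(mid - 10, mid + 10)]  # 20-frame occlusion
        frames, _ = ft.render_detections(scene)
        assert ft.run(frames).total == 51

    def test_short_occlusion_bridged_by_prediction(self, noiseless_scene):
        cfg, _, _, _ = noiseless_scene
        scene = ft.generate_scene(cfg)
        _, truth0 = ft.render_detections(scene)
        spans = {
            f: (min(ks), max(ks))
            for f, h in truth0.fruit_frames.items()
            if (ks := [k for k, s in h.items() if s.visible])
        }
        fid, (a, b) = max(spans.items(), key=lambda kv: kv[1][1] - kv[1][0])
        mid = (a + b) // 2
        scene.occlusions[fid] = [(mid - 5, mid + 5)]  # 10 frames <= retention
        frames, _ = ft.render_detections(scene)
        assert ft.run(frames).total == 50


class TestParameterTrends:
    def test_retention_window_sweep(self, field_scene):
        # no carry-over (a=0) inflates the count; it falls to a plateau by 15
        _, _, frames, _ = field_scene
        counts = {
            a: ft.run(frames, TrackerConfig(max_unobserved=a)).total
            for a in (0, 15, 30)
        }
        assert counts[0] > counts[15] >= counts[30]
        assert counts[15] - counts[30] <= 0.05 * counts[15]

    def test_gate_threshold_sweep(self, field_scene):
        # a gate at the inter-frame shift breaks tracks (over-count); an
        # over-wide gate absorbs new fruit into old tracks (depressed count)
        _, _, frames, _ = field_scene
        counts = {
            thr: ft.run(frames, TrackerConfig(distance_threshold=thr)).total
            for thr in (20, 60, 100)
        }
        assert counts[20] > counts[60] > counts[100]
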