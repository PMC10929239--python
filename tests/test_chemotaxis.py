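import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliaquant.chemotaxis import (
    ProcessTrack,
    aggregate_cell,
    auto_track_tips,
    read_tracks_csv,
    track_velocity,
    write_tracks_csv,
)
from gliaquant.synthetic import simulate_chemotaxis


def straight_track(n=10, step=1.0, x0=0.0, y0=0.0, pipette=None):
    return ProcessTrack(
        points=tuple((i, x0 + i * step, y0) for i in range(n)), pipette_xy=pipette
    )


class TestTrackVelocity:
    def test_constructed_arithmetic(self):
        # 10 frames, 1 px/frame, 0.5 µm/px, 20 s: 9 steps * 0.5 µm over 3 min
        v, trunc = track_velocity(straight_track(10), pixel_size=0.5, frame_interval=20.0)
        assert v == pytest.approx(1.5)
        assert trunc is None

    def test_stationary_track(self):
        tr = ProcessTrack(points=tuple((i, 5.0, 5.0) for i in range(6)))
        v, _ = track_velocity(tr, 0.5, 20.0)
        assert v == 0.0

    def test_arrival_truncation_uses_pre_arrival_only(self):
        # track walks toward a pipette at x=30 and dawdles afterwards
        pts = [(i, float(i), 0.0) for i in range(31)]
        pts += [(31 + i, 30.0 + 5 * i, 0.0) for i in range(10)]  # absurd post-arrival speed
        tr = ProcessTrack(points=tuple(pts), pipette_xy=(30.0, 0.0))
        v, trunc = track_velocity(tr, pixel_size=1.0, frame_interval=60.0, capture_radius=2.0)
        # first point within 2 px of pipette is frame 28 → 28 px over 28 min
        assert trunc == 28
        assert v == pytest.approx(1.0)

    def test_too_short_after_truncation_is_undefined(self):
        tr = ProcessTrack(points=((0, 0.0, 0.0), (1, 1.0, 0.0)), pipette_xy=(0.0, 0.0))
        v, trunc = track_velocity(tr, 1.0, 60.0, capture_radius=2.0)
        assert math.isnan(v)
        assert trunc == 0

    def test_invalid_calibration(self):
        with pytest.raises(ValueError):
            track_velocity(straight_track(3), 0.0, 20.0)

    def test_translation_invariance(self):
        a, _ = track_velocity(straight_track(8, x0=0.0, y0=0.0), 0.3, 15.0)
        b, _ = track_velocity(straight_track(8, x0=100.0, y0=-40.0), 0.3, 15.0)
        assert a == pytest.approx(b)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=2, max_size=12
        )
    )
    def test_path_velocity_bounds_displacement_velocity(self, xy):
        tr = ProcessTrack(points=tuple((i, x, y) for i, (x, y) in enumerate(xy)))
        v, _ = track_velocity(tr, 0.5, 20.0)
        (f0, x0, y0), (f1, x1, y1) = tr.points[0], tr.points[-1]
        disp = math.hypot(x1 - x0, y1 - y0) * 0.5 / ((f1 - f0) * 20.0 / 60.0)
        assert v >= disp - 1e-9


class TestAggregateCell:
    def test_mean_of_processes(self):
        agg = aggregate_cell([1.0, 1.2, 1.4], cell_id="c1")
        assert agg.per_cell_velocity == pytest.approx(1.2)

    def test_single_process(self):
        assert aggregate_cell([0.8]).per_cell_velocity == pytest.approx(0.8)

    def test_undefined_excluded_from_mean(self):
        agg = aggregate_cell([1.0, math.nan, 1.4])
        assert agg.per_cell_velocity == pytest.approx(1.2)
        assert agg.n_defined == 2

    def test_all_undefined_excludes_cell(self):
        assert aggregate_cell([math.nan, math.nan]) is None


class TestSimulatorRecovery:
    def test_truth_track_step_matches_unit_conversion(self, small_cfg):
        cfg = small_cfg(seed=1, image_shape=(256, 256), n_frames=11, pixel_size=0.277)
        stack, truth = simulate_chemotaxis(cfg, 1.5, n_processes=1)
        pts = truth.tip_tracks[0].points
        steps = [math.hypot(x1 - x0, y1 - y0) for (_, x0, y0), (_, x1, y1) in zip(pts, pts[1:])]
        expected = 1.5 * (20.0 / 60.0) / 0.277  # ≈ 1.805 px/frame
        assert steps == pytest.approx([expected] * len(steps), rel=1e-9)

    def test_truth_velocity_exact(self, small_cfg):
        cfg = small_cfg(seed=2, image_shape=(256, 256), n_frames=16)
        _, truth = simulate_chemotaxis(cfg, 1.5, n_processes=3)
        for tr in truth.tip_tracks:
            v, _ = track_velocity(tr, cfg.pixel_size, cfg.frame_interval)
            assert v == pytest.approx(1.5, rel=1e-6)

    def test_auto_track_recovery_within_5_percent(self, small_cfg):
        cfg = small_cfg(seed=3, image_shape=(256, 256), n_frames=21)
        stack, truth = simulate_chemotaxis(cfg, 1.5, n_processes=3)
        tracks = auto_track_tips(stack, truth.tip_tracks[0].pipette_xy, 3)
        assert len(tracks) == 3
        for tr in tracks:
            v, _ = track_velocity(tr, cfg.pixel_size, cfg.frame_interval)
            assert v == pytest.approx(1.5, rel=0.05)

    def test_static_stack_zero_velocity(self, small_cfg):
        cfg = small_cfg(seed=4, image_shape=(128, 128), n_frames=6)
        stack, truth = simulate_chemotaxis(cfg, 0.0, n_processes=2)
        tracks = auto_track_tips(stack, truth.tip_tracks[0].pipette_xy, 2)
        for tr in tracks:
            v, _ = track_velocity(tr, cfg.pixel_size, cfg.frame_interval)
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_velocity_ratio_two_vs_one(self, small_cfg):
        recovered = []
        for v_prog in (0.8, 1.6):
            vals = []
            for seed in range(3):
                cfg = small_cfg(seed=seed, image_shape=(256, 256), n_frames=21)
                stack, truth = simulate_chemotaxis(cfg, v_prog, n_processes=3)
                for tr in auto_track_tips(stack, truth.tip_tracks[0].pipette_xy, 3):
                    vals.append(track_velocity(tr, cfg.pixel_size, cfg.frame_interval)[0])
            recovered.append(np.mean(vals))
        assert recovered[1] / recovered[0] == pytest.approx(2.0, abs=0.1)

    def test_programmed_arrival_frame(self, small_cfg):
        # 30 µm at 1.5 µm/min → arrival at 20 min = frame 60 at 20-s intervals
        cfg = small_cfg(seed=5, image_shape=(320, 320), n_frames=66, pixel_size=0.277)
        _, truth = simulate_chemotaxis(
            cfg, 1.5, n_processes=1, start_distance_um=30.0, capture_radius_um=0.25
        )
        assert truth.arrival_frames[0] == 60

    def test_parameter_validation(self, small_cfg):
        with pytest.raises(ValueError):
            simulate_chemotaxis(small_cfg(), 1.0, n_processes=0)
        with pytest.raises(ValueError):
            simulate_chemotaxis(small_cfg(), -1.0)


class TestTrackCsv:
    def test_round_trip(self, tmp_path):
        tracks = [
            straight_track(5, pipette=(9.0, 0.0)),
            ProcessTrack(points=((0, 1.0, 2.0), (2, 3.0, 4.0)), cell_id="c2", track_id="t2"),
        ]
        p = tmp_path / "tracks.csv"
        write_tracks_csv(tracks, p)
        back = read_tracks_csv(p, pipette_xy=(9.0, 0.0))
        assert len(back) == 2
        assert back[0].points == tracks[0].points
        assert back[1].cell_id == "c2"
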