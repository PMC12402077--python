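"""Kymographs, linking, axial projection, and motion classification."""

import numpy as np
import pandas as pd
import pytest

from stellatrack import simcilia as sc
from stellatrack.kymotrack import (
    AxialTrack,
    Track,
    classify_motion,
    event_frequency,
    extract_kymograph,
    link_tracks,
    project_onto_axis,
    run_metrics,
)


def axial(s_values, frames=None, mid=0):
    s = np.asarray(s_values, float)
    f = np.arange(len(s)) if frames is None else np.asarray(frames)
    return AxialTrack(molecule_id=mid, frames=f, s_um=s)


class TestExtractKymograph:
    def test_row_axis_width1_nearest_is_bit_exact(self):
        rng = np.random.default_rng(0)
        stack = rng.integers(0, 1000, (6, 32, 48)).astype(np.uint16)
        row = 17
        poly = np.array([[row, 2.0], [row, 45.0]])
        ky = extract_kymograph(stack, poly, width_px=1, sampling="nearest")
        for t in range(6):
            np.testing.assert_array_equal(ky.matrix[:, t], stack[t, row, 2:46])

    def test_stationary_emitter_horizontal_line(self, default_scene):
        photo = sc.Photophysics(photons_per_frame=1000.0, bleach_half_life=float("inf"))
        camera = sc.CameraModel(gain=1.0, offset=0.0, read_noise_sd=0.0)
        poly = default_scene.polyline_px(0)
        s_pos = 3.0  # um from base
        y, x = sc.point_at_arclength(poly, s_pos / default_scene.pixel_size)
        tr = sc.GroundTruthTrack(
            molecule_id=0, kind="stationary", n_fluorophores=1, stereocilium=0,
            frames=np.arange(8), x_px=np.full(8, x), y_px=np.full(8, y),
            s_um=np.full(8, s_pos), visible=np.ones(8, bool),
        )
        stack = sc.render_movie(default_scene, [tr], photo, camera, n_frames=8,
                                apply_shot_noise=False, quantize=False)
        ky = extract_kymograph(stack, poly, width_px=3)
        rows = ky.matrix.argmax(axis=0)
        assert np.ptp(rows) == 0  # parallel to the time axis
        assert rows[0] == pytest.approx(s_pos / default_scene.pixel_size, abs=1.0)

    def test_constant_speed_diagonal_slope(self, default_scene):
        photo = sc.Photophysics(photons_per_frame=1000.0, bleach_half_life=float("inf"))
        camera = sc.CameraModel(gain=1.0, offset=0.0, read_noise_sd=0.0)
        poly = default_scene.polyline_px(0)
        n = 20
        speed_um = 0.3  # per frame
        s = 1.0 + speed_um * np.arange(n)
        pts = sc.point_at_arclength(poly, s / default_scene.pixel_size)
        tr = sc.GroundTruthTrack(
            molecule_id=0, kind="processive", n_fluorophores=1, stereocilium=0,
            frames=np.arange(n), x_px=pts[:, 1], y_px=pts[:, 0],
            s_um=s, visible=np.ones(n, bool),
        )
        stack = sc.render_movie(default_scene, [tr], photo, camera, n_frames=n,
                                apply_shot_noise=False, quantize=False)
        ky = extract_kymograph(stack, poly, width_px=3)
        rows = ky.matrix.argmax(axis=0)
        slope_px = np.polyfit(np.arange(n), rows, 1)[0]
        assert slope_px * default_scene.pixel_size == pytest.approx(speed_um, abs=0.02)

    def test_polyline_outside_field_rejected(self):
        with pytest.raises(ValueError):
            extract_kymograph(np.zeros((2, 16, 16)), np.array([[4.0, -2.0], [4.0, 10.0]]))


class TestLinkTracks:
    def test_single_emitter_one_track(self):
        det = pd.DataFrame(
            {"frame": np.arange(10), "y_px": 20 + 0.3 * np.arange(10), "x_px": np.full(10, 8.0)}
        )
        tracks = link_tracks(det)
        assert len(tracks) == 1
        assert len(tracks[0].frames) == 10

    def test_two_distant_emitters_no_switches(self):
        f = np.arange(12)
        det = pd.DataFrame(
            {
                "frame": np.tile(f, 2),
                "y_px": np.concatenate([10 + 0.2 * f, 90 - 0.2 * f]),
                "x_px": np.concatenate([np.full(12, 10.0), np.full(12, 80.0)]),
            }
        )
        tracks = link_tracks(det, max_jump_px=5.0)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.x_px) < 1.0  # no identity switches

    def test_gap_bridging(self):
        frames = [0, 1, 2, 5, 6]
        det = pd.DataFrame({"frame": frames, "y_px": [10.0] * 5, "x_px": [10.0] * 5})
        tracks = link_tracks(det, max_gap_frames=3)
        assert len(tracks) == 1
        tracks = link_tracks(det, max_gap_frames=1)
        assert len(tracks) == 2

    def test_purity_on_simulated_field(self):
        # molecules spread over several stereocilia at high SNR: linked
        # tracks must be nearly pure
        scene = sc.make_scene(3, (6.0, 10.0), (256, 256), 0.1625, seed=21)
        photo = sc.Photophysics(photons_per_frame=2000.0, bleach_half_life=float("inf"))
        camera = sc.CameraModel()
        mm = sc.MotionModel(kind="stationary")
        truth = sc.simulate_tracks(scene, mm, photo, 12, 40, seed=3)
        stack = sc.render_movie(scene, truth, photo, camera, seed=4, n_frames=40,
                                background_photons=10.0, apical_brightness=1.0,
                                texture_sd=0.0)
        from stellatrack.puncta import detect_puncta

        rows = []
        for t in range(40):
            for d in detect_puncta(stack.data[t].astype(float), 1.3, 8.0, frame=t):
                rows.append({"frame": t, "y_px": d.y, "x_px": d.x})
        tracks = link_tracks(pd.DataFrame(rows))
        # molecules closer than the diffraction-scale merge radius are a
        # single unresolvable punctum; score purity on the resolvable ones
        pos = {m.molecule_id: (m.y_px[0], m.x_px[0]) for m in truth}
        resolvable = {
            i for i, (yi, xi) in pos.items()
            if all(i == j or np.hypot(yi - yj, xi - xj) > 6.0
                   for j, (yj, xj) in pos.items())
        }
        n_pure = 0
        n_scored = 0
        for tr in tracks:
            if len(tr.frames) < 3:
                continue
            ids = [
                min(pos, key=lambda m: np.hypot(pos[m][0] - tr.y_px[k],
                                                pos[m][1] - tr.x_px[k]))
                for k in range(len(tr.frames))
            ]
            majority = max(set(ids), key=ids.count)
            if majority not in resolvable:
                continue
            n_scored += 1
            n_pure += len(set(ids)) == 1
        assert n_scored >= 5
        assert n_pure / n_scored >= 0.95


class TestProjectOntoAxis:
    poly = np.array([[0.0, 0.0], [0.0, 30.0], [40.0, 30.0]])

    def test_start_maps_to_zero(self):
        tr = Track(0, np.array([0]), np.array([0.0]), np.array([0.0]))
        at = project_onto_axis(tr, self.poly, pixel_size_um=0.1)
        assert at.s_um[0] == pytest.approx(0.0)

    def test_tip_maps_to_full_length(self):
        tr = Track(0, np.array([0]), np.array([40.0]), np.array([30.0]))
        at = project_onto_axis(tr, self.poly, pixel_size_um=0.1)
        assert at.s_um[0] == pytest.approx(7.0)  # 70 px * 0.1 um

    def test_off_axis_flagged(self):
        tr = Track(0, np.array([0]), np.array([20.0]), np.array([5.0]))
        at = project_onto_axis(tr, self.poly, pixel_size_um=0.1, off_axis_px=3.0)
        assert at.off_axis[0]

    def test_constant_speed_track_linear_in_s(self, default_scene):
        poly = default_scene.polyline_px(0)
        s_true = (1.0 + 0.1 * np.arange(30)) / default_scene.pixel_size
        pts = sc.point_at_arclength(poly, s_true)
        tr = Track(0, np.arange(30), pts[:, 0], pts[:, 1])
        at = project_onto_axis(tr, poly, pixel_size_um=default_scene.pixel_size)
        slope = np.polyfit(np.arange(30), at.s_um, 1)[0]
        assert slope == pytest.approx(0.1, abs=0.005)


class TestClassifyMotion:
    def test_uniform_advance_is_processive(self):
        ms = classify_motion(axial([0, 0.1, 0.2, 0.3, 0.4, 0.5]))
        assert ms.track_class == "directional"
        assert len(ms.runs) == 1
        run = ms.runs[0]
        assert run.klass == "processive"
        v = run_metrics([run], frame_interval=1.0)["velocity_nm_s"].iloc[0]
        assert v == pytest.approx(100.0)

    def test_constant_position_is_stationary(self):
        ms = classify_motion(axial([1.0] * 6))
        assert ms.track_class == "stationary"

    def test_back_and_forth_excluded(self):
        ms = classify_motion(axial([0, 0.2, 0.0, 0.2, 0.0, 0.2, 0.0]))
        assert ms.track_class == "excluded-random"

    def test_more_than_three_frames_rule(self):
        # 4 frames (3 same-direction intervals) qualifies ...
        assert classify_motion(axial([0, 0.1, 0.2, 0.3])).track_class == "directional"
        # ... 3 frames does not
        assert classify_motion(axial([0, 0.1, 0.2])).track_class == "stationary"

    def test_staircase_is_stepwise(self):
        s = [0, 0, 0, 0.25, 0.25, 0.25, 0.25, 0.5, 0.5, 0.5, 0.75, 0.75]
        ms = classify_motion(axial(s))
        assert ms.track_class == "directional"
        assert ms.runs[0].klass == "stepwise"

    def test_baseward_direction_sign(self):
        ms = classify_motion(axial([2.0, 1.9, 1.8, 1.7, 1.6]))
        assert ms.track_class == "directional"
        assert ms.runs[0].direction == -1
        assert ms.runs[0].displacement_um < 0

    def test_time_reversal_with_direction_flip_invariance(self):
        rng = np.random.default_rng(12)
        classes = []
        for rep in range(60):
            kind = rep % 3
            n = int(rng.integers(5, 25))
            if kind == 0:
                s = np.cumsum(rng.uniform(0.0, 0.2, n))
            elif kind == 1:
                s = 1.0 + rng.normal(0, 0.01, n)
            else:
                s = 1.0 + np.cumsum(rng.choice([-0.2, 0.2], n))
            fwd = classify_motion(axial(s))
            smax = s.max() + s.min()
            rev = classify_motion(axial((smax - s)[::-1]))
            classes.append((fwd.track_class, rev.track_class))
            assert fwd.track_class == rev.track_class
            assert len(fwd.runs) == len(rev.runs)

    def test_subpixel_reversal_absorbed(self):
        # a 0.05-um dip inside a steady run is localization noise, not a
        # direction change
        s = np.array([0, 0.1, 0.2, 0.15, 0.3, 0.4, 0.5])
        ms = classify_motion(axial(s))
        assert ms.track_class == "directional"
        assert len(ms.runs) == 1


class TestRunMetrics:
    def test_velocity_units_and_interval_scaling(self):
        ms = classify_motion(axial([0, 0.1, 0.2, 0.3, 0.4]))
        m1 = run_metrics(ms.runs, frame_interval=1.0)
        m01 = run_metrics(ms.runs, frame_interval=0.1)
        assert m1["velocity_nm_s"].iloc[0] == pytest.approx(100.0)
        assert m01["velocity_nm_s"].iloc[0] == pytest.approx(1000.0)

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            run_metrics([], 1.0)

    def test_cohort_recovery_within_2se(self):
        # truth-level cohort: noisy constant-speed tracks at the measured
        # walker distribution
        rng = np.random.default_rng(13)
        vels = []
        for _ in range(60):
            v = -1
            while v <= 0:
                v = rng.normal(101, 53)
            n = max(5, int(2300 / v))
            s = 0.5 + v / 1000.0 * np.arange(n) + rng.normal(0, 0.008, n)
            ms = classify_motion(axial(s), min_step_um=0.03)
            if ms.track_class != "directional":
                continue
            vels.append(run_metrics(ms.runs, 1.0)["velocity_nm_s"].max())
        vels = np.array(vels)
        se = vels.std(ddof=1) / np.sqrt(len(vels))
        assert abs(vels.mean() - 101) < 2 * se + 5

    def test_stepwise_vs_processive_accuracy_on_clean_input(self):
        rng = np.random.default_rng(14)
        correct = 0
        total = 0
        for rep in range(40):
            if rep % 2 == 0:
                s = 0.1 * np.arange(20)  # smooth walker
                want = "processive"
            else:
                jumps = rng.random(20) < 0.2
                s = 0.4 * np.cumsum(jumps)  # staircase
                want = "stepwise"
            ms = classify_motion(axial(s))
            if ms.track_class != "directional" or not ms.runs:
                continue
            total += 1
            correct += ms.runs[0].klass == want
        assert total >= 30
        assert correct / total >= 0.9


class TestEventFrequency:
    def test_basic_rates_and_exclusion(self):
        tbl = event_frequency(
            {"a": 2, "b": 0, "c": 3},
            {"a": 500, "b": 600, "c": 400},
        )
        a = tbl.set_index("cell")
        assert a.loc["a", "frequency_per_frame"] == pytest.approx(0.004)
        assert a.loc["b", "frequency_per_frame"] == 0.0
        assert bool(a.loc["a", "included"]) and bool(a.loc["b", "included"])
        assert not a.loc["c", "included"]  # fewer than 500 frames
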