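"""Synthetic side-view trap video: rendering, determinism, recovery."""

import math

import numpy as np
import pytest

from trapcolor import (
    RampSchedule,
    SyntheticScene,
    TrapSpec,
    delta_e_series,
    generate_sequence,
    render_frame,
    rgb_to_lab,
    simulate_trap,
)
from trapcolor.compare import align, pearson, rms_difference


class TestRenderFrame:
    def test_empty_trap_is_uniform_fluid(self, small_scene):
        scene = SyntheticScene(**{**small_scene.__dict__, "noise_sd": 0.0})
        frame = render_frame(scene, 0.0)
        trap = frame[scene.trap_y : scene.trap_y + scene.trap_h,
                     scene.trap_x : scene.trap_x + scene.trap_w]
        assert np.all(trap == np.array(scene.fluid_rgb, dtype=np.uint8))

    def test_full_trap_is_uniform_air(self, small_scene):
        scene = SyntheticScene(**{**small_scene.__dict__, "noise_sd": 0.0})
        trap = render_frame(scene, 1.0)[scene.trap_y : scene.trap_y + scene.trap_h,
                                        scene.trap_x : scene.trap_x + scene.trap_w]
        assert np.all(trap == np.array(scene.air_rgb, dtype=np.uint8))

    @pytest.mark.parametrize("fraction", [0.25, 0.5, 0.8])
    def test_air_row_count_pixel_oracle(self, small_scene, fraction):
        scene = SyntheticScene(**{**small_scene.__dict__, "noise_sd": 0.0})
        frame = render_frame(scene, fraction)
        trap = frame[scene.trap_y : scene.trap_y + scene.trap_h,
                     scene.trap_x : scene.trap_x + scene.trap_w]
        air_rows = int(np.sum(np.all(trap == np.array(scene.air_rgb), axis=(1, 2))))
        assert air_rows == math.ceil(fraction * scene.trap_h)

    def test_out_of_range_fraction_rejected(self, small_scene):
        with pytest.raises(ValueError):
            render_frame(small_scene, 1.01)

    def test_deterministic_for_seed_and_index(self, small_scene):
        a = render_frame(small_scene, 0.3, frame_index=5)
        b = render_frame(small_scene, 0.3, frame_index=5)
        c = render_frame(small_scene, 0.3, frame_index=6)
        assert a.tobytes() == b.tobytes()
        assert a.tobytes() != c.tobytes()  # fresh noise per frame

    def test_trap_must_fit_in_frame(self):
        with pytest.raises(ValueError):
            SyntheticScene(width=30, height=30, trap_x=20, trap_y=0, trap_w=20, trap_h=10)

    def test_lightness_increases_with_air_fraction(self, small_scene, white):
        scene = SyntheticScene(**{**small_scene.__dict__, "noise_sd": 0.0})
        roi = scene.trap_roi
        # row-center fractions: each step adds exactly one air row, so the
        # strict monotonicity is not broken by ceil ties at row boundaries
        fractions = np.concatenate(
            [[0.0], (np.arange(1, scene.trap_h + 1) - 0.5) / scene.trap_h]
        )
        L = []
        for f in fractions:
            frame = render_frame(scene, f)
            from trapcolor import roi_mean_lab
            L.append(roi_mean_lab(frame, roi, white)[0])
        assert np.all(np.diff(L) > 0)


class TestGenerateSequence:
    def _trace(self, phi=0.2, t_end=6.0):
        return simulate_trap(
            50.0, RampSchedule(phi_final=phi), TrapSpec(capacity_ul=0.5), t_end=t_end
        )

    def test_frame_count(self, small_scene):
        stack, truth = generate_sequence(small_scene, self._trace(), fps=10)
        assert len(stack) == int(6.0 * 10)
        assert len(truth) == len(stack)
        assert list(truth.columns) == ["frame", "time_s", "air_fraction", "v_air_ul"]

    def test_same_seed_byte_identical(self, small_scene):
        a, _ = generate_sequence(small_scene, self._trace(), fps=10)
        b, _ = generate_sequence(small_scene, self._trace(), fps=10)
        assert a.frames.tobytes() == b.frames.tobytes()

    def test_constant_scene_has_near_zero_delta_e(self, small_scene, white):
        stack, _ = generate_sequence(small_scene, self._trace(phi=0.0), fps=10)
        series = delta_e_series(stack, small_scene.trap_roi, white)
        assert abs(series.deltaE.mean()) < 3 * small_scene.noise_sd

    def test_ground_truth_tracks_trace(self, small_scene):
        trace = self._trace()
        _, truth = generate_sequence(small_scene, trace, fps=10)
        expected = np.interp(truth["time_s"], trace.time_s, trace.v_air_ul)
        np.testing.assert_allclose(truth["v_air_ul"], expected, atol=1e-12)

    def test_empty_fps_rejected(self, small_scene):
        with pytest.raises(ValueError):
            generate_sequence(small_scene, self._trace(), fps=0)


class TestEndToEndRecovery:
    def test_delta_e_tracks_volume_with_noise(self, small_scene, white):
        trace = simulate_trap(
            50.0, RampSchedule(phi_final=0.2), TrapSpec(capacity_ul=2.0), t_end=12.0
        )
        stack, _ = generate_sequence(small_scene, trace, fps=10)
        series = delta_e_series(stack, small_scene.trap_roi, white)
        pair = align(series, trace)
        assert pearson(pair) >= 0.95

    def test_noiseless_recovery_is_nearly_exact(self, small_scene, white):
        scene = SyntheticScene(**{**small_scene.__dict__, "noise_sd": 0.0})
        trace = simulate_trap(
            50.0, RampSchedule(phi_final=0.2), TrapSpec(capacity_ul=2.0), t_end=12.0
        )
        stack, _ = generate_sequence(scene, trace, fps=10)
        series = delta_e_series(stack, scene.trap_roi, white)
        pair = align(series, trace)
        assert pearson(pair) >= 0.99
        assert rms_difference(pair) < 0.1
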