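"""Cardiac motion pipeline and worm activity metric."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from rapmicro.activity import (
    activation_map,
    compare_groups,
    conduction_velocity,
    motion_signal,
    roi_trace,
    worm_activity,
)
from rapmicro.stacks import FrameStack
from rapmicro.synth import MonolayerParams, simulate_monolayer


def _stack(frames, fps=40.0, **kw):
    return FrameStack(np.asarray(frames, dtype=float), fps=fps, **kw)


class TestMotionSignal:
    def test_constant_stack_gives_zero(self):
        out = motion_signal(_stack(np.full((10, 4, 4), 100.0)), n=6)
        assert out.n_frames == 4
        assert np.all(out.frames == 0.0)

    def test_step_pixel_reads_for_n_frames(self):
        frames = np.zeros((20, 3, 3))
        frames[8:, 1, 1] = 10.0  # step of +10 at frame 8
        out = motion_signal(_stack(frames), n=6)
        vals = out.frames[:, 1, 1]
        assert np.count_nonzero(vals == 10.0) == 6
        assert np.all(vals[(vals != 10.0)] == 0.0)

    def test_sinusoid_peak_amplitude(self):
        # |a sin(wt) - a sin(w(t - n/fps))| peaks at 2a |sin(pi f n / fps)|
        a, f, fps, n = 40.0, 3.0, 100.0, 6
        t = np.arange(400) / fps
        frames = (a * np.sin(2 * np.pi * f * t))[:, None, None] * np.ones((1, 2, 2))
        out = motion_signal(_stack(frames, fps=fps), n=n)
        expected = 2 * a * abs(np.sin(np.pi * f * n / fps))
        assert out.frames.max() == pytest.approx(expected, rel=0.02)

    def test_no_uint8_wraparound(self):
        frames = np.zeros((8, 2, 2), dtype=np.uint8)
        frames[4:] = 200
        out = motion_signal(FrameStack(frames, fps=10.0), n=2)
        assert out.frames.max() == 200.0

    def test_nonnegative_and_zero_iff_static(self, rng):
        frames = rng.uniform(0, 255, (12, 5, 5))
        out = motion_signal(_stack(frames), n=3)
        assert np.all(out.frames >= 0.0)

    def test_too_short_stack_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            motion_signal(_stack(np.zeros((5, 2, 2))), n=6)

    def test_timestamps_shift_by_lag(self):
        out = motion_signal(_stack(np.zeros((10, 2, 2)), fps=40.0), n=6)
        assert out.timestamps[0] == pytest.approx(6 / 40.0)


class TestRoiTrace:
    def test_zero_motion_gives_zero_trace(self):
        out = roi_trace(_stack(np.zeros((5, 30, 30))), center=(15, 15))
        assert np.all(out.values == 0.0)

    def test_single_bright_pixel_mean(self):
        frames = np.zeros((2, 30, 30))
        frames[:, 15, 15] = 400.0
        out = roi_trace(_stack(frames), center=(15, 15), size=(20, 20))
        assert np.all(out.values == pytest.approx(1.0))  # 400 / 400 px

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            roi_trace(_stack(np.zeros((2, 30, 30))), center=(5, 5), size=(20, 20))

    def test_two_peaks_per_beat_on_simulated_monolayer(self):
        stack, _ = simulate_monolayer(MonolayerParams(seed=3))
        motion = motion_signal(stack, n=6)
        trace = roi_trace(motion, center=(40, 40))
        peaks, _ = find_peaks(trace.values, prominence=0.25 * trace.values.max())
        n_cycles = MonolayerParams.duration_s // MonolayerParams.period_s
        assert len(peaks) == 2 * int(n_cycles)  # contraction + relaxation per beat


class TestActivationMap:
    def test_hand_computed_crossings(self):
        # two active pixels whose smoothed-free signals reach half-max at
        # frames 3 and 7 exactly
        frames = np.zeros((10, 1, 2))
        frames[3, 0, 0] = 0.5
        frames[4:, 0, 0] = 1.0
        frames[7, 0, 1] = 0.5
        frames[8:, 0, 1] = 1.0
        m = _stack(frames, fps=40.0)
        amap = activation_map(m, smooth_px=0.0, smooth_frames=1)
        assert amap.times_s[0, 0] == pytest.approx(3 / 40.0)
        assert amap.times_s[0, 1] == pytest.approx(7 / 40.0)

    def test_uniform_flash_activates_simultaneously(self):
        frames = np.zeros((10, 6, 6))
        frames[5:] = 1.0
        amap = activation_map(_stack(frames, fps=40.0), smooth_px=0.0, smooth_frames=1)
        t = amap.times_s
        assert np.all(np.isfinite(t))
        assert t.max() - t.min() < 1.0 / 40.0

    def test_quiet_prefix_shifts_times(self):
        stack, _ = simulate_monolayer(MonolayerParams(seed=5, noise_std=0.0))
        m = motion_signal(stack, n=6)
        a1 = activation_map(m)
        pad = 8
        padded = np.concatenate([np.repeat(stack.frames[:1], pad, axis=0), stack.frames])
        m2 = motion_signal(_stack(padded, fps=stack.fps), n=6)
        a2 = activation_map(m2)
        mask = a1.activated & a2.activated
        shift = a2.times_s[mask] - a1.times_s[mask]
        assert np.nanmedian(shift) == pytest.approx(pad / stack.fps, abs=0.5 / stack.fps)

    def test_all_quiet_warns_and_marks_unactivated(self):
        with pytest.warns(UserWarning, match="all-quiet"):
            amap = activation_map(_stack(np.zeros((6, 4, 4))))
        assert not amap.activated.any()

    def test_times_within_stack_range(self):
        stack, _ = simulate_monolayer(MonolayerParams(seed=2))
        m = motion_signal(stack, n=6)
        amap = activation_map(m)
        finite = amap.times_s[amap.activated]
        assert finite.min() >= m.timestamps[0]
        assert finite.max() <= m.timestamps[-1]


class TestConductionVelocity:
    def test_recovers_simulated_planar_wave(self):
        """20 mm/s ground-truth wave recovered within 5% / 5 deg, 10 seeds."""
        for seed in range(10):
            stack, truth = simulate_monolayer(MonolayerParams(seed=seed))
            amap = activation_map(motion_signal(stack, n=6))
            cv = conduction_velocity(amap)
            assert cv.speed_mm_s == pytest.approx(truth["speed_mm_s"], rel=0.05)
            delta = (cv.direction_deg - truth["direction_deg"] + 180.0) % 360.0 - 180.0
            assert abs(delta) < 5.0

    def test_rotating_map_rotates_direction(self):
        stack, _ = simulate_monolayer(MonolayerParams(seed=0, noise_std=0.0))
        amap = activation_map(motion_signal(stack, n=6))
        cv0 = conduction_velocity(amap)
        amap.times_s = np.rot90(amap.times_s)
        cv90 = conduction_velocity(amap)
        assert cv90.speed_mm_s == pytest.approx(cv0.speed_mm_s, rel=0.01)
        delta = (cv90.direction_deg - cv0.direction_deg) % 360.0
        assert delta == pytest.approx(270.0, abs=1.0)  # rot90 maps +x onto -y

    def test_uniform_map_is_quasi_simultaneous(self):
        from rapmicro.activity import ActivationMap

        amap = ActivationMap(np.full((10, 10), 0.5), fps=40.0, pixel_pitch_um=25.0)
        cv = conduction_velocity(amap)
        assert cv.quasi_simultaneous
        assert cv.speed_mm_s is None

    def test_too_few_pixels_rejected(self):
        from rapmicro.activity import ActivationMap

        t = np.full((3, 3), np.nan)
        t[0, :3] = [0.0, 0.1, 0.2]
        amap = ActivationMap(t, fps=40.0, pixel_pitch_um=25.0)
        with pytest.raises(ValueError, match="at least 10"):
            conduction_velocity(amap)


class TestWormActivity:
    def test_static_stack_is_zero(self):
        wa = worm_activity(_stack(np.full((5, 10, 10), 128.0)))
        assert wa.pixels_per_frame == 0.0
        assert wa.fraction == 0.0

    def test_direct_count(self):
        frames = np.zeros((2, 100, 100))
        frames[1].flat[:500] = 100.0  # exactly 500 pixels change by 100
        wa = worm_activity(_stack(frames), threshold=65.0)
        assert wa.pixels_per_frame == 500.0
        assert wa.fraction == pytest.approx(0.05)

    def test_threshold_is_strict(self):
        frames = np.zeros((2, 4, 4))
        frames[1] = 65.0  # change of exactly 65 does not count
        assert worm_activity(_stack(frames)).pixels_per_frame == 0.0
        frames[1] = 65.5
        assert worm_activity(_stack(frames)).pixels_per_frame == 16.0

    def test_invariant_to_constant_offset(self, rng):
        frames = rng.uniform(0, 200, (10, 8, 8))
        a = worm_activity(_stack(frames))
        b = worm_activity(_stack(frames + 30.0))
        assert a.pixels_per_frame == b.pixels_per_frame

    def test_equivariant_under_time_reversal(self, rng):
        frames = rng.uniform(0, 255, (10, 8, 8))
        a = worm_activity(_stack(frames))
        b = worm_activity(_stack(frames[::-1].copy()))
        assert a.pixels_per_frame == b.pixels_per_frame

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="two frames"):
            worm_activity(_stack(np.zeros((1, 4, 4))))


class TestCompareGroups:
    def _wells(self, values):
        return [
            worm_activity(
                _stack(self._frames_with_count(v)), threshold=65.0
            )
            for v in values
        ]

    @staticmethod
    def _frames_with_count(k):
        frames = np.zeros((2, 10, 10))
        frames[1].flat[: int(k)] = 100.0
        return frames

    def test_identical_groups_p_one(self):
        a = self._wells([10, 20, 30])
        res = compare_groups(a, list(a))
        assert res.p_value == 1.0

    def test_symmetry(self):
        a = self._wells([5, 10, 15, 20])
        b = self._wells([30, 40, 50, 60])
        assert compare_groups(a, b).p_value == pytest.approx(
            compare_groups(b, a).p_value
        )

    def test_separated_groups_significant(self):
        a = self._wells([50, 55, 60, 52])
        b = self._wells([10, 12, 8, 11])
        res = compare_groups(a, b)
        assert res.p_value < 0.01
        assert res.mean_a > res.mean_b

    def test_small_group_rejected(self):
        a = self._wells([5, 10])
        with pytest.raises(ValueError, match="at least two"):
            compare_groups(a, a[:1])
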