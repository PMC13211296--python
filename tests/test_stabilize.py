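"""Stabilization tests: shift estimation, accumulation, resampling, cropping."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from isletscope.stabilize import (
    CropWindow,
    RegistrationError,
    ShiftSeries,
    Translation2D,
    accumulate_shifts,
    estimate_pairwise_shift,
    resample_to_reference,
    stabilize_stack,
    valid_crop_window,
)
from isletscope.stack import TimeLapseStack
from isletscope.synth import DriftModel, NoiseModel, render_scene
from isletscope.benchmark import drift_benchmark


def fourier_shift(frame, dy, dx):
    """Band-limited subpixel translation of content by (dy, dx)."""
    from scipy.fft import fft2, ifft2
    from scipy.ndimage import fourier_shift as _fs

    return ifft2(_fs(fft2(frame), (dy, dx))).real


class TestEstimatePairwiseShift:
    def test_identical_frames_give_zero(self, textured_frame):
        t = estimate_pairwise_shift(textured_frame, textured_frame, upsample=1)
        assert t.as_tuple() == (0.0, 0.0)

    @pytest.mark.parametrize("dy,dx", [(3, -2), (0, 5), (-7, -1), (10, 10)])
    def test_integer_roll_recovered_exactly(self, textured_frame, dy, dx):
        moved = np.roll(textured_frame, (dy, dx), axis=(0, 1))
        t = estimate_pairwise_shift(moved, textured_frame, upsample=1)
        assert t.as_tuple() == (float(dy), float(dx))

    def test_subpixel_shift_recovered(self, textured_frame):
        moved = fourier_shift(textured_frame, 0.5, -0.25)
        t = estimate_pairwise_shift(moved, textured_frame, upsample=20)
        assert abs(t.dy - 0.5) < 0.1 and abs(t.dx + 0.25) < 0.1

    @pytest.mark.parametrize("dy,dx", [(2.3, -1.1), (-0.7, 3.4), (4.0, 0.5)])
    def test_antisymmetry(self, textured_frame, dy, dx):
        upsample = 10
        moved = fourier_shift(textured_frame, dy, dx)
        ab = estimate_pairwise_shift(moved, textured_frame, upsample=upsample)
        ba = estimate_pairwise_shift(textured_frame, moved, upsample=upsample)
        assert abs(ab.dy + ba.dy) <= 1.0 / upsample
        assert abs(ab.dx + ba.dx) <= 1.0 / upsample

    def test_constant_frame_rejected(self, textured_frame):
        with pytest.raises(RegistrationError, match="constant"):
            estimate_pairwise_shift(np.ones((32, 32)), textured_frame[:32, :32])

    def test_shape_mismatch_rejected(self, textured_frame):
        with pytest.raises(RegistrationError, match="shapes differ"):
            estimate_pairwise_shift(textured_frame[:50], textured_frame)


class TestAccumulateShifts:
    def test_empty_list_gives_identity_series(self):
        series = accumulate_shifts([])
        assert len(series) == 1 and series[0].as_tuple() == (0.0, 0.0)

    def test_worked_running_sum(self):
        series = accumulate_shifts(
            [Translation2D(1, 2), Translation2D(-1, 0), Translation2D(0, 3)]
        )
        assert [s.as_tuple() for s in series.cumulative] == [
            (0.0, 0.0), (1.0, 2.0), (0.0, 2.0), (0.0, 5.0)
        ]

    def test_repeated_step_is_linear(self):
        k, a, b = 9, 0.25, -1.5
        series = accumulate_shifts([Translation2D(a, b)] * k)
        assert series[k].as_tuple() == pytest.approx((k * a, k * b))

    def test_non_finite_step_rejected(self):
        with pytest.raises(RegistrationError):
            accumulate_shifts([Translation2D(np.nan, 0.0)])


class TestResample:
    def _series(self, shifts):
        return ShiftSeries(tuple(Translation2D(*s) for s in shifts))

    def test_zero_shifts_identity(self, textured_frame):
        stack = TimeLapseStack(np.stack([textured_frame + 1] * 3))
        out = resample_to_reference(stack, self._series([(0, 0)] * 3))
        assert np.array_equal(out.frames, stack.frames)

    def test_integer_shift_zero_borders(self, textured_frame):
        frame = textured_frame + 1
        moved = np.roll(frame, (4, -3), axis=(0, 1))
        stack = TimeLapseStack(np.stack([frame, moved]))
        out = resample_to_reference(stack, self._series([(0, 0), (4, -3)]))
        # content restored on the overlap, zero-filled borders of exact widths
        assert np.array_equal(out.frames[1][:-4, 3:], frame[:-4, 3:])
        assert np.all(out.frames[1][-4:, :] == 0)
        assert np.all(out.frames[1][:, :3] == 0)

    def test_known_integer_drift_restores_frame0_exactly(self, small_scene, quiet):
        path = ((0.0, 0.0), (3.0, -2.0), (-1.0, 4.0)) + ((0.0, 0.0),) * 9
        stack, man = render_scene(
            small_scene, DriftModel(kind="fixed_path", path=path), quiet
        )
        series = self._series([tuple(s) for s in man.true_shifts])
        out = resample_to_reference(stack, series)
        window = valid_crop_window(series, stack.frame_shape)
        rs, cs = window.slices()
        for t in range(stack.n_frames):
            assert np.allclose(out.frames[t][rs, cs], stack.frames[0][rs, cs],
                               atol=1e-9)

    def test_known_fractional_drift_restores_frame0_to_interpolation(
        self, small_scene, quiet
    ):
        # one bilinear pass at render + one at resample double-smooths sharp
        # islet edges, so the residual is bounded in RMS, not in max
        path = ((0.0, 0.0), (2.5, -1.25), (-1.0, 3.0)) + ((0.0, 0.0),) * 9
        stack, man = render_scene(
            small_scene, DriftModel(kind="fixed_path", path=path), quiet
        )
        series = self._series([tuple(s) for s in man.true_shifts])
        out = resample_to_reference(stack, series)
        window = valid_crop_window(series, stack.frame_shape)
        rs, cs = window.slices()
        scale = np.ptp(stack.frames[0])
        for t in (1, 2):
            err = out.frames[t][rs, cs] - stack.frames[0][rs, cs]
            assert np.sqrt(np.mean(err**2)) < 0.03 * scale

    def test_no_overlap_rejected(self, textured_frame):
        stack = TimeLapseStack(np.stack([textured_frame + 1] * 2))
        with pytest.raises(RegistrationError, match="no overlap"):
            resample_to_reference(stack, self._series([(0, 0), (96, 0)]))


def brute_force_window(shifts, shape):
    """Oracle: shift a ones-image per frame, intersect near-unity pixels."""
    valid = np.ones(shape, dtype=bool)
    for dy, dx in shifts:
        ones = np.ones(shape)
        moved = ndi.shift(ones, (-dy, -dx), order=1, mode="constant", cval=0.0)
        valid &= moved > 1 - 1e-9
    return valid


class TestValidCropWindow:
    def _series(self, shifts):
        return ShiftSeries(tuple(Translation2D(*s) for s in shifts))

    def test_zero_shifts_full_frame(self):
        w = valid_crop_window(self._series([(0, 0)] * 4), (64, 48))
        assert (w.row_start, w.row_end, w.col_start, w.col_end) == (0, 64, 0, 48)

    def test_frame_height_shift_rejected(self):
        with pytest.raises(RegistrationError, match="extreme|valid"):
            valid_crop_window(self._series([(0, 0), (100, 0)]), (100, 100))

    @pytest.mark.parametrize("seed", range(6))
    def test_maximality_against_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        shifts = [(0.0, 0.0)] + [
            (float(rng.uniform(-6, 6)), float(rng.uniform(-6, 6)))
            for _ in range(n - 1)
        ]
        if rng.random() < 0.5:  # exercise the integer path too
            shifts = [(round(a), round(b)) for a, b in shifts]
        shape = (40, 36)
        w = valid_crop_window(self._series(shifts), shape)
        oracle = brute_force_window(shifts, shape)
        rs, cs = w.slices()
        # every pixel inside the window is valid in every frame
        assert oracle[rs, cs].all()
        # each binding side is tight: growing by one pixel admits an invalid one
        if w.row_start > 0:
            assert not oracle[w.row_start - 1, cs].all()
        if w.row_end < shape[0]:
            assert not oracle[w.row_end, cs].all()
        if w.col_start > 0:
            assert not oracle[rs, w.col_start - 1].all()
        if w.col_end < shape[1]:
            assert not oracle[rs, w.col_end].all()


class TestStabilizeStack:
    def test_static_stack_untouched(self, textured_frame):
        stack = TimeLapseStack(np.stack([textured_frame + 1] * 4))
        out, shifts, window = stabilize_stack(stack, upsample=1)
        assert np.allclose(shifts.as_array(), 0)
        assert window.shape == stack.frame_shape
        assert np.array_equal(out.frames, stack.frames)

    def test_recovers_random_walk_drift(self):
        stack, manifest = drift_benchmark(11)
        _, shifts, _ = stabilize_stack(stack)
        rmse = np.sqrt(np.mean((shifts.as_array() - manifest.true_shifts) ** 2))
        assert rmse <= 0.5

    def test_idempotence(self):
        # the residual motion a second pass finds between consecutive frames
        # is the first pass's per-step estimation error, near zero
        stack, _ = drift_benchmark(12)
        stabilized, _, _ = stabilize_stack(stack)
        _, shifts2, _ = stabilize_stack(stabilized)
        pairwise = np.diff(shifts2.as_array(), axis=0)
        assert np.abs(pairwise).max() <= 0.25

    def test_single_frame_rejected(self, textured_frame):
        with pytest.raises(RegistrationError):
            stabilize_stack(TimeLapseStack(textured_frame[None] + 1))
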