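"""Step-detector tests: the metric against a brute-force oracle, its exact
ideal-step calibration, peak picking, and effluent alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletscope.events import (
    EventError,
    align_events_to_bins,
    detect_events,
    rescale_for_display,
    smooth_trace,
    step_event_metric,
)
from isletscope.synth import EffluentBin


def oracle_metric(series, pre, post):
    """Independent double-loop implementation of the windowed step metric."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    out = np.full(n, np.nan)
    for t in range(n):
        if t - pre < 0 or t + post >= n:
            continue
        before = sum(series[t - pre + i] for i in range(pre)) / pre
        after = sum(series[t + 1 + i] for i in range(post)) / post
        out[t] = before - after
    return out


def ideal_step(n=40, k=20, base=10.0, delta=2.0):
    x = np.full(n, base)
    x[k:] = base - delta
    return x


class TestSmoothTrace:
    def test_constant_preserved(self):
        assert np.allclose(smooth_trace(np.full(9, 4.2), 3), 4.2)

    def test_shrinking_edge_arithmetic(self):
        out = smooth_trace([0, 3, 0, 3, 0], 3)
        assert np.allclose(out, [1.5, 1.0, 2.0, 1.0, 1.5])

    def test_window_one_is_identity(self, rng):
        x = rng.random(20)
        assert np.array_equal(smooth_trace(x, 1), x)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(EventError):
            smooth_trace(np.ones(10), window)

    def test_short_series_rejected(self):
        with pytest.raises(EventError):
            smooth_trace([1.0, 2.0], 5)


class TestStepEventMetric:
    def test_constant_series_all_zero(self):
        metric = step_event_metric(np.full(20, 7.0), 3, 3)
        assert np.allclose(metric.values[metric.valid], 0.0)

    def test_validity_contract(self):
        metric = step_event_metric(np.arange(20.0), pre=3, post=2,
                                   smoothing_window=3)
        margin = 1  # (3 - 1) // 2
        expected = np.zeros(20, dtype=bool)
        expected[3 + margin: 20 - 2 - margin] = True
        assert np.array_equal(metric.valid, expected)
        assert np.all(np.isnan(metric.values[~metric.valid]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 200))
        pre = int(rng.integers(1, 4))
        post = int(rng.integers(1, 4))
        if n <= pre + post:
            n = pre + post + 2
        x = rng.normal(size=n)
        metric = step_event_metric(x, pre, post)
        expected = oracle_metric(x, pre, post)
        assert np.array_equal(metric.valid, ~np.isnan(expected))
        assert np.allclose(metric.values[metric.valid],
                           expected[metric.valid], atol=1e-12)

    def test_unsmoothed_ideal_step_peaks_at_delta(self):
        delta = 2.0
        metric = step_event_metric(ideal_step(delta=delta), 3, 3)
        vals = metric.values[metric.valid]
        assert vals.max() == pytest.approx(delta, rel=1e-12)
        # the peak sits where the windows exactly flank the step
        peak_frames = np.flatnonzero(
            np.isclose(metric.values, delta) & metric.valid
        )
        assert set(peak_frames) == {19, 20}

    def test_smoothed_ideal_step_peaks_at_eight_ninths_delta(self):
        delta = 2.0
        smoothed = smooth_trace(ideal_step(delta=delta), 3)
        metric = step_event_metric(smoothed, 3, 3, smoothing_window=3)
        expected = oracle_metric(smoothed, 3, 3)  # brute force on the ramp
        vals = metric.values[metric.valid]
        assert vals.max() == pytest.approx((8.0 / 9.0) * delta, rel=1e-12)
        assert vals.max() == pytest.approx(np.nanmax(expected), rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=10, max_size=60),
        st.floats(-5, 5),
        st.floats(0.1, 10),
    )
    def test_affine_equivariance(self, xs, beta, alpha):
        x = np.asarray(xs)
        m1 = step_event_metric(alpha * x + beta, 3, 3)
        m0 = step_event_metric(x, 3, 3)
        assert np.allclose(m1.values[m1.valid], alpha * m0.values[m0.valid],
                           atol=1e-8 * max(1.0, np.abs(x).max()))

    @pytest.mark.parametrize("seed", range(5))
    def test_time_reversal_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=37)
        fwd = step_event_metric(x, 3, 3)
        rev = step_event_metric(x[::-1], 3, 3)
        assert np.allclose(rev.values[rev.valid],
                           -fwd.values[fwd.valid][::-1], atol=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(EventError, match="too short"):
            step_event_metric(np.ones(6), 3, 3)


class TestRescaleForDisplay:
    def test_worked_example(self):
        out = rescale_for_display(_manual([-1.0, 0.0, 3.0]))
        assert np.allclose(out, [0.0, 0.25, 1.0])

    def test_nonnegative_with_zero_min_divides_only(self):
        out = rescale_for_display(_manual([0.0, 2.0, 4.0]))
        assert np.allclose(out, [0.0, 0.5, 1.0])

    def test_pair_maps_to_unit_interval(self):
        out = rescale_for_display(_manual([1.5, 2.5]))
        assert np.allclose(out, [0.0, 1.0])

    def test_invalid_frames_propagate_as_nan(self):
        m = _manual([0.0, 1.0, 2.0], valid=[False, True, True])
        out = rescale_for_display(m)
        assert np.isnan(out[0]) and np.allclose(out[1:], [0.0, 1.0])

    def test_zero_range_rejected(self):
        with pytest.raises(EventError, match="zero range"):
            rescale_for_display(_manual([2.0, 2.0, 2.0]))


def _manual(values, valid=None):
    from isletscope.events import EventTrace

    values = np.asarray(values, dtype=float)
    valid = np.ones(len(values), dtype=bool) if valid is None else np.asarray(valid)
    vals = np.where(valid, values, np.nan)
    return EventTrace(values=vals, valid=valid, smoothing_window=1,
                      pre_window=1, post_window=1)


class TestDetectEvents:
    def test_single_peak_found(self):
        x = np.zeros(30)
        x[15:] = -1.0  # a single decrease
        metric = step_event_metric(x, 3, 3)
        events = detect_events(metric, top_k=1)
        assert len(events) == 1
        assert events[0].onset_frame in (14, 15)
        assert events[0].amplitude == pytest.approx(1.0)

    def test_equal_peaks_tie_break_earlier(self):
        m = _manual([0.0, 5.0, 5.0, 0.0, 0.0, 0.0, 0.0])
        events = detect_events(m, min_separation=5, top_k=5, )
        assert [e.onset_frame for e in events] == [1]

    def test_no_positive_values_gives_empty_list(self):
        m = _manual([-3.0, -1.0, -2.0, -5.0])
        assert detect_events(m, threshold=0.0) == []

    def test_separation_constraint(self):
        m = _manual([0, 4, 0, 0, 3, 0, 0, 0, 2, 0], valid=None)
        events = detect_events(m, min_separation=4, top_k=10, )
        assert [e.onset_frame for e in events] == [1, 8]


class TestAlignEventsToBins:
    def _bins(self, amounts, width=5):
        return [
            EffluentBin(i * width, (i + 1) * width, float(a))
            for i, a in enumerate(amounts)
        ]

    def _event(self, frame, amp=1.0):
        from isletscope.events import DetectedEvent

        return DetectedEvent(onset_frame=frame, amplitude=amp)

    def test_bin_assignment_by_integer_division(self):
        report = align_events_to_bins([self._event(17)], self._bins([0, 0, 0, 5]))
        assert report.loc[0, "bin_index"] == 3

    def test_empty_events_empty_report(self):
        assert len(align_events_to_bins([], self._bins([1, 2]))) == 0

    def test_increase_detection_in_bin_or_successor(self):
        bins = self._bins([0.0, 0.0, 4.0, 1.0])
        # event lands in the bin with the rise
        assert align_events_to_bins([self._event(11)], bins).loc[0, "effluent_increase"]
        # event lands one bin early; successor carries the rise
        assert align_events_to_bins([self._event(7)], bins).loc[0, "effluent_increase"]
        # flat neighborhood: no increase
        assert not align_events_to_bins([self._event(16)], bins).loc[0, "effluent_increase"]
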