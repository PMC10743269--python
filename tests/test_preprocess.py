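import numpy as np
import pytest

from crckit import (
    ExtrapolationError,
    FilterParams,
    InsufficientDataError,
    adaptive_filter,
    remove_recognition_errors,
    resample_uniform,
)
from conftest import make_intervals

PARAMS = FilterParams()


class TestRecognitionErrors:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.40, 1e-12, 0.42], [0.40, 0.42]),  # zero-length-ish interval
            ([0.40, 3.5, 0.42], [0.40, 0.42]),  # pause beyond rr_bounds
            ([0.40, 0.41, 0.42], [0.40, 0.41, 0.42]),  # all plausible
        ],
    )
    def test_deletes_implausible_intervals(self, values, expected):
        out = remove_recognition_errors(make_intervals(values), PARAMS)
        np.testing.assert_allclose(out.values, expected)

    def test_all_removed_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            remove_recognition_errors(make_intervals([5.0, 7.0]), PARAMS)

    def test_ibi_uses_its_own_bounds(self):
        s = make_intervals([2.0, 12.0, 16.0], kind="IBI")
        out = remove_recognition_errors(s, PARAMS)
        np.testing.assert_allclose(out.values, [2.0, 12.0])


class TestAdaptiveFilter:
    def test_constant_series_is_untouched(self):
        s = make_intervals([0.4] * 100)
        for seed in (0, 1, 99):
            out = adaptive_filter(s, PARAMS, np.random.default_rng(seed))
            np.testing.assert_array_equal(out.values, s.values)

    def test_outlier_free_data_identical_for_every_seed(self):
        # gentle drift: every jump well under the percent limit, every value
        # within sigma_mult adaptive stds
        t = np.arange(200)
        s = make_intervals(0.4 + 0.02 * np.sin(2 * np.pi * t / 40))
        ref = adaptive_filter(s, PARAMS, np.random.default_rng(0))
        np.testing.assert_array_equal(ref.values, s.values)
        for seed in (1, 2, 3):
            out = adaptive_filter(s, PARAMS, np.random.default_rng(seed))
            np.testing.assert_array_equal(out.values, s.values)

    def test_spike_replaced_within_adaptive_interval(self):
        # constant head -> mu_a = 0.4, sigma_a = 0, so the replacement interval
        # degenerates to the point {0.4}
        params = FilterParams(percent_limit=0.1)
        s = make_intervals([0.4] * 50 + [1.2] + [0.4] * 50)
        out, mask = adaptive_filter(s, params, np.random.default_rng(5), return_mask=True)
        assert mask[50] and mask.sum() == 1
        assert out.values[50] == pytest.approx(0.4)
        np.testing.assert_array_equal(np.delete(out.values, 50), [0.4] * 100)

    def test_seeds_differ_only_at_replaced_positions(self, rng):
        base = 0.4 + 0.01 * rng.standard_normal(300)
        base[[60, 150, 240]] = [1.3, 0.05, 1.1]  # isolated spikes
        s = make_intervals(np.abs(base) + 0.01)
        out1, m1 = adaptive_filter(s, PARAMS, np.random.default_rng(1), return_mask=True)
        out2, m2 = adaptive_filter(s, PARAMS, np.random.default_rng(2), return_mask=True)
        np.testing.assert_array_equal(m1, m2)
        assert m1.sum() >= 3
        diff = out1.values != out2.values
        assert diff.any()
        assert not np.any(diff & ~m1)
        np.testing.assert_array_equal(out1.values[~m1], s.values[~m1])

    def test_sustained_shift_is_preserved(self):
        # a bradycardia-like step: only the onset sample may be replaced,
        # the plateau itself must survive the filter
        s = make_intervals([0.4] * 60 + [0.75] * 10 + [0.4] * 60)
        out, mask = adaptive_filter(s, PARAMS, np.random.default_rng(0), return_mask=True)
        np.testing.assert_array_equal(out.values[61:70], [0.75] * 9)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            adaptive_filter(make_intervals([0.4] * 9), PARAMS, np.random.default_rng(0))


class TestResampleUniform:
    def test_constant_series_resamples_to_constant(self):
        s = make_intervals([0.5] * 30)
        u = resample_uniform(s, fs=4.0)
        assert np.allclose(u.values, 0.5)
        assert u.fs == 4.0

    def test_grid_length_formula(self):
        from crckit import IntervalSeries

        times = np.linspace(0.0, 12.0, 40)
        series = IntervalSeries("RR", times + 0.001 * np.arange(40), np.full(40, 0.5))
        u = resample_uniform(series, fs=4.0, t_start=0.01, t_end=10.01)
        assert len(u) == int(np.floor(10.0 * 4.0)) + 1 == 41
        assert np.allclose(np.diff(u.times), 0.25)

    def test_linear_ramp_recovered_on_nonuniform_samples(self, rng):
        times = np.sort(rng.uniform(0.0, 30.0, size=200))
        times += np.arange(200) * 1e-6  # guarantee strict increase
        from crckit import IntervalSeries

        s = IntervalSeries("RR", times, 0.4 + 0.01 * times)
        u = resample_uniform(s, fs=4.0, t_start=times[0], t_end=times[-1])
        np.testing.assert_allclose(u.values, 0.4 + 0.01 * u.times, atol=1e-6)

    def test_paired_series_share_identical_grid(self, small_subject_intervals):
        rr, ibi = small_subject_intervals
        t0 = max(rr.times[0], ibi.times[0])
        t1 = min(rr.times[-1], ibi.times[-1])
        u_rr = resample_uniform(rr, fs=4.0, t_start=t0, t_end=t1)
        u_ibi = resample_uniform(ibi, fs=4.0, t_start=t0, t_end=t1)
        assert u_rr.t0 == u_ibi.t0 and u_rr.fs == u_ibi.fs
        assert len(u_rr) == len(u_ibi)
        np.testing.assert_array_equal(u_rr.times, u_ibi.times)

    def test_positive_intervals_stay_positive_across_steps(self):
        # PCHIP must not overshoot below zero at a bradycardia step
        s = make_intervals([0.35] * 20 + [0.9] * 5 + [0.35] * 20)
        u = resample_uniform(s, fs=4.0)
        assert np.all(u.values > 0)

    def test_grid_outside_span_is_extrapolation_error(self):
        s = make_intervals([0.5] * 20)
        with pytest.raises(ExtrapolationError):
            resample_uniform(s, fs=4.0, t_start=0.0, t_end=100.0)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            resample_uniform(make_intervals([0.5, 0.5, 0.5]))
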