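import numpy as np
import pytest

from crckit import IntervalSeries, SynthConfig, generate_subject


def make_intervals(values, kind="RR", t0=0.0):
    """Interval series from values alone: event times are the cumulative sum."""
    values = np.asarray(values, dtype=float)
    times = t0 + np.cumsum(values)
    return IntervalSeries(kind=kind, times=times, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_subject():
    """A 15-min synthetic subject with a handful of bradycardia episodes."""
    cfg = SynthConfig(duration=900.0, brady_rate=24.0, seed=7)
    return generate_subject(cfg, "s_test", seed=1234)


@pytest.fixture(scope="session")
def small_subject_intervals(small_subject):
    from crckit import FilterParams, intervals_from_events, remove_recognition_errors

    params = FilterParams()
    rr = remove_recognition_errors(intervals_from_events(small_subject.beats), params)
    ibi = remove_recognition_errors(intervals_from_events(small_subject.breaths), params)
    return rr, ibi
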