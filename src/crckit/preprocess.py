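"""Interval-series preprocessing: artifact removal, adaptive filtering, resampling.

Three stages, applied in order to both the R-R and the IBI series:

1. *Recognition-error removal* deletes physically impossible intervals:
   non-positive durations and values outside a plausibility range (e.g. an
   R-R of 3.5 s in a neonate is a detector pause, not a heartbeat).
2. *Adaptive replacement filtering* maintains an exponentially updated
   adaptive mean ``mu_a`` and standard deviation ``sigma_a`` over accepted
   samples and replaces outliers with uniform random draws from
   ``[mu_a - 0.5*sigma_a, mu_a + 0.5*sigma_a]``.  The random replacement is
   the pipeline's source of trial-to-trial variability.
3. *Uniform resampling* interpolates both series onto a shared fixed-rate
   grid (4 Hz by default) so that R-R and IBI samples are paired in time.

Outlier rule.  A sample ``v_k`` is tested against the previous corrected
value (percent filter: relative jump larger than ``percent_limit``) and
against the adaptive mean (controlling filter: deviation larger than
``sigma_mult * sigma_a``).  A sample failing either test is still *accepted*
when it is within the percent tolerance of the previous **raw** sample:
two successive samples that agree with each other are evidence of a genuine
rhythm shift (the onset of a bradycardic deceleration looks exactly like a
step), whereas an isolated spike disagrees with both neighbours.  Without
this consistency clause a percent filter erases every sustained deceleration
— and the whole point of the downstream analysis is to keep them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d

from .errors import ExtrapolationError, InsufficientDataError
from .events import IntervalSeries

log = logging.getLogger(__name__)

#: grid positions are computed as floor((t_end - t_start) * fs) + 1 with this
#: slack so that an exactly representable span is not truncated by float error
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the adaptive replacement filter.

    adapt_coeff
        Weight ``c`` of the exponential update ``x_new = (1-c)*x_old + c*sample``
        for the adaptive mean/variance (per accepted sample).
    percent_limit
        Fractional beat-to-beat jump above which a sample is suspect.  The
        default 0.5 tolerates strong respiratory sinus arrhythmia (which in
        neonates can swing R-R by >30% between beats) while catching
        missed-beat doublings.
    sigma_mult
        Controlling-filter width in adaptive standard deviations.
    rr_bounds, ibi_bounds
        Plausibility ranges (seconds) used by recognition-error removal.
    init_window
        Number of leading samples whose mean/std seed ``mu_a``/``sigma_a``.
    """

    adapt_coeff: float = 0.05
    percent_limit: float = 0.5
    sigma_mult: float = 3.0
    rr_bounds: tuple[float, float] = (0.2, 2.0)
    ibi_bounds: tuple[float, float] = (0.3, 15.0)
    init_window: int = 20

    def __post_init__(self) -> None:
        if not 0.0 < self.adapt_coeff < 1.0:
            raise ValueError("adapt_coeff must be in (0, 1)")
        if self.percent_limit <= 0:
            raise ValueError("percent_limit must be positive")
        if self.sigma_mult <= 0:
            raise ValueError("sigma_mult must be positive")
        for lo, hi in (self.rr_bounds, self.ibi_bounds):
            if not lo < hi:
                raise ValueError("bounds must satisfy low < high")

    def bounds_for(self, kind: str) -> tuple[float, float]:
        return self.rr_bounds if kind == "RR" else self.ibi_bounds


@dataclass(frozen=True)
class UniformSeries:
    """Interval values resampled on a fixed-rate time grid."""

    kind: Literal["RR", "IBI"]
    fs: float
    t0: float
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def __len__(self) -> int:
        return int(self.values.size)


def remove_recognition_errors(s: IntervalSeries, params: FilterParams) -> IntervalSeries:
    """Delete (not replace) non-positive and out-of-bounds intervals."""
    lo, hi = params.bounds_for(s.kind)
    keep = (s.values > 0) & (s.values >= lo) & (s.values <= hi)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("%s: removed %d recognition errors (%d samples kept)",
                 s.kind, n_removed, int(keep.sum()))
    if len(s) and n_removed > 0.2 * len(s):
        log.warning("%s: %.0f%% of samples removed as recognition errors",
                    s.kind, 100.0 * n_removed / len(s))
    out = s.take(keep)
    if len(out) == 0:
        raise InsufficientDataError(f"{s.kind}: no intervals left after error removal")
    return out


def adaptive_filter(
    s: IntervalSeries,
    params: FilterParams,
    rng: np.random.Generator,
    return_mask: bool = False,
) -> IntervalSeries | tuple[IntervalSeries, np.ndarray]:
    """Replace outlier intervals with draws from ``[mu_a - 0.5 s_a, mu_a + 0.5 s_a]``.

    Same length in as out; the output depends on ``rng`` only at replaced
    positions.  ``mu_a``/``sigma_a`` are updated exponentially over accepted
    samples only.  With ``return_mask=True`` also returns the boolean array of
    replaced positions.
    """
    raw = np.asarray(s.values, dtype=float)
    n = raw.size
    if n < 10:
        raise InsufficientDataError(
            f"{s.kind}: adaptive filter needs >= 10 samples, got {n}"
        )
    c = params.adapt_coeff
    pl = params.percent_limit
    sm = params.sigma_mult

    head = raw[: min(params.init_window, n)]
    mu = float(np.mean(head))
    var = float(np.var(head, ddof=1))

    out = raw.copy()
    replaced = np.zeros(n, dtype=bool)
    half = 0.5
    for k in range(1, n):
        v = raw[k]
        prev_raw = raw[k - 1]
        prev_out = out[k - 1]
        consistent_raw = abs(v - prev_raw) <= pl * prev_raw
        if not consistent_raw:
            sigma = var ** 0.5
            percent_ok = abs(v - prev_out) <= pl * prev_out
            ctrl_ok = abs(v - mu) <= sm * sigma
            if not (percent_ok and ctrl_ok):
                out[k] = rng.uniform(mu - half * sigma, mu + half * sigma)
                replaced[k] = True
                continue
        dev = v - mu
        mu += c * dev
        var = (1.0 - c) * var + c * dev * dev

    if replaced.any():
        log.debug("%s: adaptive filter replaced %d/%d samples",
                  s.kind, int(replaced.sum()), n)
    result = s.replace_values(out)
    if return_mask:
        return result, replaced
    return result


def resample_uniform(
    s: IntervalSeries,
    fs: float = 4.0,
    t_start: float | None = None,
    t_end: float | None = None,
    interp: Literal["pchip", "linear"] = "pchip",
) -> UniformSeries:
    """Interpolate an interval series onto the grid ``t_start + k/fs``.

    The grid has ``floor((t_end - t_start) * fs) + 1`` points and must lie
    inside the data span (no extrapolation).  Shape-preserving piecewise-cubic
    (PCHIP) interpolation is the default: unlike a natural cubic spline it
    cannot overshoot into negative interval values at bradycardia steps.
    """
    if len(s) < 4:
        raise InsufficientDataError(f"{s.kind}: need >= 4 samples to resample")
    t_start = float(s.times[0] if t_start is None else t_start)
    t_end = float(s.times[-1] if t_end is None else t_end)
    if t_start < s.times[0] - _GRID_EPS or t_end > s.times[-1] + _GRID_EPS:
        raise ExtrapolationError(
            f"{s.kind}: grid [{t_start}, {t_end}] outside data span "
            f"[{s.times[0]}, {s.times[-1]}]"
        )
    if t_end < t_start:
        raise ExtrapolationError("t_end must be >= t_start")
    n = int(np.floor((t_end - t_start) * fs + _GRID_EPS)) + 1
    grid = t_start + np.arange(n) / fs
    # clip away float dust at the edges so the interpolator never sees an
    # out-of-domain query
    grid = np.clip(grid, s.times[0], s.times[-1])
    if interp == "pchip":
        f = PchipInterpolator(s.times, s.values, extrapolate=False)
    elif interp == "linear":
        f = interp1d(s.times, s.values, kind="linear", bounds_error=True)
    else:
        raise ValueError(f"unknown interpolation kind: {interp!r}")
    values = np.asarray(f(grid), dtype=float)
    return UniformSeries(kind=s.kind, fs=float(fs), t0=t_start, values=values)
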