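"""Bradycardia segmentation and B/NB sample balancing.

Neonatal bradycardia is operationalised as a heart-rate drop below 100 bpm
(R-R above 0.6 s) lasting at least two beats.  Each beat-wise R-R sample
``v[k]`` is flagged when

    v[k] >= 0.6 s  and  (v[k] + v[k+1] >= 1.2 s  or  v[k-1] + v[k] >= 1.2 s)

— a long beat qualifies together with either adjacent beat.  Pairing only
forward would silently drop the final beat of every episode whose successor
is a short recovered beat, which contradicts the definition: the last long
beat of a run *is* part of the bradycardia.  The rule is evaluated on the beat-domain
series — "lasts at least two beats" is a beat-domain statement — and the
flagged runs are then mapped to time spans that label the uniformly resampled
grid: a grid point belongs to the bradycardic (B) condition when its time
falls inside a span (closed on the left, open on the right), otherwise to the
non-bradycardic (NB) condition.

Because B periods are rare, the NB condition has vastly more grid samples;
random undersampling (RUS) draws an NB subset of exactly the B size, without
replacement, preserving the (R-R, IBI) pairing by selecting the same grid
indices in both series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import BalanceError, InsufficientDataError, SubjectExcludedError
from .events import IntervalSeries
from .preprocess import UniformSeries

#: R-R threshold equivalent to 100 bpm
RR_THRESHOLD = 0.6
#: minimum summed duration of two successive intervals
PAIR_THRESHOLD = 1.2
#: minimum number of B grid samples (2 s at 4 Hz) for a usable subject-trial
MIN_B_SAMPLES = 8


@dataclass(frozen=True)
class BeatFlagSeries:
    """Beat-wise R-R values with a boolean bradycardia flag per interval."""

    times: np.ndarray
    values: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.values) == len(self.flags)):
            raise ValueError("times, values and flags must have equal length")


@dataclass(frozen=True)
class SpanSet:
    """Disjoint, sorted [t_begin, t_end) time spans in seconds."""

    spans: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for b, e in self.spans:
            if not b < e:
                raise ValueError(f"span [{b}, {e}] must have t_begin < t_end")
            if b < prev_end:
                raise ValueError("spans must be sorted and non-overlapping")
            prev_end = e

    def __len__(self) -> int:
        return len(self.spans)

    def total_duration(self) -> float:
        return float(sum(e - b for b, e in self.spans))


@dataclass(frozen=True)
class PairedConditionSample:
    """Equal-length paired (R-R, IBI) grid values for one condition."""

    condition: Literal["B", "NB"]
    rr_values: np.ndarray
    ibi_values: np.ndarray
    source_indices: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.rr_values) == len(self.ibi_values) == len(self.source_indices)):
            raise ValueError("rr_values, ibi_values and source_indices must match")

    def __len__(self) -> int:
        return int(len(self.rr_values))


def flag_bradycardia(rr: IntervalSeries) -> BeatFlagSeries:
    """Apply the two-beat bradycardia rule to a beat-wise R-R series."""
    v = np.asarray(rr.values, dtype=float)
    n = v.size
    if n < 2:
        raise InsufficientDataError("bradycardia flagging needs >= 2 intervals")
    fwd = np.full(n, -np.inf)
    fwd[:-1] = v[:-1] + v[1:]
    back = np.full(n, -np.inf)
    back[1:] = v[:-1] + v[1:]
    flags = (v >= RR_THRESHOLD) & ((fwd >= PAIR_THRESHOLD) | (back >= PAIR_THRESHOLD))
    return BeatFlagSeries(times=rr.times, values=v, flags=flags)


def flags_to_spans(bf: BeatFlagSeries) -> SpanSet:
    """Convert maximal runs of flagged intervals into time spans.

    Each interval is end-anchored, so a flagged interval covers
    ``[time - value, time]``; a run of flagged intervals becomes the span from
    the start of its first interval to the end time of its last.
    """
    flags = np.asarray(bf.flags, dtype=bool)
    if not flags.any():
        return SpanSet()
    padded = np.concatenate(([False], flags, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2] - 1
    spans = tuple(
        (float(bf.times[i0] - bf.values[i0]), float(bf.times[i1]))
        for i0, i1 in zip(starts, stops)
    )
    return SpanSet(spans=spans)


def label_grid(u: UniformSeries, spans: SpanSet) -> np.ndarray:
    """Boolean B mask over the uniform grid: True iff t_k is in some span."""
    t = u.times
    mask = np.zeros(t.size, dtype=bool)
    for b, e in spans.spans:
        mask |= (t >= b) & (t < e)
    return mask


def split_conditions(
    u_rr: UniformSeries, u_ibi: UniformSeries, b_mask: np.ndarray
) -> tuple[PairedConditionSample, PairedConditionSample]:
    """Split paired uniform series into B and NB paired samples."""
    if len(u_rr) != len(u_ibi):
        raise ValueError("RR and IBI uniform series must share one grid")
    idx = np.arange(len(u_rr))
    b = PairedConditionSample(
        "B", u_rr.values[b_mask], u_ibi.values[b_mask], idx[b_mask]
    )
    nb = PairedConditionSample(
        "NB", u_rr.values[~b_mask], u_ibi.values[~b_mask], idx[~b_mask]
    )
    return b, nb


def balance_rus(
    b: PairedConditionSample,
    nb: PairedConditionSample,
    rng: np.random.Generator,
    min_b_samples: int = MIN_B_SAMPLES,
) -> PairedConditionSample:
    """Random undersampling: draw an NB subset of exactly ``len(b)`` paired samples.

    Sampling is uniform without replacement over NB grid indices, so the
    (R-R, IBI) pairing is preserved.  Deterministic given ``rng`` state.
    """
    if len(b) < min_b_samples:
        raise SubjectExcludedError(
            f"only {len(b)} bradycardic grid samples (< {min_b_samples})"
        )
    if len(nb) < len(b):
        raise BalanceError(
            f"NB condition has {len(nb)} samples, fewer than B's {len(b)}"
        )
    sel = np.sort(rng.choice(len(nb), size=len(b), replace=False))
    return PairedConditionSample(
        "NB", nb.rr_values[sel], nb.ibi_values[sel], nb.source_indices[sel]
    )
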