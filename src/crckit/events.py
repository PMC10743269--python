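"""Event-series ingestion: beat/breath annotation times and interval series.

Beat and breath events are represented as strictly increasing timestamps in
seconds from record start.  The derived interval series (R-R for beats, IBI
for breaths) anchors each interval to its *ending* event, so the k-th interval
value is ``times[k] - times[k-1]`` and is timestamped at ``times[k]``.  This
end-anchoring makes the time span of a run of flagged bradycardic beats
well-defined (see :mod:`crckit.segmentation`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import FormatError, InsufficientDataError, OrderingError

log = logging.getLogger(__name__)

EventKind = Literal["beat", "breath"]
IntervalKind = Literal["RR", "IBI"]

_KIND_TO_INTERVAL: dict[str, IntervalKind] = {"beat": "RR", "breath": "IBI"}


@dataclass(frozen=True)
class EventSeries:
    """Monotone event timestamps (beats or breaths), seconds from record start."""

    kind: EventKind
    times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise FormatError("event times must be a 1-D array")
        if times.size and times[0] < 0:
            raise OrderingError("event times must be non-negative")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise OrderingError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class IntervalSeries:
    """Interval durations (seconds) anchored to the ending event of each interval."""

    kind: IntervalKind
    times: np.ndarray
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise FormatError("interval times and values must be matching 1-D arrays")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise OrderingError("interval times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def replace_values(self, values: np.ndarray) -> "IntervalSeries":
        return IntervalSeries(self.kind, self.times, values, self.subject_id)

    def take(self, mask_or_idx) -> "IntervalSeries":
        return IntervalSeries(
            self.kind, self.times[mask_or_idx], self.values[mask_or_idx], self.subject_id
        )


def read_events(
    path: str | Path,
    kind: EventKind,
    format: Literal["wfdb_annotation", "event_text"] = "event_text",
    subject_id: str = "",
    annotator: str | None = None,
) -> EventSeries:
    """Read beat/breath event times from a file.

    ``event_text`` files hold one timestamp per line (seconds, ``.`` decimal
    separator); lines starting with ``#`` and blank lines are ignored.
    ``wfdb_annotation`` reads a PhysioNet annotation file via the optional
    ``wfdb`` package (``path`` is the record path, ``annotator`` the annotation
    extension); every annotation sample is accepted as an event, with no
    beat-type filtering.

    Duplicate timestamps are collapsed to a single event with a logged warning.
    """
    path = Path(path)
    if format == "event_text":
        times = _read_event_text(path)
    elif format == "wfdb_annotation":
        times = _read_wfdb_annotation(path, annotator)
    else:
        raise FormatError(f"unknown event format: {format!r}")

    if times.size >= 2 and np.any(np.diff(times) < 0):
        raise OrderingError(f"{path}: event times are not non-decreasing")
    uniq = np.unique(times)
    if uniq.size < times.size:
        log.warning(
            "%s: collapsed %d duplicate event timestamps", path, times.size - uniq.size
        )
    if uniq.size < 2:
        raise InsufficientDataError(
            f"{path}: need at least 2 events, found {uniq.size}"
        )
    return EventSeries(kind=kind, times=uniq, subject_id=subject_id)


def _read_event_text(path: Path) -> np.ndarray:
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    times: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: cannot parse {line!r} as a timestamp"
                ) from exc
    return np.asarray(times, dtype=float)


def _read_wfdb_annotation(path: Path, annotator: str | None) -> np.ndarray:
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB annotations requires the optional 'wfdb' package "
            "(pip install crckit[wfdb]); alternatively convert annotations to "
            "event_text (one timestamp per line)"
        ) from exc
    if annotator is None:
        raise FormatError("wfdb_annotation format requires an annotator extension")
    try:
        ann = wfdb.rdann(str(path), annotator)
    except Exception as exc:  # pragma: no cover - depends on wfdb internals
        raise FormatError(f"cannot read WFDB annotation {path}.{annotator}: {exc}") from exc
    return np.asarray(ann.sample, dtype=float) / float(ann.fs)


def intervals_from_events(events: EventSeries) -> IntervalSeries:
    """Derive the interval series (R-R or IBI) from an event series.

    Produces ``len(events) - 1`` intervals; interval k has value
    ``times[k+1] - times[k]`` and is timestamped at its ending event.
    """
    if len(events) < 2:
        raise InsufficientDataError("need at least 2 events to form intervals")
    diffs = np.diff(events.times)
    if np.any(diffs <= 0):
        raise OrderingError("event times must be strictly increasing")
    return IntervalSeries(
        kind=_KIND_TO_INTERVAL[events.kind],
        times=events.times[1:],
        values=diffs,
        subject_id=events.subject_id,
    )
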