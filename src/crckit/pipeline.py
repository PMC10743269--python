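"""End-to-end orchestration: synth/ingest -> preprocess -> trials -> comparison.

One call to :func:`run_pipeline` reproduces the whole study for a cohort:
per subject it extracts interval series, removes recognition errors once
(deterministic), runs the trial protocol (stochastic stages re-run per
trial), aggregates per-subject medians and finally compares B against NB
across subjects.  Everything is traceable to ``base_seed``; the resolved
configuration is snapshotted into the run directory before computation so a
run can be audited and repeated.

The numbered scripts under ``analysis/`` are thin drivers over this module.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import CohortError, SubjectExcludedError
from .events import EventSeries, IntervalSeries, intervals_from_events, read_events
from .preprocess import FilterParams, remove_recognition_errors
from .segmentation import MIN_B_SAMPLES
from .synth import SubjectFixture, SynthConfig, generate_cohort
from .trials import (
    SubjectSummary,
    TrialResult,
    cohort_compare,
    run_trials,
    subject_summaries_frame,
    trial_results_frame,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines one reproducible run."""

    mode: str = "synthetic"  # "synthetic" | "event_text"
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter_params: FilterParams = field(default_factory=FilterParams)
    fs: float = 4.0
    n_bins: int = 16
    interp: str = "pchip"
    n_trials: int = 100
    base_seed: int = 0
    min_b_samples: int = MIN_B_SAMPLES
    # event_text mode: list of (subject_id, beats_path, breaths_path)
    subjects: tuple[tuple[str, str, str], ...] = ()
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.mode not in ("synthetic", "event_text"):
            raise ValueError(f"unknown input mode: {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synth" in raw:
            synth = dict(raw["synth"])
            for key in ("mean_rr_range", "rsa_amp_range"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            raw["synth"] = SynthConfig(**synth)
        if "filter_params" in raw:
            fp = dict(raw["filter_params"])
            for key in ("rr_bounds", "ibi_bounds"):
                if key in fp:
                    fp[key] = tuple(fp[key])
            raw["filter_params"] = FilterParams(**fp)
        if "subjects" in raw:
            raw["subjects"] = tuple(tuple(s) for s in raw["subjects"])
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory outputs of one pipeline run."""

    trial_results: pd.DataFrame
    subject_summaries: pd.DataFrame
    cohort_comparison: pd.DataFrame
    summaries: list[SubjectSummary]
    excluded_subjects: list[str]
    out_dir: Path | None = None


def _load_subjects(cfg: RunConfig) -> list[tuple[str, EventSeries, EventSeries]]:
    if cfg.mode == "synthetic":
        fixtures = generate_cohort(cfg.synth)
        return [(fx.subject_id, fx.beats, fx.breaths) for fx in fixtures]
    subjects = []
    for subject_id, beats_path, breaths_path in cfg.subjects:
        beats = read_events(beats_path, kind="beat", subject_id=subject_id)
        breaths = read_events(breaths_path, kind="breath", subject_id=subject_id)
        subjects.append((subject_id, beats, breaths))
    if not subjects:
        raise CohortError("event_text mode requires at least one subject entry")
    return subjects


def prepare_subject(
    beats: EventSeries, breaths: EventSeries, params: FilterParams
) -> tuple[IntervalSeries, IntervalSeries]:
    """Deterministic per-subject preparation: intervals + recognition errors."""
    rr = remove_recognition_errors(intervals_from_events(beats), params)
    ibi = remove_recognition_errors(intervals_from_events(breaths), params)
    return rr, ibi


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full study described by ``cfg``.

    Subject ``i`` uses trial seeds ``base_seed + i*n_trials + k`` for trial
    ``k``, so every random draw is traceable to ``base_seed`` and subjects'
    streams never overlap.  Subjects without usable bradycardic data are
    logged and excluded; if none survive a :class:`CohortError` is raised.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(_config_to_dict(cfg), fh, indent=2, sort_keys=True)
            fh.write("\n")

    summaries: list[SubjectSummary] = []
    all_results: list[TrialResult] = []
    excluded: list[str] = []
    for i, (subject_id, beats, breaths) in enumerate(_load_subjects(cfg)):
        try:
            rr, ibi = prepare_subject(beats, breaths, cfg.filter_params)
            summary, results = run_trials(
                rr,
                ibi,
                n_trials=cfg.n_trials,
                base_seed=cfg.base_seed + i * cfg.n_trials,
                subject_id=subject_id,
                params=cfg.filter_params,
                fs=cfg.fs,
                n_bins=cfg.n_bins,
                min_b_samples=cfg.min_b_samples,
                interp=cfg.interp,
            )
        except (SubjectExcludedError, CohortError) as exc:
            log.warning("subject %s excluded: %s", subject_id, exc)
            excluded.append(subject_id)
            continue
        summaries.append(summary)
        all_results.extend(results)

    if not summaries:
        raise CohortError("no subject produced usable results")
    if len(summaries) < 3:
        raise CohortError(
            f"only {len(summaries)} usable subjects; need >= 3 for the comparison"
        )

    result = RunResult(
        trial_results=trial_results_frame(all_results),
        subject_summaries=subject_summaries_frame(summaries),
        cohort_comparison=cohort_compare(summaries),
        summaries=summaries,
        excluded_subjects=excluded,
        out_dir=out_dir,
    )
    if out_dir is not None:
        result.trial_results.to_csv(out_dir / "trial_results.csv", index=False)
        result.subject_summaries.to_csv(out_dir / "subject_summaries.csv", index=False)
        result.cohort_comparison.to_csv(out_dir / "cohort_comparison.csv", index=False)
        log.info("run outputs written to %s", out_dir)
    return result


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
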