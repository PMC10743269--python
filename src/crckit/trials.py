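"""The 100-trial protocol and the exact Wilcoxon signed-rank comparison.

Each trial re-runs the stochastic stages of the pipeline for one subject —
adaptive filtering (random replacements), 4 Hz resampling, bradycardia
segmentation and random undersampling — and evaluates the five
information-theory metrics under both conditions.  Per subject, the median
of each metric over trials is the quantity carried to the cohort-level
comparison: an exact two-sided Wilcoxon matched-pairs signed-rank test of
B against NB across subjects.

With ten subjects the normal approximation to the signed-rank null is poor,
so p-values come from the exact distribution of W+ over all 2^n equiprobable
sign assignments (zero differences dropped, tied |differences| given average
ranks).  The distribution is computed by subset-sum counting over the ranks,
which enumerates the 2^n assignments implicitly and exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateTestError, SubjectExcludedError
from .events import IntervalSeries
from .infotheory import METRIC_NAMES, condition_metrics, make_binning
from .preprocess import FilterParams, adaptive_filter, resample_uniform
from .segmentation import (
    MIN_B_SAMPLES,
    balance_rus,
    flag_bradycardia,
    flags_to_spans,
    label_grid,
    split_conditions,
)

log = logging.getLogger(__name__)

CONDITIONS = ("B", "NB")


@dataclass(frozen=True)
class TrialResult:
    """Metric values for one subject-trial, per condition."""

    subject_id: str
    trial_index: int
    metrics: dict  # {"B": {metric: value}, "NB": {...}}
    n_b_samples: int


@dataclass(frozen=True)
class SubjectSummary:
    """Per-condition median of each metric over a subject's completed trials."""

    subject_id: str
    medians: dict  # {"B": {metric: value}, "NB": {...}}
    n_trials_completed: int
    n_trials_attempted: int


def run_trial(
    rr_clean: IntervalSeries,
    ibi_clean: IntervalSeries,
    seed: int,
    subject_id: str = "",
    trial_index: int = 0,
    params: FilterParams | None = None,
    fs: float = 4.0,
    n_bins: int = 16,
    min_b_samples: int = MIN_B_SAMPLES,
    interp: str = "pchip",
) -> TrialResult:
    """One stochastic pass: filter -> flag -> resample -> balance -> measure.

    ``rr_clean``/``ibi_clean`` are recognition-error-free beat-wise series;
    all randomness (filter replacements, undersampling) derives from ``seed``,
    so the result is bit-reproducible.
    """
    params = params or FilterParams()
    rng = np.random.default_rng(seed)
    rr_f = adaptive_filter(rr_clean, params, rng)
    ibi_f = adaptive_filter(ibi_clean, params, rng)

    spans = flags_to_spans(flag_bradycardia(rr_f))

    t0 = max(float(rr_f.times[0]), float(ibi_f.times[0]))
    t1 = min(float(rr_f.times[-1]), float(ibi_f.times[-1]))
    u_rr = resample_uniform(rr_f, fs=fs, t_start=t0, t_end=t1, interp=interp)
    u_ibi = resample_uniform(ibi_f, fs=fs, t_start=t0, t_end=t1, interp=interp)

    b, nb = split_conditions(u_rr, u_ibi, label_grid(u_rr, spans))
    nb_bal = balance_rus(b, nb, rng, min_b_samples=min_b_samples)

    spec = make_binning(
        np.concatenate([b.rr_values, nb_bal.rr_values]),
        np.concatenate([b.ibi_values, nb_bal.ibi_values]),
        n_bins=n_bins,
    )
    metrics = {
        "B": condition_metrics(b.rr_values, b.ibi_values, spec),
        "NB": condition_metrics(nb_bal.rr_values, nb_bal.ibi_values, spec),
    }
    return TrialResult(subject_id, trial_index, metrics, n_b_samples=len(b))


def run_trials(
    rr_clean: IntervalSeries,
    ibi_clean: IntervalSeries,
    n_trials: int = 100,
    base_seed: int = 0,
    subject_id: str = "",
    **trial_kwargs,
) -> tuple[SubjectSummary, list[TrialResult]]:
    """Repeat :func:`run_trial` with seeds ``base_seed + k`` and take medians.

    Trials that raise :class:`SubjectExcludedError` (too little bradycardic
    data) are logged and skipped; if no trial completes the subject is
    excluded.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    results: list[TrialResult] = []
    for k in range(n_trials):
        try:
            results.append(
                run_trial(
                    rr_clean,
                    ibi_clean,
                    seed=base_seed + k,
                    subject_id=subject_id,
                    trial_index=k,
                    **trial_kwargs,
                )
            )
        except SubjectExcludedError as exc:
            log.info("subject %s trial %d excluded: %s", subject_id, k, exc)
    if not results:
        raise SubjectExcludedError(
            f"subject {subject_id}: no trial produced usable bradycardic data"
        )
    return aggregate_medians(results, n_trials_attempted=n_trials), results


def aggregate_medians(
    results: list[TrialResult], n_trials_attempted: int | None = None
) -> SubjectSummary:
    """Per-metric, per-condition median over a subject's trial results."""
    if not results:
        raise SubjectExcludedError("no trial results to aggregate")
    medians = {
        cond: {
            m: float(np.median([r.metrics[cond][m] for r in results]))
            for m in METRIC_NAMES
        }
        for cond in CONDITIONS
    }
    return SubjectSummary(
        subject_id=results[0].subject_id,
        medians=medians,
        n_trials_completed=len(results),
        n_trials_attempted=n_trials_attempted or len(results),
    )


def wilcoxon_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; ties in |d| receive average ranks.  Returns
    ``(W, p)`` where ``W = min(W+, W-)`` and ``p`` is the exact two-sided
    probability under the null that every retained difference is positive or
    negative with probability 1/2 independently:
    ``p = min(1, 2 * min(P(W+ <= w+), P(W+ >= w+)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not 3 <= x.size <= 25:
        raise ValueError("exact test supported for 3 <= n <= 25 pairs")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    # exact null distribution of 2*W+ by subset-sum counting over the doubled
    # (hence integer) ranks; equivalent to enumerating all 2^n sign vectors
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        dist[r:] += dist[: dist.size - r].copy()
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    p = min(1.0, 2.0 * min(cdf, sf))
    return w, p


def cohort_compare(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """B vs NB across subjects for each metric.

    Returns one row per metric with the cohort mean +/- sd of the per-subject
    medians under each condition, the signed-rank statistic W and the exact
    two-sided p.  A metric whose differences are all zero is reported with
    NaN statistics and a note, without aborting the other metrics.
    """
    if len(summaries) < 3:
        raise ValueError("cohort comparison needs >= 3 subjects")
    rows = []
    for m in METRIC_NAMES:
        b_vals = np.array([s.medians["B"][m] for s in summaries])
        nb_vals = np.array([s.medians["NB"][m] for s in summaries])
        row = {
            "metric": m,
            "mean_B": float(b_vals.mean()),
            "sd_B": float(b_vals.std(ddof=1)),
            "mean_NB": float(nb_vals.mean()),
            "sd_NB": float(nb_vals.std(ddof=1)),
            "n_subjects": len(summaries),
        }
        try:
            w, p = wilcoxon_exact(b_vals, nb_vals)
            row.update({"W": w, "p": p, "note": ""})
        except DegenerateTestError as exc:
            row.update({"W": np.nan, "p": np.nan, "note": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)


def trial_results_frame(results: list[TrialResult]) -> pd.DataFrame:
    """Long-format table: one row per (subject, trial, condition)."""
    rows = []
    for r in results:
        for cond in CONDITIONS:
            rows.append(
                {
                    "subject": r.subject_id,
                    "trial": r.trial_index,
                    "condition": cond,
                    **{m: r.metrics[cond][m] for m in METRIC_NAMES},
                }
            )
    return pd.DataFrame(rows)


def subject_summaries_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for cond in CONDITIONS:
            rows.append(
                {
                    "subject": s.subject_id,
                    "condition": cond,
                    "n_trials_completed": s.n_trials_completed,
                    **{m: s.medians[cond][m] for m in METRIC_NAMES},
                }
            )
    return pd.DataFrame(rows)
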