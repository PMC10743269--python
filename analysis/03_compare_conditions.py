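#!/usr/bin/env python
"""Compare bradycardic and non-bradycardic conditions across subjects.

Takes the per-subject medians from 02_run_trial_protocol.py and, for each of
the five measures, runs the exact two-sided Wilcoxon matched-pairs
signed-rank test of B against NB across subjects, reporting cohort
mean +/- sd per condition.  Writes results/cohort_comparison.csv and, if
matplotlib is available, a per-subject B-vs-NB boxplot figure to
scratch/figures/.

Run from the repository root:  python analysis/03_compare_conditions.py
"""

import argparse
from pathlib import Path

import pandas as pd

from crckit import cohort_compare
from crckit.infotheory import METRIC_NAMES
from crckit.trials import SubjectSummary

ROOT = Path(__file__).resolve().parents[1]


def summaries_from_frame(df: pd.DataFrame) -> list[SubjectSummary]:
    summaries = []
    for subject, group in df.groupby("subject", sort=False):
        medians = {
            row["condition"]: {m: float(row[m]) for m in METRIC_NAMES}
            for _, row in group.iterrows()
        }
        n_done = int(group["n_trials_completed"].iloc[0])
        summaries.append(SubjectSummary(str(subject), medians, n_done, n_done))
    return summaries


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--summaries", type=Path, default=ROOT / "results" / "subject_summaries.csv"
    )
    args = ap.parse_args()
    if not args.summaries.exists():
        raise SystemExit(
            f"{args.summaries} not found - run analysis/02_run_trial_protocol.py first"
        )

    df = pd.read_csv(args.summaries)
    summaries = summaries_from_frame(df)
    comparison = cohort_compare(summaries)
    out = ROOT / "results" / "cohort_comparison.csv"
    comparison.to_csv(out, index=False)

    print(f"{len(summaries)} subjects compared; table written to {out}\n")
    print(comparison.round(4).to_string(index=False))
    sig = comparison[comparison["p"] < 0.05]["metric"].tolist()
    print(
        f"\nmetrics with p < 0.05: {', '.join(sig) if sig else 'none'} "
        "(exact Wilcoxon signed-rank on per-subject medians)"
    )

    try:
        _plot(df)
    except ImportError:
        print("matplotlib not installed - skipping the boxplot figure")


def _plot(df: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(METRIC_NAMES), figsize=(15, 3.2))
    for ax, metric in zip(axes, METRIC_NAMES):
        data = [
            df.loc[df.condition == cond, metric].to_numpy() for cond in ("B", "NB")
        ]
        ax.boxplot(data, tick_labels=["B", "NB"])
        ax.set_title(metric)
        ax.set_ylabel("bits")
    fig.suptitle("Per-subject medians by condition")
    fig.tight_layout()
    out = ROOT / "scratch" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    fig.savefig(out / "condition_boxplots.png", dpi=120)
    print(f"boxplot figure written to {out / 'condition_boxplots.png'}")


if __name__ == "__main__":
    main()
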