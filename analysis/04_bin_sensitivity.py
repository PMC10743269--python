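#!/usr/bin/env python
"""Sensitivity of the condition contrast to the histogram bin count.

The number of bins is the one free parameter of the plug-in estimators: too
few bins wash out distribution shape, too many inflate the finite-sample
bias.  This sweep reruns a reduced protocol (10 subjects, 10 trials) at
several bin counts and reports the cohort MI means and the exact Wilcoxon
p-value per metric, showing that the direction of the B-vs-NB contrast does
not depend on the default of 16.

Run from the repository root:  python analysis/04_bin_sensitivity.py [--seed N]
"""

import argparse
from pathlib import Path

import pandas as pd

from crckit import RunConfig, SynthConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bins", type=int, nargs="+", default=[8, 12, 16, 24, 32])
    args = ap.parse_args()

    rows = []
    for n_bins in args.bins:
        cfg = RunConfig(
            synth=SynthConfig(seed=args.seed),
            n_trials=10,
            base_seed=args.seed,
            n_bins=n_bins,
        )
        res = run_pipeline(cfg)
        comp = res.cohort_comparison.set_index("metric")
        rows.append(
            {
                "n_bins": n_bins,
                "mi_mean_b": comp.loc["MI", "mean_B"],
                "mi_mean_nb": comp.loc["MI", "mean_NB"],
                "mi_p": comp.loc["MI", "p"],
                "h_rr_p": comp.loc["H_rr", "p"],
                "h_ibi_p": comp.loc["H_ibi", "p"],
            }
        )
    df = pd.DataFrame(rows)
    out = ROOT / "results" / "bin_sensitivity.csv"
    out.parent.mkdir(exist_ok=True)
    df.to_csv(out, index=False)
    print(df.round(4).to_string(index=False))
    consistent = (df.mi_mean_b < df.mi_mean_nb).all()
    print(
        f"\nMI_B < MI_NB at every bin count: {consistent}; table written to {out}"
    )


if __name__ == "__main__":
    main()
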