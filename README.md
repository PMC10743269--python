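# crckit — cardiorespiratory coupling under neonatal bradycardia

`crckit` analyses the interdependence of cardiac and respiratory rhythms in
preterm infants, comparing periods with and without bradycardia.  It is
written for physiologists and biomedical engineers who have beat and breath
*event annotations* (not waveforms) and want a reproducible, statistically
calibrated answer to: *does cardiorespiratory coupling weaken when the heart
slows?*

## What it computes

From beat events the interbeat (R-R) series is derived, from breath events
the inter-breath interval (IBI) series.  After artifact filtering and
resampling to a shared 4 Hz grid, samples are split into bradycardic (B:
R-R ≥ 0.6 s for at least two beats) and non-bradycardic (NB) conditions,
balanced by random undersampling, binned, and compared with plug-in
information measures in bits:

- entropy `H(X) = -Σ p(x_i) log2 p(x_i)` of R-R and of IBI,
- cross-entropy `cH(X,Y) = -Σ p(x_i) log2 p(y_i)`,
- mutual information `MI(X,Y) = H(X) + H(Y) - H(X,Y)` — the coupling index.

Because the artifact filter replaces outliers with random draws and the
undersampling is random, the stochastic stages are repeated over 100 trials
per subject; per-subject medians are compared across subjects with an exact
two-sided Wilcoxon matched-pairs signed-rank test.

A synthetic cohort generator (`crckit.synth`) produces beat/breath event
series with controllable respiratory sinus arrhythmia depth and injectable
bradycardia episodes, so the full analysis runs — and is validated — with no
recorded data.

## Worked example

```python
from crckit import RunConfig, SynthConfig, run_pipeline

cfg = RunConfig(synth=SynthConfig(seed=1), n_trials=100, base_seed=1)
res = run_pipeline(cfg)
print(res.cohort_comparison.round(4).to_string(index=False))
```

prints (10 synthetic subjects, 30-min records, coupling depth 0.05 during
episodes vs 0.3 outside):

```
   metric  mean_B   sd_B  mean_NB  sd_NB  n_subjects   W     p note
     H_rr  1.7680 0.0888   3.0036 0.0199          10 0.0 0.002
    H_ibi  3.1788 0.1857   3.4811 0.0526          10 0.0 0.002
       MI  0.2894 0.0800   0.4761 0.1078          10 0.0 0.002
cH_rr_ibi  7.8380 1.2645   4.3209 0.2378          10 0.0 0.002
cH_ibi_rr  6.8637 0.2113   5.2659 0.3414          10 0.0 0.002
```

Read: during bradycardia the R-R distribution collapses (H_rr 1.77 vs 3.00
bits), breathing irregularity barely changes, and mutual information drops
(0.29 vs 0.48 bits) — the generator's suppressed-coupling episodes are
recovered as weaker CRC, each with exact signed-rank p = 2/1024 across the
ten subjects.  `res.trial_results` holds the underlying 1000 trial values
per metric and condition; with `out_dir` set, `run_pipeline` writes
`trial_results.csv`, `subject_summaries.csv`, `cohort_comparison.csv` and a
config snapshot into a run directory.

## The analysis, step by step

The numbered scripts under `analysis/` run the study as a narrative, from
the repository root:

```bash
python analysis/01_simulate_cohort.py      # cohort fixtures -> scratch/cohort/
python analysis/02_run_trial_protocol.py   # 100-trial protocol per subject
python analysis/03_compare_conditions.py   # exact Wilcoxon B vs NB + boxplots
python analysis/04_bin_sensitivity.py      # contrast stability over bin counts
```

Small result tables land in `results/`; bulky per-trial tables and figures
go to `scratch/`.  To analyse real recordings instead, export beat and
breath annotations to event-text (one timestamp per line; `#` comments
allowed) and use `RunConfig(mode="event_text", subjects=...)` as in
`analysis/02_run_trial_protocol.py`, or read WFDB annotation files directly
via `read_events(..., format="wfdb_annotation", annotator=...)` with the
optional `wfdb` package installed.

## Layout

- `src/crckit/` — the library: `events` (ingestion), `preprocess`
  (adaptive filter, resampling), `segmentation` (bradycardia rule, RUS),
  `infotheory` (measures), `trials` (protocol, exact Wilcoxon), `synth`
  (generator), `pipeline` (orchestration).
- `analysis/` — the numbered study drivers above.
- `docs/methods.md` — models, parameter choices and their rationale,
  numerical conventions, limitations.
- `tests/` — unit, property and end-to-end suites.
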