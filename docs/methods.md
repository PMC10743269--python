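# Methods

## Problem and quantities

Preterm infants frequently show bradycardia — heart rate below 100 bpm,
equivalently interbeat (R-R) intervals above 0.6 s, lasting at least two
beats.  The analysis asks whether cardiorespiratory coupling (CRC), the
statistical interdependence between the cardiac and respiratory rhythms,
differs between bradycardic (B) and non-bradycardic (NB) periods.  The
observables are the beat-wise R-R series and the breath-wise inter-breath
interval (IBI) series derived from event annotations; the measures are
histogram (plug-in) estimators, in bits:

- Shannon entropy `H(X) = -Σ p(x_i) log2 p(x_i)` of the binned R-R and IBI
  values, a measure of irregularity;
- cross-entropy `cH(X,Y) = -Σ p(x_i) log2 p(y_i)` over a by-index shared bin
  alphabet (asymmetric in its arguments);
- mutual information `MI(X,Y) = H(X) + H(Y) - H(X,Y)`, the CRC measure.

## Pipeline

Per subject and per trial:

1. **Interval extraction.**  Beat/breath event times (strictly increasing,
   seconds) become interval series; each interval is anchored to its ending
   event, so a run of flagged beats maps to a well-defined time span.
2. **Recognition-error removal** (deterministic): non-positive intervals and
   values outside plausibility bounds (R-R outside 0.2–2.0 s, IBI outside
   0.3–15 s) are deleted.
3. **Adaptive replacement filtering** (stochastic): an adaptive mean `mu_a`
   and standard deviation `sigma_a` are maintained by exponential updates
   (`x_new = (1-c) x_old + c·sample`, c = 0.05) over accepted samples,
   seeded from the first 20 samples.  A sample is suspect when it jumps more
   than `percent_limit` relative to the previous corrected value (percent
   filter) or deviates more than `sigma_mult·sigma_a` from `mu_a`
   (controlling filter); a suspect sample is nevertheless accepted when it
   is within the percent tolerance of the previous *raw* sample.  Outliers
   are replaced by uniform draws from `[mu_a - 0.5 sigma_a, mu_a + 0.5 sigma_a]`;
   these random replacements are the pipeline's source of trial-to-trial
   variability, alongside undersampling.
4. **Bradycardia flagging** on the filtered beat-wise series:
   `v[k] >= 0.6 s` and `v[k]+v[k+1] >= 1.2 s` or `v[k-1]+v[k] >= 1.2 s`.
   Maximal flagged runs become time spans.
5. **Uniform resampling** of both series at 4 Hz over the intersection of
   their time spans (shared grid, so samples are paired in time), using
   shape-preserving piecewise-cubic (PCHIP) interpolation.
6. **Condition labelling and balancing.**  Grid points inside a span
   (closed left, open right) are B, the rest NB.  Random undersampling
   draws an NB subset of exactly the B size, uniformly without replacement
   over grid indices, preserving the (R-R, IBI) pairing.
7. **Measures.**  Equal-width bin edges (16 bins per variable) are built
   over the pooled B+NB range of the trial, so both conditions share one
   alphabet; the five metrics (H_rr, H_ibi, MI, and both cross-entropies)
   are evaluated per condition.

The stochastic stages (3–7) are repeated over 100 trials per subject; the
per-subject median of each metric enters an exact two-sided Wilcoxon
matched-pairs signed-rank test of B against NB across subjects.

## Design choices and their rationale

**Adaptive-filter thresholds.**  `percent_limit = 0.5` and the
raw-consistency clause are deliberate departures from the common "10%
percent filter".  Neonatal records combine two features that defeat a naive
percent filter: respiratory sinus arrhythmia at ~5 beats per breath can
legitimately change R-R by >30% between beats, and bradycardic
decelerations are sustained near-step changes.  A 10% filter without a
consistency clause replaces the majority of physiological samples and
erases every episode before segmentation can see it.  The implemented rule
— replace only samples inconsistent with both the corrected series and the
immediately preceding raw sample — removes isolated spikes (missed/extra
detections) while passing any shift that two successive samples agree on.
The cost is that two-beat artifacts are adopted as rhythm; no causal
single-pass filter can distinguish those from a genuine deceleration onset.
All thresholds are exposed in `FilterParams`.

**Two-beat rule pairing.**  The duration clause pairs a long interval with
either adjacent interval.  Forward-only pairing would unflag the final beat
of an episode whenever the first recovered beat is short, systematically
truncating every detected span by one beat; under the symmetric rule,
detected spans on clean data equal the injected episodes exactly.  The hard
invariant — an interval below 0.6 s is never flagged — is independent of the
pairing choice.

**Segmentation domain.**  The two-beat rule is evaluated on the beat-domain
(filtered, non-resampled) series, because "lasts two beats" is a statement
about beats; labels are transferred to the 4 Hz grid via the spans.

**Binning.**  16 equal-width bins per variable, constant across subjects,
trials and conditions, with edges spanning the pooled range of the two
balanced conditions within each subject-trial.  A fixed count keeps the two
conditions' entropies comparable (both bounded by 4 bits) and, because the
conditions are balanced to equal sample counts on shared edges, the
estimators' finite-sample bias largely cancels in the B-NB contrast.  The
plug-in estimators are used literally, with no bias correction; the
positive MI bias is a documented property, not corrected away.
`analysis/04_bin_sensitivity.py` shows the contrast direction is stable
over 8–32 bins.

**Cross-entropy zero handling.**  `-Σ p log2 q` is infinite when q has an
empty bin where p is positive.  Only in that case q is replaced by its
Jeffreys-smoothed version (add 0.5 to each bin count, renormalise); when q
has no relevant empty bins the raw distribution is used, so `cH(p, p) =
H(p)` whenever p has full support.

**Exact Wilcoxon.**  With n = 10 subjects the normal approximation is poor,
so the p-value comes from the exact null distribution of W+ over all 2^n
sign assignments (zeros dropped, average ranks for ties), computed by
subset-sum counting over the doubled ranks; `p = min(1, 2·min(P(W+ <= w),
P(W+ >= w)))`.  This matches `scipy.stats.wilcoxon(..., method="exact")` on
tie-free data and remains exact with ties, where scipy falls back to an
approximation.

**Seeding.**  Subject i's trial k uses seed `base_seed + i·n_trials + k`;
fixture generation derives per-subject seeds from the cohort seed via
`SeedSequence`.  A configuration therefore determines every output
bit-for-bit.

**Minimum bradycardic data.**  A subject-trial with fewer than 8 B grid
samples (2 s at 4 Hz) is excluded and not re-rolled; a subject with no
completed trial is dropped from the cohort comparison with a log entry.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- **Breathing:** positive-truncated AR(1) inter-breath intervals
  (mean 2 s, CV 0.2, lag-1 correlation 0.4).
- **RSA:** `RR = mean_rr·(depth + m·a(D)·sin 2πφ)·(1+ε)`, with φ the
  fractional phase of the breath cycle at the beat time, m the coupling
  depth (0.3 outside episodes, 0.05 inside, by default), ε Gaussian with
  CV 0.02, and `a(D) = clip(D/mean_ibi, 0.5, 1.5)` scaling RSA amplitude
  with the current breath duration.  The amplitude–period scaling is what
  couples the R-R *value* to the IBI *value* — phase modulation alone
  leaves the two histograms independent, and deeper RSA in slower breathing
  is the standard physiological picture of vagal modulation.
- **Bradycardia:** Poisson onsets (20/h), each raising the baseline term
  from 1 to `brady_depth = 2` for 10 beats (R-R ≈ 0.8 s at the default
  0.4 s mean; episodes starting inside an episode merge into one).  The
  baseline shift is additive with respect to the RSA term so the absolute
  RSA swing — and hence histogram support width — is the same in both
  conditions; a multiplicative shift would widen the B support, handing the
  plug-in MI estimator a condition-asymmetric bias that breaks null
  calibration.  With the defaults every episode beat stays above 0.6 s at
  the deepest RSA dip, so injected and detected spans coincide on clean
  data.
- **Cohort:** per-subject mean R-R drawn from 0.36–0.44 s; with the ~2%
  lengthening contributed by episodes this keeps realised mean heart rates
  inside the 131–167 bpm band observed in preterm cohorts.
- 30-minute records (not the 20–70 h of bedside monitoring) are enough for
  stable 16-bin histograms while keeping a 10-subject, 100-trial study in
  seconds of compute.

What the generator does *not* emulate: apnea, movement artifacts, missed or
spurious detections (tests inject those separately), non-stationary drift
of the baseline rates, sleep-state structure, and any maturation effect.
Passing tests therefore show that the pipeline recovers the coupling
structure it is pointed at and is calibrated under its own null — not that
real recordings satisfy these assumptions.

## Numerical conventions

- `0·log2 0 = 0` throughout; probabilities validated to 1e-12.
- Histogram bins are left-closed, right-open, last bin closed (numpy
  convention), with the pooled range guaranteeing no out-of-range value.
- Resampling grids have `floor((t_end - t_start)·fs) + 1` points with a
  1e-9 slack against float truncation, and never extrapolate.
- The balanced NB selection is sorted for determinism; the measures are
  order-invariant, so sorting is cosmetic.
- Spans are compared with a 1e-9 s tolerance (cumulative-sum float error).

## Problem sizes used in checks

The repeated-protocol checks run at the study's native scale (10 subjects,
30-min records, 100 trials — about 7 s of compute); the coupling-recovery
check uses 20 replicate cohorts at 20 trials, and the null-calibration
check 200 replicate cohorts at 15-min/3-trial scale, chosen so each
replicate still yields >100 B grid samples per subject.

## Known limitations

- The plug-in MI bias grows with bin count and shrinks with B-segment
  duration; absolute MI values are therefore comparable only within a
  fixed binning and balanced design, not across studies.
- The cross-entropy pairs R-R bin i with IBI bin i although the two
  variables have different physical supports; it is a shape-difference
  index, not a calibrated divergence.
- The adaptive filter adopts any two-beat-consistent shift, so sustained
  sensor drift passes through; plausibility bounds catch only gross cases.
- WFDB annotation ingestion requires the optional `wfdb` package; without
  it, annotations must be exported to event-text (one timestamp per line).
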