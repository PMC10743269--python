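"""Synthetic neonatal beat/breath event generator with injectable bradycardia.

The generator emulates the statistical structure the downstream analysis
assumes, not waveform physiology:

* Breathing: inter-breath intervals follow a positive-truncated AR(1)
  process around ``mean_ibi`` (neonatal breaths run roughly 1-3 s).
* Respiratory sinus arrhythmia (RSA): each R-R interval is modulated by the
  fractional phase ``phi`` of the breath cycle in progress at the beat time,

      RR = mean_rr * (depth + m * a(D) * sin(2*pi*phi)) * (1 + eps)

  where ``m`` is the coupling depth (``coupling_nb`` outside bradycardia
  episodes, ``coupling_b`` inside), ``eps ~ N(0, rr_noise_cv)``, and
  ``a(D) = clip(D / mean_ibi, *rsa_amp_range)`` scales the RSA amplitude
  with the current breath duration ``D``.  The amplitude-period scaling is
  what makes the R-R *value* statistically dependent on the IBI *value*
  (slower breaths produce deeper RSA swings, a well-known feature of vagal
  modulation); phase modulation alone would leave the two histograms
  independent.
* Bradycardia: episode onsets arrive as a Poisson process at ``brady_rate``
  per hour; each episode raises the baseline term from 1 to ``brady_depth``
  for ``brady_beats`` beats.  The baseline shift is additive with respect to
  the RSA term, so the absolute RSA swing — and hence the width of histogram
  support — is the same inside and outside episodes; with the default
  ``brady_depth * mean_rr = 0.8 s`` every episode beat stays above the 0.6 s
  bradycardia threshold even at the deepest RSA dip of the default coupling.

Fixtures are serialised as event_text files (one timestamp per line) plus a
JSON manifest recording every parameter and per-subject seed, so a cohort is
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .events import EventSeries
from .segmentation import RR_THRESHOLD

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults give 10 subjects of 30 min each with per-subject mean heart
    rates in the 131-167 bpm band reported for preterm infants, breaths
    around 2 s, moderate RSA outside episodes (m = 0.3), suppressed RSA
    inside episodes (m = 0.05, the mechanism behind lower bradycardic MI),
    and ~10 bradycardia episodes of ~8 s per 30-min record.
    """

    n_subjects: int = 10
    duration: float = 1800.0
    mean_rr: float = 0.4
    mean_rr_range: tuple[float, float] = (0.36, 0.44)
    mean_ibi: float = 2.0
    ibi_cv: float = 0.2
    ibi_ar1: float = 0.4
    coupling_nb: float = 0.3
    coupling_b: float = 0.05
    brady_rate: float = 20.0
    brady_depth: float = 2.0
    brady_beats: int = 10
    rr_noise_cv: float = 0.02
    rsa_amp_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "mean_rr", "mean_ibi", "brady_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("coupling_nb", "coupling_b"):
            m = getattr(self, name)
            if not 0.0 <= m <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if self.brady_depth * self.mean_rr < RR_THRESHOLD:
            raise ValueError(
                "brady_depth * mean_rr must reach the 0.6 s bradycardia threshold"
            )
        if self.brady_rate < 0 or self.brady_beats < 2:
            raise ValueError("brady_rate must be >= 0 and brady_beats >= 2")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class SubjectFixture:
    """One subject's generated events plus the injected ground truth."""

    subject_id: str
    beats: EventSeries
    breaths: EventSeries
    true_spans: tuple[tuple[float, float], ...]
    coupling_nb: float
    coupling_b: float
    mean_rr: float
    seed: int

    @property
    def mean_heart_rate_bpm(self) -> float:
        rr = np.diff(self.beats.times)
        return float(60.0 / rr.mean())


def generate_breaths(cfg: SynthConfig, rng: np.random.Generator) -> EventSeries:
    """AR(1) inter-breath intervals, cumulated into breath event times.

    The process has stationary mean ``mean_ibi``, coefficient of variation
    ``ibi_cv`` and lag-1 autocorrelation ``ibi_ar1``; intervals are truncated
    below at 15% of the mean so event times stay strictly increasing.
    """
    n = int(np.ceil(cfg.duration / cfg.mean_ibi * 1.5)) + 10
    sigma = cfg.ibi_cv * cfg.mean_ibi
    if sigma == 0.0:
        intervals = np.full(n, cfg.mean_ibi)
    else:
        innov = rng.normal(0.0, sigma * np.sqrt(1.0 - cfg.ibi_ar1**2), size=n)
        x0 = rng.normal(0.0, sigma)
        dev, _ = lfilter([1.0], [1.0, -cfg.ibi_ar1], innov, zi=[cfg.ibi_ar1 * x0])
        intervals = cfg.mean_ibi + dev
        intervals = np.maximum(intervals, 0.15 * cfg.mean_ibi)
    times = np.concatenate(([0.0], np.cumsum(intervals)))
    # keep one breath beyond the nominal duration so beat phases are defined
    # over the whole record
    stop = np.searchsorted(times, cfg.duration + 2.0 * cfg.mean_ibi)
    return EventSeries(kind="breath", times=times[: max(stop, 2)])


def generate_beats(
    breaths: EventSeries, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[EventSeries, tuple[tuple[float, float], ...]]:
    """Sequentially generate beat times phase-locked to the breath cycle.

    Returns the beat event series and the injected episode spans, each span
    running from the start of its first lengthened interval to the end of its
    last (the same end-anchored convention the segmentation module uses).
    """
    bt = breaths.times
    t_end = min(cfg.duration, float(bt[-1]))
    rate_per_s = cfg.brady_rate / 3600.0
    if rate_per_s > 0:
        gaps = rng.exponential(1.0 / rate_per_s, size=max(int(t_end * rate_per_s * 3) + 10, 10))
        starts = np.cumsum(gaps)
        starts = starts[starts < t_end]
    else:
        starts = np.empty(0)

    amp_lo, amp_hi = cfg.rsa_amp_range
    times = [0.0]
    t = 0.0
    j = 0  # index of breath interval containing t
    ep_idx = 0
    beats_left = 0
    ep_start_t = 0.0
    spans: list[tuple[float, float]] = []
    while t < t_end:
        while j + 1 < bt.size - 1 and bt[j + 1] <= t:
            j += 1
        d = bt[j + 1] - bt[j]
        phi = (t - bt[j]) / d
        if beats_left == 0 and ep_idx < starts.size and t >= starts[ep_idx]:
            beats_left = cfg.brady_beats
            ep_start_t = t
            # skip any onset that would fall inside this episode
            while ep_idx < starts.size and starts[ep_idx] <= t:
                ep_idx += 1
        in_episode = beats_left > 0
        m = cfg.coupling_b if in_episode else cfg.coupling_nb
        depth = cfg.brady_depth if in_episode else 1.0
        a = min(max(d / cfg.mean_ibi, amp_lo), amp_hi)
        eps = rng.normal(0.0, cfg.rr_noise_cv) if cfg.rr_noise_cv > 0 else 0.0
        rr = cfg.mean_rr * (depth + m * a * np.sin(2.0 * np.pi * phi)) * (1.0 + eps)
        rr = max(rr, 0.05)
        t += rr
        times.append(t)
        if in_episode:
            beats_left -= 1
            if beats_left == 0:
                if spans and ep_start_t <= spans[-1][1] + 1e-12:
                    # back-to-back onsets form one physical episode
                    spans[-1] = (spans[-1][0], t)
                else:
                    spans.append((ep_start_t, t))
    beats = EventSeries(kind="beat", times=np.asarray(times), subject_id=breaths.subject_id)
    return beats, tuple(spans)


def generate_subject(
    cfg: SynthConfig, subject_id: str, seed: int, mean_rr: float | None = None
) -> SubjectFixture:
    """Generate one subject; ``mean_rr`` overrides the config value if given."""
    sub_cfg = cfg.replace(mean_rr=float(mean_rr)) if mean_rr is not None else cfg
    rng = np.random.default_rng(seed)
    breaths = generate_breaths(sub_cfg, rng)
    beats, spans = generate_beats(breaths, sub_cfg, rng)
    return SubjectFixture(
        subject_id=subject_id,
        beats=EventSeries("beat", beats.times, subject_id),
        breaths=EventSeries("breath", breaths.times, subject_id),
        true_spans=spans,
        coupling_nb=sub_cfg.coupling_nb,
        coupling_b=sub_cfg.coupling_b,
        mean_rr=sub_cfg.mean_rr,
        seed=seed,
    )


def generate_cohort(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> list[SubjectFixture]:
    """Generate ``cfg.n_subjects`` fixtures; optionally serialise them.

    Per-subject mean R-R values are drawn uniformly from ``mean_rr_range``
    (Table-1-like neonatal heart rates); per-subject generator seeds derive
    deterministically from ``cfg.seed``, so the same config yields
    byte-identical fixture files.
    """
    cohort_rng = np.random.default_rng([cfg.seed, 0x5EED])
    lo, hi = cfg.mean_rr_range
    mean_rrs = cohort_rng.uniform(lo, hi, size=cfg.n_subjects)
    fixtures = [
        generate_subject(
            cfg,
            subject_id=f"s{i + 1:02d}",
            seed=int(np.random.SeedSequence([cfg.seed, i + 1]).generate_state(1)[0] % (2**31)),
            mean_rr=mean_rrs[i],
        )
        for i in range(cfg.n_subjects)
    ]
    if out_dir is not None:
        write_cohort(fixtures, cfg, out_dir)
    return fixtures


def write_cohort(
    fixtures: list[SubjectFixture], cfg: SynthConfig, out_dir: str | Path
) -> Path:
    """Write event_text files, ground-truth spans and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "subjects": []}
    for fx in fixtures:
        beats_file = out / f"{fx.subject_id}_beats.txt"
        breaths_file = out / f"{fx.subject_id}_breaths.txt"
        spans_file = out / f"{fx.subject_id}_true_spans.csv"
        _write_event_text(beats_file, fx.beats.times)
        _write_event_text(breaths_file, fx.breaths.times)
        with open(spans_file, "w") as fh:
            fh.write("t_begin,t_end\n")
            for b, e in fx.true_spans:
                fh.write(f"{b:.9f},{e:.9f}\n")
        manifest["subjects"].append(
            {
                "subject_id": fx.subject_id,
                "seed": fx.seed,
                "mean_rr": fx.mean_rr,
                "coupling_nb": fx.coupling_nb,
                "coupling_b": fx.coupling_b,
                "n_beats": len(fx.beats),
                "n_breaths": len(fx.breaths),
                "n_episodes": len(fx.true_spans),
                "beats_file": beats_file.name,
                "breaths_file": breaths_file.name,
                "spans_file": spans_file.name,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("wrote %d subject fixtures to %s", len(fixtures), out)
    return out / "manifest.json"


def _write_event_text(path: Path, times: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# event times in seconds, one per line\n")
        for t in times:
            fh.write(f"{t:.9f}\n")
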