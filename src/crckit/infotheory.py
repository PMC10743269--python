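"""Histogram-based information-theory measures, in bits.

Value arrays are binned into empirical probability distributions and the
plug-in estimators are evaluated directly on the bin probabilities:

    H(X)      = - sum_i p(x_i) log2 p(x_i)                 (Shannon entropy)
    cH(X,Y)   = - sum_i p(x_i) log2 p(y_i)                 (cross-entropy)
    MI(X,Y)   = H(X) + H(Y) - H(X,Y)                       (mutual information)

with the convention 0*log2(0) = 0.  The cross-entropy pairs the i-th R-R bin
with the i-th IBI bin (a by-index shared alphabet), so both distributions
must use the same number of bins.  Bin edges are equal-width over the pooled
range of both conditions of a subject-trial, so that condition differences
reflect distribution shape rather than support.

The plug-in estimators carry a positive finite-sample bias (no Miller-Madow
or coverage correction is applied); comparisons are therefore always made
between conditions with *equal* sample counts and *shared* edges, which is
what the balancing step guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlphabetError,
    DegenerateDataError,
    OutOfRangeError,
    PairingError,
)

DEFAULT_N_BINS = 16
#: Jeffreys pseudo-count used to smooth q in the cross-entropy when an
#: infinite term would otherwise appear
SMOOTHING_ALPHA = 0.5

#: metric column names used throughout the trial protocol
METRIC_NAMES = ("H_rr", "H_ibi", "MI", "cH_rr_ibi", "cH_ibi_rr")


@dataclass(frozen=True)
class BinningSpec:
    """Shared bin edges for the R-R and IBI variables of one subject-trial."""

    edges_rr: np.ndarray
    edges_ibi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("edges_rr", "edges_ibi"):
            edges = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, edges)
            if edges.size < 3 or np.any(np.diff(edges) <= 0):
                raise ValueError(f"{name} must be strictly increasing with >= 2 bins")
        if self.edges_rr.size != self.edges_ibi.size:
            raise AlphabetError("RR and IBI alphabets must have equal bin counts")

    @property
    def n_bins(self) -> int:
        return int(self.edges_rr.size - 1)


@dataclass(frozen=True)
class ProbDist:
    """Binned probability vector plus the sample count behind it."""

    p: np.ndarray
    n_samples: int
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def n_bins(self) -> int:
        return int(self.p.size)


@dataclass(frozen=True)
class JointProbDist:
    """Joint (rr-bin x ibi-bin) probability matrix."""

    p_xy: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p_xy, dtype=float)
        object.__setattr__(self, "p_xy", p)
        if p.ndim != 2:
            raise ValueError("joint distribution must be a 2-D matrix")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("joint probabilities must be non-negative and sum to 1")

    @property
    def marginal_x(self) -> ProbDist:
        return ProbDist(self.p_xy.sum(axis=1), self.n_samples)

    @property
    def marginal_y(self) -> ProbDist:
        return ProbDist(self.p_xy.sum(axis=0), self.n_samples)


def make_binning(rr_all, ibi_all, n_bins: int = DEFAULT_N_BINS) -> BinningSpec:
    """Equal-width edges per variable over the pooled B+NB range of a trial."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = []
    for name, values in (("RR", rr_all), ("IBI", ibi_all)):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise DegenerateDataError(f"{name}: no values to bin")
        lo, hi = float(values.min()), float(values.max())
        if not hi > lo:
            raise DegenerateDataError(f"{name}: all values identical ({lo})")
        edges.append(np.linspace(lo, hi, n_bins + 1))
    return BinningSpec(edges_rr=edges[0], edges_ibi=edges[1])


def hist_prob(values, edges) -> ProbDist:
    """Histogram probabilities: left-closed right-open bins, last bin closed."""
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if values.size == 0:
        raise DegenerateDataError("cannot build a distribution from no values")
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise OutOfRangeError(
            f"values span [{values.min()}, {values.max()}] outside edges "
            f"[{edges[0]}, {edges[-1]}]"
        )
    counts, _ = np.histogram(values, bins=edges)
    return ProbDist(p=counts / counts.sum(), n_samples=int(values.size), counts=counts)


def entropy(d: ProbDist) -> float:
    """Shannon entropy in bits with the 0*log2(0)=0 convention."""
    p = d.p[d.p > 0]
    return float(-(p * np.log2(p)).sum())


def _entropy_matrix(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cross_entropy(p: ProbDist, q: ProbDist, alpha: float = SMOOTHING_ALPHA) -> float:
    """Cross-entropy -sum p_i log2 q_i over the by-index shared alphabet.

    When q has an empty bin at an index where p is positive, the term would be
    infinite; only in that case q is replaced by its Jeffreys-smoothed version
    (add ``alpha`` to every bin count, renormalise).  Otherwise q is used as
    is, so cross_entropy(p, p) equals entropy(p) whenever p has no empty bins.
    """
    if p.n_bins != q.n_bins:
        raise AlphabetError(
            f"distributions have {p.n_bins} vs {q.n_bins} bins; "
            "cross-entropy needs a common alphabet"
        )
    q_p = q.p
    if np.any((p.p > 0) & (q_p == 0)):
        counts = q.counts if q.counts is not None else q.p * q.n_samples
        smoothed = np.asarray(counts, dtype=float) + alpha
        q_p = smoothed / smoothed.sum()
    mask = p.p > 0
    return float(-(p.p[mask] * np.log2(q_p[mask])).sum())


def joint_hist_prob(rr_values, ibi_values, spec: BinningSpec) -> JointProbDist:
    """2-D histogram probabilities on the trial's shared edges."""
    rr_values = np.asarray(rr_values, dtype=float)
    ibi_values = np.asarray(ibi_values, dtype=float)
    if rr_values.size != ibi_values.size:
        raise PairingError(
            f"paired samples required: {rr_values.size} RR vs {ibi_values.size} IBI"
        )
    for vals, edges, name in (
        (rr_values, spec.edges_rr, "RR"),
        (ibi_values, spec.edges_ibi, "IBI"),
    ):
        if vals.min() < edges[0] or vals.max() > edges[-1]:
            raise OutOfRangeError(f"{name} values outside the binning range")
    counts, _, _ = np.histogram2d(
        rr_values, ibi_values, bins=[spec.edges_rr, spec.edges_ibi]
    )
    return JointProbDist(p_xy=counts / counts.sum(), n_samples=int(rr_values.size))


def joint_entropy(j: JointProbDist) -> float:
    return _entropy_matrix(j.p_xy.ravel())


def mutual_information(j: JointProbDist) -> float:
    """Plug-in MI = H(X) + H(Y) - H(X,Y), in bits (no bias correction)."""
    return entropy(j.marginal_x) + entropy(j.marginal_y) - joint_entropy(j)


def condition_metrics(
    rr_values, ibi_values, spec: BinningSpec, alpha: float = SMOOTHING_ALPHA
) -> dict[str, float]:
    """All five trial metrics for one condition's paired samples."""
    p_rr = hist_prob(rr_values, spec.edges_rr)
    p_ibi = hist_prob(ibi_values, spec.edges_ibi)
    joint = joint_hist_prob(rr_values, ibi_values, spec)
    return {
        "H_rr": entropy(p_rr),
        "H_ibi": entropy(p_ibi),
        "MI": mutual_information(joint),
        "cH_rr_ibi": cross_entropy(p_rr, p_ibi, alpha),
        "cH_ibi_rr": cross_entropy(p_ibi, p_rr, alpha),
    }
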