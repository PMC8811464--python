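"""Spike-train validation statistics and distribution comparison.

Three measures of increasing order characterize network activity:

* **FR** — average firing rate, n_sp / T;
* **CV** — coefficient of variation of the inter-spike intervals,
  the sample standard deviation (n-1 denominator) of the ISIs over
  their mean (0 for a clock, ~1 for Poisson firing);
* **CC** — pairwise Pearson correlation coefficient of spike trains
  binned at 2 ms, pooled over neuron pairs within a population.

Two simulations are compared at the level of the *distributions* of
these per-neuron (or per-pair) measures, after discarding the initial
1,000 ms startup transient.  The comparison reports the two-sample
Kolmogorov-Smirnov statistic and a histogram overlap coefficient;
the pass criterion (KS <= 0.1 by default) is this package's own
operational threshold for "statistically equivalent".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = [
    "SpikeTrainSet",
    "BinnedTrains",
    "firing_rate",
    "cv_isi",
    "pearson_cc",
    "cc_matrix",
    "compare_distributions",
    "population_measures",
    "validation_report",
]

DEFAULT_TRANSIENT_MS = 1000.0
DEFAULT_BIN_MS = 2.0
DEFAULT_KS_THRESHOLD = 0.1


@dataclass
class SpikeTrainSet:
    """Per-neuron ordered spike times (ms) within an observation window."""

    trains: list                  # list of float arrays, ms
    t0: float
    t_end: float
    labels: np.ndarray | None = None  # population index per neuron

    def __post_init__(self) -> None:
        for tr in self.trains:
            if len(tr) and (tr[0] < self.t0 - 1e-9 or tr[-1] > self.t_end + 1e-9):
                raise ValueError("spike times outside the observation window")

    @property
    def T(self) -> float:
        return self.t_end - self.t0

    @classmethod
    def from_record(cls, record, t0: float = DEFAULT_TRANSIENT_MS,
                    t_end: float | None = None) -> "SpikeTrainSet":
        """Build from an engine SpikeRecord, cutting the transient."""
        times = record.times_ms
        if t_end is None:
            t_end = record.dt * 0 + float(times.max() if len(times) else t0)
        keep = (times >= t0) & (times <= t_end)
        times = times[keep]
        gids = record.gids[keep]
        order = np.argsort(gids, kind="stable")
        gids, times = gids[order], times[order]
        bounds = np.searchsorted(gids, np.arange(record.n_neurons + 1))
        trains = [times[bounds[i]:bounds[i + 1]] for i in range(record.n_neurons)]
        labels = None
        if record.pop_ranges:
            labels = np.empty(record.n_neurons, dtype=np.int64)
            for p, (name, lo, hi) in enumerate(record.pop_ranges):
                labels[lo:hi] = p
        return cls(trains=trains, t0=t0, t_end=t_end, labels=labels)


@dataclass
class BinnedTrains:
    """Matrix of spike counts per (neuron, bin)."""

    counts: np.ndarray
    bin_ms: float

    @classmethod
    def from_trains(cls, ts: SpikeTrainSet, bin_ms: float = DEFAULT_BIN_MS,
                    subset: np.ndarray | None = None) -> "BinnedTrains":
        n_bins = int(np.floor(ts.T / bin_ms))
        edges = ts.t0 + bin_ms * np.arange(n_bins + 1)
        idx = range(len(ts.trains)) if subset is None else subset
        counts = np.stack([
            np.histogram(ts.trains[i], bins=edges)[0] for i in idx
        ]).astype(np.int64)
        return cls(counts=counts, bin_ms=bin_ms)


# ---------------------------------------------------------------------------
# the three measures
# ---------------------------------------------------------------------------

def firing_rate(train: np.ndarray, T_ms: float) -> float:
    """Average rate n_sp / T in spikes/s over a window of T_ms ms."""
    if T_ms <= 0:
        raise ValueError("window length must be > 0")
    return len(train) / (T_ms / 1000.0)


def cv_isi(train: np.ndarray) -> float:
    """Coefficient of variation of the inter-spike intervals.

    Sample standard deviation (n-1 denominator) of the ISIs over the
    mean ISI.  Requires at least 3 spikes (2 intervals); returns NaN
    otherwise, and such neurons are excluded from distributions.
    """
    if len(train) < 3:
        return float("nan")
    isi = np.diff(np.asarray(train, dtype=np.float64))
    m = isi.mean()
    if m <= 0:
        return float("nan")
    return float(np.sqrt(np.sum((isi - m) ** 2) / (len(isi) - 1)) / m)


def pearson_cc(b_i: np.ndarray, b_j: np.ndarray) -> float:
    """Pearson correlation of two binned spike trains, with the
    symmetric normalization sqrt(<bi-mi,bi-mi><bj-mj,bj-mj>).

    NaN if either train has zero variance.
    """
    x = np.asarray(b_i, dtype=np.float64) - np.mean(b_i)
    y = np.asarray(b_j, dtype=np.float64) - np.mean(b_j)
    den = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if den == 0:
        return float("nan")
    return float(np.dot(x, y) / den)


def cc_matrix(binned: BinnedTrains):
    """N x N symmetric Pearson matrix with unit diagonal.

    Returns (matrix, valid_mask): rows with zero variance are flagged
    invalid and carry NaN off-diagonals.
    """
    counts = binned.counts.astype(np.float64)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trains")
    var = counts.var(axis=1)
    valid = var > 0
    C = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(counts[valid])
        ii = np.nonzero(valid)[0]
        C[np.ix_(ii, ii)] = sub
    np.fill_diagonal(C, 1.0)
    return C, valid


def pooled_offdiag(C: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(C.shape[0], k=1)
    vals = C[iu]
    return vals[np.isfinite(vals)]


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

def compare_distributions(sample_a, sample_b,
                          ks_threshold: float = DEFAULT_KS_THRESHOLD,
                          n_hist_bins: int = 50) -> dict:
    """Two-sample KS statistic + histogram overlap coefficient.

    ``pass`` is True iff KS <= ks_threshold (an operational criterion;
    no particular equivalence test is canonical for this comparison).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    ks = float(_st.ks_2samp(a, b, method="asymp").statistic)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        overlap = 1.0
    else:
        edges = np.linspace(lo, hi, n_hist_bins + 1)
        pa, _ = np.histogram(a, bins=edges, density=False)
        pb, _ = np.histogram(b, bins=edges, density=False)
        overlap = float(np.minimum(pa / len(a), pb / len(b)).sum())
    return {"ks": ks, "overlap": overlap, "pass": ks <= ks_threshold}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def population_measures(record, t0: float = DEFAULT_TRANSIENT_MS,
                        t_end: float | None = None,
                        bin_ms: float = DEFAULT_BIN_MS,
                        cc_subsample: int = 100, seed: int = 0) -> dict:
    """FR/CV/CC distributions per population from one spike record.

    All measures are computed strictly after the transient cut.  CC is
    evaluated on a deterministic subsample of neurons per population
    (the pair count would otherwise be quadratic in the population
    size); zero-variance trains and neurons with < 3 spikes are
    excluded, with exclusion counts reported.
    """
    if t_end is None:
        t_end = float(record.steps.max() * record.dt) if len(record) else t0 + 1.0
    ts = SpikeTrainSet.from_record(record, t0=t0, t_end=t_end)
    out = {}
    rng = np.random.default_rng(seed)
    for p, (name, lo, hi) in enumerate(record.pop_ranges):
        trains = ts.trains[lo:hi]
        fr = np.array([firing_rate(tr, ts.T) for tr in trains])
        cv = np.array([cv_isi(tr) for tr in trains])
        n_cv_excluded = int(np.sum(~np.isfinite(cv)))
        size = hi - lo
        sub = lo + (rng.permutation(size)[:min(cc_subsample, size)]
                    if size > cc_subsample else np.arange(size))
        binned = BinnedTrains.from_trains(ts, bin_ms=bin_ms, subset=np.sort(sub))
        if binned.counts.shape[0] >= 2:
            C, valid = cc_matrix(binned)
            cc = pooled_offdiag(C)
            n_cc_excluded = int((~valid).sum())
        else:
            cc, n_cc_excluded = np.array([]), 0
        out[name] = {
            "fr": fr, "cv": cv[np.isfinite(cv)], "cc": cc,
            "n_neurons": size,
            "n_cv_excluded": n_cv_excluded,
            "n_cc_excluded": n_cc_excluded,
        }
    return out


def validation_report(measures_a: dict, measures_b: dict,
                      ks_threshold: float = DEFAULT_KS_THRESHOLD) -> dict:
    """Compare the pooled FR/CV/CC distributions of two simulations."""
    report = {}
    for key in ("fr", "cv", "cc"):
        a = np.concatenate([m[key] for m in measures_a.values()])
        b = np.concatenate([m[key] for m in measures_b.values()])
        report[key] = compare_distributions(a, b, ks_threshold=ks_threshold)
    report["pass"] = all(report[k]["pass"] for k in ("fr", "cv", "cc"))
    return report
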