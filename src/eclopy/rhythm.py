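"""Population eclosion rhythmicity: correlogram, rhythmicity index, period.

A population eclosion assay counts, in uniform time bins, the number of
adult flies emerging from a developing culture held in constant darkness.
Rhythmicity is quantified from the biased sample autocorrelogram of the
binned record; the rhythmicity index (RI) is the correlogram coefficient at
the second non-zero-lag peak (the "third peak" when lag 0 is counted), and
the dominant period is the lag of the first non-zero-lag peak.

Classification follows the standard cutoffs for this statistic: RI > 0.3
rhythmic, 0.1 <= RI <= 0.3 weakly rhythmic, RI < 0.1 (or an obviously
aperiodic correlogram, i.e. fewer than two peaks) arrhythmic.

A complementary qualitative criterion, useful for short records that cannot
support a correlogram, is that rhythmic records invariably contain valleys
— stretches when few flies emerge — spaced by roughly one circadian period
(:func:`valley_criterion`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "EventRecord",
    "Correlogram",
    "RhythmResult",
    "bin_events",
    "autocorrelogram",
    "rhythm_analyze",
    "valley_criterion",
    "read_events_csv",
    "write_events_csv",
]

RI_RHYTHMIC = 0.3
RI_ARRHYTHMIC = 0.1


@dataclass
class EventRecord:
    """Binned emergence counts over uniform, half-open time bins."""

    bin_start_t_h: np.ndarray
    counts: np.ndarray
    bin_h: float
    dd_start_t_h: float = 0.0
    prior_ld_phase_h: float = 12.0  # hours after lights-on at DD start

    def __post_init__(self) -> None:
        self.bin_start_t_h = np.asarray(self.bin_start_t_h, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_start_t_h.shape != self.counts.shape:
            raise ValueError("bin starts and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.bin_start_t_h) > 1:
            steps = np.diff(self.bin_start_t_h)
            if not np.allclose(steps, self.bin_h, atol=1e-9):
                raise ValueError("bins must be uniform with width bin_h")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def span_h(self) -> float:
        return self.n_bins * self.bin_h

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class Correlogram:
    """Autocorrelation coefficients at lags 0..max_lag in bin steps."""

    lags_h: np.ndarray
    coefficients: np.ndarray
    n_bins: int
    bin_h: float

    def __post_init__(self) -> None:
        self.lags_h = np.asarray(self.lags_h, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if abs(self.coefficients[0] - 1.0) > 1e-9:
            raise ValueError("coefficient at lag 0 must be 1")
        if np.any(np.abs(self.coefficients) > 1 + 1e-9):
            raise ValueError("autocorrelation coefficients must lie in [-1, 1]")


@dataclass
class RhythmResult:
    ri: float
    period_h: float | None
    classification: str  # rhythmic | weakly_rhythmic | arrhythmic
    aperiodic_flag: bool = False
    peak_lags_h: list = field(default_factory=list)


def bin_events(
    emergence_times_h, bin_h: float, t_start: float, t_end: float, **metadata
) -> EventRecord:
    """Bin event times into half-open bins ``[b, b + bin_h)`` covering
    ``[t_start, t_end)``; events outside the window are dropped."""
    if bin_h <= 0:
        raise ValueError("bin_h must be positive")
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    times = np.asarray(emergence_times_h, dtype=float)
    n_bins = int(np.ceil((t_end - t_start) / bin_h))
    edges = t_start + bin_h * np.arange(n_bins + 1)
    in_window = (times >= t_start) & (times < t_end)
    counts, _ = np.histogram(times[in_window], bins=edges)
    return EventRecord(edges[:-1], counts.astype(int), bin_h, **metadata)


def autocorrelogram(record: EventRecord, max_lag_h: float) -> Correlogram:
    """Biased (divide-by-total-variance, non-circular) sample autocorrelation.

    ``r(l) = sum_t (x_t - xbar)(x_{t+l} - xbar) / sum_t (x_t - xbar)^2``

    The biased estimator's decaying peak envelope is what the RI convention
    assumes; the unbiased estimator would inflate coefficients at long lags.
    """
    x = record.counts.astype(float)
    n = x.size
    xc = x - x.mean()
    denom = float(np.sum(xc * xc))
    if denom == 0:
        raise ValueError("degenerate record: zero variance, correlogram undefined")
    max_lag_bins = int(np.floor(max_lag_h / record.bin_h))
    if max_lag_bins > n // 2:
        raise ValueError(
            f"max_lag_h={max_lag_h} exceeds half the record span "
            f"({n * record.bin_h / 2} h)"
        )
    lags = np.arange(max_lag_bins + 1)
    coeffs = np.array([np.sum(xc[: n - l] * xc[l:]) / denom for l in lags])
    return Correlogram(lags * record.bin_h, coeffs, n, record.bin_h)


def _smooth3(y: np.ndarray) -> np.ndarray:
    # centered 3-point moving average, window truncated at the ends
    kernel = np.ones(3)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def rhythm_analyze(
    correlogram: Correlogram,
    prominence: float = 0.02,
    ri_peak_index: int = 1,
    noise_z: float = 2.0,
) -> RhythmResult:
    """Extract period, RI and a three-way classification from a correlogram.

    Peaks are local maxima of the 3-lag-smoothed correlogram (lag 0
    excluded) whose prominence exceeds both ``prominence`` and a noise floor
    of ``noise_z / sqrt(N)`` — the sampling fluctuation scale of the
    autocorrelation of an N-bin uncorrelated record, without which the
    first-peak period estimate locks onto counting-noise lobes (set
    ``noise_z=0`` to disable).  The period is the lag of the first peak; RI
    is the raw coefficient at peak ``ri_peak_index`` (default 1, i.e. the
    second non-zero-lag peak, near twice the period — the "third peak"
    counting lag 0).  Set ``ri_peak_index=0`` to read RI at the first peak
    instead.  Records with fewer than two peaks are flagged aperiodic and
    classified arrhythmic.
    """
    smoothed = _smooth3(correlogram.coefficients)
    effective = max(prominence, noise_z / np.sqrt(correlogram.n_bins))
    peaks, _ = find_peaks(smoothed, prominence=effective)
    peaks = peaks[peaks > 0]
    # refine to the raw-coefficient maximum within the smoothing window:
    # smoothing can displace a sharp correlogram spike by one lag, and both
    # the period and the RI are read off the raw correlogram
    raw = correlogram.coefficients
    refined = []
    for p in peaks:
        lo, hi = max(1, p - 1), min(len(raw) - 1, p + 1)
        refined.append(lo + int(np.argmax(raw[lo : hi + 1])))
    peaks = np.unique(refined).astype(int)
    peak_lags = correlogram.lags_h[peaks].tolist()
    if len(peaks) < 2:
        return RhythmResult(
            ri=0.0, period_h=peak_lags[0] if peak_lags else None,
            classification="arrhythmic", aperiodic_flag=True,
            peak_lags_h=peak_lags,
        )
    period_h = float(correlogram.lags_h[peaks[0]])
    ri = float(correlogram.coefficients[peaks[min(ri_peak_index, len(peaks) - 1)]])
    if ri > RI_RHYTHMIC:
        cls = "rhythmic"
    elif ri >= RI_ARRHYTHMIC:
        cls = "weakly_rhythmic"
    else:
        cls = "arrhythmic"
    return RhythmResult(ri=ri, period_h=period_h, classification=cls,
                        aperiodic_flag=False, peak_lags_h=peak_lags)


def valley_criterion(
    record: EventRecord, expected_period_h: float, tol_h: float = 4.0
) -> bool:
    """True iff the record shows >= 2 low-emergence valleys spaced by about
    one expected period — the qualitative rhythmicity criterion for records
    too short for a correlogram.

    Counts are smoothed with a 3-h moving average; valleys are maximal runs
    at or below the 20th percentile of the smoothed values over the nonzero
    span of the record (at-or-below, because a strongly gated record spends
    well over a fifth of its span at exactly zero).  The criterion asks that
    valleys recur *periodically*: the median spacing between consecutive
    valley centers must lie within ``expected_period_h +- tol_h``.  An
    irregular record with many shallow lulls has a much shorter typical
    spacing and fails.
    """
    counts = record.counts.astype(float)
    if counts.sum() == 0:
        warnings.warn("all-zero record: valley criterion vacuously false")
        return False
    w = max(1, int(round(3.0 / record.bin_h)))
    smoothed = pd.Series(counts).rolling(w, center=True, min_periods=1).mean().to_numpy()
    nz = np.nonzero(counts)[0]
    lo, hi = nz[0], nz[-1]
    span = smoothed[lo : hi + 1]
    cutoff = np.percentile(span, 20)
    low = span <= cutoff
    centers = []
    i = 0
    while i < low.size:
        if low[i]:
            j = i
            while j + 1 < low.size and low[j + 1]:
                j += 1
            centers.append(record.bin_start_t_h[lo + (i + j) // 2])
            i = j + 1
        else:
            i += 1
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 2:
        return False
    spacing = float(np.median(np.diff(centers)))
    return abs(spacing - expected_period_h) <= tol_h


# -- CSV dialects ------------------------------------------------------------

def write_events_csv(record: EventRecord, path) -> None:
    pd.DataFrame(
        {"bin_start_h": record.bin_start_t_h, "count": record.counts}
    ).to_csv(path, index=False)


def read_events_csv(path, bin_h: float | None = None) -> EventRecord:
    """Read an event CSV in either the binned (``bin_start_h,count``) or the
    raw (``t_h``) dialect, auto-detected from the header.  Raw event times
    are binned at ``bin_h`` (default 0.5 h) over their own span."""
    df = pd.read_csv(path)
    cols = {c.strip().lower() for c in df.columns}
    if {"bin_start_h", "count"} <= cols:
        starts = df["bin_start_h"].to_numpy(dtype=float)
        width = float(starts[1] - starts[0]) if len(starts) > 1 else (bin_h or 0.5)
        return EventRecord(starts, df["count"].to_numpy(), width)
    if "t_h" in cols:
        times = df["t_h"].to_numpy(dtype=float)
        width = bin_h or 0.5
        t0 = np.floor(times.min() / width) * width
        t1 = np.ceil((times.max() + width) / width) * width
        return bin_events(times, width, t0, t1)
    raise ValueError(
        f"unrecognized event CSV header {sorted(cols)}; "
        "expected columns (bin_start_h, count) or (t_h)"
    )
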