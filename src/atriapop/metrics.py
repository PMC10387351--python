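"""Rhythm statistics for optical AP trains and heart recordings.

Implements the platform's quantification toolbox: baseline normalization
of optical traces, peak-to-peak interval extraction, the arrhythmia index
(AI), the two-sample Kolmogorov–Smirnov distance (KS-D), the scaled median
absolute deviation (MAD) and its normalized form (nMAD), and M-mode
derived intervals (systolic/diastolic interval, heart period, fractional
shortening).

The arrhythmia index is the coefficient of variation of peak-to-peak
intervals expressed in percent; trains with AI > 20 are classified as
irregular.  MAD uses the scale constant k = 1.4826 (the reciprocal of the
0.75 quantile of the standard normal), which makes it a consistent
estimator of the standard deviation for normal data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats


@dataclass(frozen=True)
class MetricsConfig:
    """Constants of the rhythm metrics."""

    mad_k: float = 1.4826           # normal-consistency constant
    ai_threshold: float = 20.0      # AI above this -> "irregular"
    rate_tolerance: float = 0.10    # beat-rate matching band (fraction)
    min_prominence: float = 0.20    # peak prominence (fraction of amplitude)
    refractory_ms: float = 100.0    # minimum peak separation
    detrend_degree: int = 1         # polynomial degree for drift removal

    def __post_init__(self) -> None:
        if self.mad_k <= 0 or self.ai_threshold <= 0:
            raise ValueError("mad_k and ai_threshold must be positive")
        if not (0 < self.rate_tolerance < 1):
            raise ValueError("rate_tolerance must lie in (0, 1)")


@dataclass(frozen=True)
class OpticalTrace:
    """Uniformly sampled fluorescence recording (arbitrary units)."""

    values: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 2:
            raise ValueError("values must be a 1-D array with >= 2 samples")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        object.__setattr__(self, "values", v)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(len(self.values)) * (1000.0 / self.rate_hz)


@dataclass(frozen=True)
class IntervalSeries:
    """Ordered beat-to-beat (peak-to-peak) intervals in ms."""

    intervals_ms: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals_ms, dtype=float)
        if len(iv) and (iv <= 0).any():
            raise ValueError("all intervals must be positive")
        object.__setattr__(self, "intervals_ms", iv)

    def __len__(self) -> int:
        return len(self.intervals_ms)


def normalize(trace: OpticalTrace, config: MetricsConfig | None = None) -> OpticalTrace:
    """Baseline-corrected, amplitude-normalized copy of an optical trace.

    A low-order polynomial (default linear, covering photobleaching drift)
    is subtracted, then the trace is min-max scaled to [0, 1]; the result
    is invariant under affine transforms a*F + b with a > 0.
    """
    if config is None:
        config = MetricsConfig()
    v = trace.values
    if np.ptp(v) == 0:
        raise ValueError("cannot normalize a constant trace")
    x = np.arange(len(v), dtype=float)
    # fit the drift on the diastolic (lower-envelope) samples so the beats
    # themselves do not bias the trend estimate; the mask is refined on the
    # fit residuals so baseline samples are selected uniformly in time
    mask = np.ones(len(v), dtype=bool)
    coeffs = np.polyfit(x, v, config.detrend_degree)
    for _ in range(3):
        resid = v - np.polyval(coeffs, x)
        mask = resid <= np.percentile(resid, 30)
        if mask.sum() < config.detrend_degree + 1:
            break
        coeffs = np.polyfit(x[mask], v[mask], config.detrend_degree)
    detrended = v - np.polyval(coeffs, x)
    lo, hi = detrended.min(), detrended.max()
    return OpticalTrace((detrended - lo) / (hi - lo), trace.rate_hz)


def peak_intervals(
    trace: OpticalTrace, config: MetricsConfig | None = None
) -> tuple[IntervalSeries, float]:
    """Peak-to-peak intervals and beat rate (Hz) of an optical train.

    Peaks are found on the normalized trace with a minimum prominence and
    refractory separation; the rate is (n_peaks - 1) / span.  Fewer than
    two peaks yield an empty series with a warning.
    """
    if config is None:
        config = MetricsConfig()
    norm = normalize(trace, config)
    dt_ms = 1000.0 / trace.rate_hz
    distance = max(1, int(round(config.refractory_ms / dt_ms)))
    # noise-aware prominence floor: on a trace that is noise all the way
    # down, rescaling to [0, 1] would otherwise manufacture "beats"
    diffs = np.diff(norm.values)
    noise_sd = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2)
    prominence = max(config.min_prominence, 8.0 * noise_sd)
    peaks, _ = signal.find_peaks(
        norm.values, prominence=prominence, distance=distance
    )
    if len(peaks) < 2:
        warnings.warn("fewer than two peaks detected; empty interval series")
        return IntervalSeries(np.array([])), float("nan")
    t_peaks = peaks * dt_ms
    intervals = np.diff(t_peaks)
    span_s = (t_peaks[-1] - t_peaks[0]) / 1000.0
    rate = (len(peaks) - 1) / span_s
    return IntervalSeries(intervals), rate


def arrhythmia_index(
    intervals: IntervalSeries | np.ndarray, config: MetricsConfig | None = None
) -> float:
    """Arrhythmia index: 100 x (sample SD / mean) of beat-to-beat intervals.

    Dimensionless and invariant under time-unit rescaling.  Undefined for
    fewer than two intervals (NaN with a warning).
    """
    iv = intervals.intervals_ms if isinstance(intervals, IntervalSeries) else np.asarray(intervals, float)
    if len(iv) < 2:
        warnings.warn("arrhythmia index undefined for fewer than 2 intervals")
        return float("nan")
    return 100.0 * float(np.std(iv, ddof=1) / np.mean(iv))


def classify_irregular(ai: float, config: MetricsConfig | None = None) -> bool:
    """True when the AI exceeds the irregularity threshold (default 20)."""
    if config is None:
        config = MetricsConfig()
    return bool(ai > config.ai_threshold)


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov–Smirnov distance: the supremum absolute
    difference between empirical CDFs, in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def mad(values, config: MetricsConfig | None = None) -> float:
    """Scaled median absolute deviation: k * median(|X - median(X)|)."""
    if config is None:
        config = MetricsConfig()
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("mad of an empty sample is undefined")
    return config.mad_k * float(np.median(np.abs(x - np.median(x))))


def nmad(heart_periods, config: MetricsConfig | None = None) -> float:
    """Normalized MAD: the scaled MAD divided by the median heart period."""
    x = np.asarray(heart_periods, dtype=float)
    med = float(np.median(x)) if len(x) else 0.0
    if med <= 0:
        raise ValueError("median heart period must be positive")
    return mad(x, config) / med


def rates_comparable(
    rate_a_hz: float, rate_b_hz: float, config: MetricsConfig | None = None
) -> bool:
    """Guard for cross-condition APD comparisons: beat rates must agree
    within the configured tolerance (default +/-10%)."""
    if config is None:
        config = MetricsConfig()
    if rate_a_hz <= 0 or rate_b_hz <= 0:
        return False
    return abs(rate_a_hz - rate_b_hz) / rate_a_hz <= config.rate_tolerance


def mmode_intervals(
    t_ms: np.ndarray, diameter: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Per-beat intervals from an M-mode-derived diameter signal.

    The contracted phase is where the diameter is below the midpoint of
    its range.  For each beat: SI = contracted-phase duration, DI =
    following relaxed-phase duration, HP = SI + DI (onset to onset), and
    fractional shortening = (diastolic - systolic diameter) / diastolic.

    Returns the per-beat table and a summary dict; no contractions yield
    an empty table with a warning.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    d = np.asarray(diameter, dtype=float)
    if np.ptp(d) == 0:
        warnings.warn("no contractions found in diameter signal")
        return pd.DataFrame(columns=["SI_ms", "DI_ms", "HP_ms"]), {}
    dia = float(np.percentile(d, 95))
    sys_ = float(np.percentile(d, 5))
    mid = 0.5 * (dia + sys_)
    contracted = d < mid
    edges = np.diff(contracted.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if len(onsets) < 2:
        warnings.warn("no contractions found in diameter signal")
        return pd.DataFrame(columns=["SI_ms", "DI_ms", "HP_ms"]), {}
    rows = []
    for k in range(len(onsets) - 1):
        on = onsets[k]
        nxt = onsets[k + 1]
        offs = offsets[(offsets > on) & (offsets <= nxt)]
        if len(offs) == 0:
            continue
        off = offs[0]
        si = float(t_ms[off] - t_ms[on])
        hp = float(t_ms[nxt] - t_ms[on])
        rows.append({"SI_ms": si, "DI_ms": hp - si, "HP_ms": hp})
    table = pd.DataFrame(rows)
    fs = (dia - sys_) / dia
    summary = {
        "HP_ms": float(table["HP_ms"].median()) if len(table) else float("nan"),
        "SI_ms": float(table["SI_ms"].median()) if len(table) else float("nan"),
        "DI_ms": float(table["DI_ms"].median()) if len(table) else float("nan"),
        "rate_hz": 1000.0 / float(table["HP_ms"].median()) if len(table) else float("nan"),
        "fractional_shortening": fs,
    }
    return table, summary
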