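"""Per-beat feature extraction and arrhythmic-event detection.

Works on simulated voltage/Ca2+ traces and on synthetic optical traces.
The quantities follow the conventions of optical action-potential
platforms: APD_x is the duration from the maximum-upstroke instant to the
point where the signal has repolarized by x% of the beat amplitude
(diastolic-to-peak), with linear interpolation between samples; CTD_x is
the same measure on the Ca2+ transient.

Arrhythmic events during the pause of a pacing–pause protocol are
classified exhaustively and exclusively per deflection:

* tAP (triggered action potential) — crosses the absolute voltage
  threshold or exceeds the upstroke-rate threshold;
* DAD (delayed afterdepolarization) — any remaining deflection whose
  amplitude above the pause baseline reaches the DAD threshold.

EADs (early afterdepolarizations) are depolarizing reversals during the
repolarization phase of a paced beat.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and windows for event detection.

    Voltage thresholds are in mV for simulated traces; with
    ``relative=True`` they are interpreted as fractions of the beat
    amplitude (for affine-scaled optical signals).
    """

    dad_threshold: float = 5.0          # mV above pause baseline
    tap_voltage: float = -40.0          # mV absolute crossing
    tap_upstroke: float = 10.0          # mV/ms
    ead_rate: float = 0.05              # mV/ms depolarizing reversal
    ead_sustain_ms: float = 10.0        # reversal must persist this long
    # the lower bound sits at 40% repolarization: the atrial spike-notch-
    # dome transiently recrosses the 30% level, and a 30% bound would
    # misread the physiologic dome as an EAD
    ead_window: tuple[float, float] = (40.0, 90.0)  # APD-level bounds
    merge_window_ms: float = 50.0
    baseline_window_ms: float = 500.0
    # afterdepolarizations are transient humps; amplitudes are measured
    # against a running-median baseline so slow diastolic drift (seconds
    # scale) is not mistaken for one long deflection
    local_baseline_ms: float = 2000.0
    smooth_samples: int = 0             # moving average (optical: 3)
    relative: bool = False
    rel_dad_threshold: float = 0.05     # fraction of beat amplitude
    rel_tap_level: float = 0.40         # baseline + fraction * amplitude
    rel_tap_upstroke: float = 0.10      # amplitude fractions per ms

    def __post_init__(self) -> None:
        if self.dad_threshold <= 0 or self.tap_upstroke <= 0 or self.ead_rate <= 0:
            raise ValueError("thresholds must be positive")
        if self.ead_window[0] >= self.ead_window[1]:
            raise ValueError("ead_window bounds must be ordered")
        if self.merge_window_ms <= 0:
            raise ValueError("merge_window_ms must be positive")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class BeatWindow:
    """Index range of one beat: [start, stop) with the upstroke sample."""

    start: int
    stop: int
    upstroke: int


@dataclass
class BeatFeatures:
    """Per-beat action-potential / Ca2+-transient features (times in ms)."""

    apd: dict[int, float]               # level -> APD (NaN if unreached)
    peak: float
    diastolic: float
    vmax_up: float
    vmax_down: float
    t_upstroke_ms: float
    ctd: dict[int, float] = field(default_factory=dict)
    t_rise_25_75_ms: float = float("nan")
    t_decay_75_25_ms: float = float("nan")


@dataclass
class EventReport:
    """Counts and times of pause-period and repolarization-phase events."""

    dad_times_ms: list[float] = field(default_factory=list)
    tap_times_ms: list[float] = field(default_factory=list)
    ead_times_ms: list[float] = field(default_factory=list)
    config_hash: str = ""

    @property
    def dad_count(self) -> int:
        return len(self.dad_times_ms)

    @property
    def tap_count(self) -> int:
        return len(self.tap_times_ms)

    @property
    def ead_count(self) -> int:
        return len(self.ead_times_ms)

    @property
    def has_dad(self) -> bool:
        return self.dad_count >= 1

    def to_row(self) -> dict:
        return {
            "dad_count": self.dad_count,
            "tap_count": self.tap_count,
            "ead_count": self.ead_count,
            "has_dad": int(self.has_dad),
            "config_hash": self.config_hash,
        }


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    kernel = np.ones(window) / window
    return np.convolve(v, kernel, mode="same")


def segment_beats(
    t_ms: np.ndarray,
    v: np.ndarray,
    stim_times_ms: np.ndarray | None = None,
    config: DetectionConfig | None = None,
    refractory_ms: float = 100.0,
    min_prominence_frac: float = 0.3,
) -> list[BeatWindow]:
    """Split a uniformly sampled trace into one window per beat.

    With stimulus times given, windows span stimulus to stimulus; otherwise
    upstrokes are detected from prominent peaks.  Quiescent traces yield an
    empty list.
    """
    from scipy.signal import find_peaks

    t_ms = np.asarray(t_ms, dtype=float)
    v = np.asarray(v, dtype=float)
    if config is not None and config.smooth_samples > 1:
        v = _smooth(v, config.smooth_samples)
    dt = t_ms[1] - t_ms[0]
    n = len(v)

    if stim_times_ms is not None and len(stim_times_ms):
        bounds = [int(np.searchsorted(t_ms, s)) for s in np.sort(stim_times_ms)]
        bounds.append(n)
        windows = []
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            if i1 - i0 < 3:
                continue
            up = i0 + int(np.argmax(np.diff(v[i0:i1])))
            windows.append(BeatWindow(i0, i1, up))
        return windows

    vrange = v.max() - v.min()
    if vrange <= 0:
        return []
    distance = max(1, int(round(refractory_ms / dt)))
    peaks, _ = find_peaks(v, prominence=min_prominence_frac * vrange,
                          distance=distance)
    if len(peaks) == 0:
        return []
    # window boundaries midway between consecutive peaks
    mids = [0] + [int((a + b) // 2) for a, b in zip(peaks[:-1], peaks[1:])] + [n]
    windows = []
    for i0, i1 in zip(mids[:-1], mids[1:]):
        if i1 - i0 < 3:
            continue
        up = i0 + int(np.argmax(np.diff(v[i0:i1])))
        windows.append(BeatWindow(i0, i1, up))
    return windows


def _beat_anatomy(t_ms, v, w: BeatWindow):
    """Upstroke time, diastolic level, peak level/sample for one window."""
    seg = v[w.start:w.stop]
    up_rel = w.upstroke - w.start
    peak_rel = up_rel + int(np.argmax(seg[up_rel:]))
    diastolic = float(seg[: up_rel + 1].min()) if up_rel > 0 else float(seg[0])
    return up_rel, peak_rel, diastolic, float(seg[peak_rel])


def _crossing_time(t_ms, v, i_from, threshold, direction="down"):
    """First linearly interpolated crossing of ``threshold`` after i_from."""
    seg = v[i_from:]
    if direction == "down":
        hits = np.flatnonzero(seg[:-1] >= threshold)
        below = np.flatnonzero(seg < threshold)
        if len(below) == 0 or below[0] == 0:
            return None
        k = below[0]
    else:
        above = np.flatnonzero(seg > threshold)
        if len(above) == 0 or above[0] == 0:
            return None
        k = above[0]
    v0, v1 = seg[k - 1], seg[k]
    t0, t1 = t_ms[i_from + k - 1], t_ms[i_from + k]
    if v1 == v0:
        return float(t1)
    frac = (threshold - v0) / (v1 - v0)
    return float(t0 + frac * (t1 - t0))


def apd_at_level(
    t_ms: np.ndarray, v: np.ndarray, window: BeatWindow, level: float
) -> float:
    """APD at ``level``% repolarization for one beat (ms; NaN if unreached).

    Measured from the maximum-upstroke instant to the linearly interpolated
    crossing of ``peak - level/100 * (peak - diastolic)``.
    """
    if not (0.0 < level < 100.0):
        raise ValueError("level must lie strictly between 0 and 100")
    up_rel, peak_rel, diastolic, peak = _beat_anatomy(t_ms, v, window)
    amp = peak - diastolic
    if amp <= 0:
        return float("nan")
    threshold = peak - (level / 100.0) * amp
    t_cross = _crossing_time(t_ms, v, window.start + peak_rel, threshold)
    if t_cross is None:
        return float("nan")
    return t_cross - float(t_ms[window.start + up_rel])


def ctd_at_level(
    t_ms: np.ndarray, ca: np.ndarray, window: BeatWindow, level: float
) -> float:
    """Ca2+-transient duration at ``level``% recovery (ms; NaN if unreached).

    Same geometry as :func:`apd_at_level`, applied to the Ca2+ channel,
    measured from the transient's own maximum-upstroke instant.
    """
    ca_window = BeatWindow(
        window.start,
        window.stop,
        window.start + int(np.argmax(np.diff(ca[window.start:window.stop]))),
    )
    return apd_at_level(t_ms, ca, ca_window, level)


def beat_features(
    t_ms: np.ndarray,
    v: np.ndarray,
    window: BeatWindow,
    ca: np.ndarray | None = None,
    levels: tuple[int, ...] = (10, 25, 50, 75, 90),
) -> BeatFeatures:
    """All per-beat features for one window."""
    dt = float(t_ms[1] - t_ms[0])
    up_rel, peak_rel, diastolic, peak = _beat_anatomy(t_ms, v, window)
    seg = v[window.start:window.stop]
    dv = np.diff(seg) / dt
    apd = {int(lv): apd_at_level(t_ms, v, window, lv) for lv in levels}
    amp = peak - diastolic
    t25 = _crossing_time(t_ms, v, window.start, diastolic + 0.25 * amp, "up")
    t75 = _crossing_time(t_ms, v, window.start, diastolic + 0.75 * amp, "up")
    rise = (t75 - t25) if (t25 is not None and t75 is not None) else float("nan")
    d75 = apd.get(75, float("nan"))
    d25 = apd.get(25, float("nan"))
    decay = d75 - d25 if np.isfinite(d75) and np.isfinite(d25) else float("nan")
    feats = BeatFeatures(
        apd=apd,
        peak=peak,
        diastolic=diastolic,
        vmax_up=float(dv.max()) if len(dv) else float("nan"),
        vmax_down=float(dv.min()) if len(dv) else float("nan"),
        t_upstroke_ms=float(t_ms[window.start + up_rel]),
        t_rise_25_75_ms=rise,
        t_decay_75_25_ms=decay,
    )
    if ca is not None:
        feats.ctd = {int(lv): ctd_at_level(t_ms, ca, window, lv) for lv in (50, 75)}
    return feats


def features_table(trace, config: DetectionConfig | None = None) -> pd.DataFrame:
    """Beat-feature table for a :class:`~atriapop.cell.SimTrace`."""
    stim = trace.stim_times_ms
    windows = segment_beats(trace.t_ms, trace.V_mV, stim, config)
    if trace.pause_start_ms is not None:
        stim = stim[stim < trace.pause_start_ms]
        i_pause = int(np.searchsorted(trace.t_ms, trace.pause_start_ms))
        windows = [
            BeatWindow(w.start, min(w.stop, i_pause), w.upstroke)
            for w in segment_beats(trace.t_ms, trace.V_mV, stim, config)
            if w.upstroke < i_pause
        ]
    rows = []
    for i, w in enumerate(windows):
        f = beat_features(trace.t_ms, trace.V_mV, w, ca=trace.Cai_uM)
        row = {"beat": i, "t_upstroke_ms": f.t_upstroke_ms,
               "peak_mV": f.peak, "diastolic_mV": f.diastolic,
               "vmax_up": f.vmax_up, "vmax_down": f.vmax_down,
               "t_rise_25_75_ms": f.t_rise_25_75_ms,
               "t_decay_75_25_ms": f.t_decay_75_25_ms}
        for lv, val in f.apd.items():
            row[f"APD{lv}"] = val
        for lv, val in f.ctd.items():
            row[f"CTD{lv}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def detect_pause_events(
    t_ms: np.ndarray,
    v: np.ndarray,
    pause_start_ms: float,
    config: DetectionConfig | None = None,
) -> EventReport:
    """Detect and classify DADs and tAPs in the unpaced period.

    The pause baseline is the median voltage over the first
    ``baseline_window_ms`` of the pause.  Suprathreshold deflections closer
    than the merge window count as one event; each event is a tAP if it
    crosses the tAP voltage threshold or exceeds the upstroke-rate
    threshold, otherwise a DAD.
    """
    if config is None:
        config = DetectionConfig()
    t_ms = np.asarray(t_ms, dtype=float)
    v = np.asarray(v, dtype=float)
    if config.smooth_samples > 1:
        v = _smooth(v, config.smooth_samples)
    dt = t_ms[1] - t_ms[0]
    i0 = int(np.searchsorted(t_ms, pause_start_ms))
    pv = v[i0:]
    pt = t_ms[i0:]
    if len(pv) * dt < config.merge_window_ms:
        raise ValueError(
            f"pause ({len(pv) * dt:.0f} ms) is shorter than the merge window"
        )
    n_base = max(1, int(round(config.baseline_window_ms / dt)))
    baseline = float(np.median(pv[:n_base]))
    # running-median local baseline absorbs slow drift
    from scipy.ndimage import median_filter

    n_local = max(3, int(round(config.local_baseline_ms / dt)) | 1)
    local_base = median_filter(pv, size=n_local, mode="nearest")
    rel = pv - local_base

    if config.relative:
        amp_ref = float(v.max() - v.min())
        dad_thr = config.rel_dad_threshold * amp_ref
        tap_level = baseline + config.rel_tap_level * amp_ref
        tap_rate = config.rel_tap_upstroke * amp_ref
    else:
        dad_thr = config.dad_threshold
        tap_level = config.tap_voltage
        tap_rate = config.tap_upstroke

    above = rel >= dad_thr
    if not above.any():
        return EventReport(config_hash=config.config_hash)

    # group suprathreshold samples into events, merging close neighbours
    idx = np.flatnonzero(above)
    gaps = np.flatnonzero(np.diff(idx) * dt > config.merge_window_ms)
    groups = np.split(idx, gaps + 1)

    report = EventReport(config_hash=config.config_hash)
    dv = np.gradient(pv, dt)
    for g in groups:
        peak_i = g[int(np.argmax(pv[g]))]
        peak_v = pv[peak_i]
        rate = float(dv[g].max())
        t_peak = float(pt[peak_i])
        if peak_v >= tap_level or rate >= tap_rate:
            report.tap_times_ms.append(t_peak)
        else:
            report.dad_times_ms.append(t_peak)
    return report


def detect_eads(
    t_ms: np.ndarray,
    v: np.ndarray,
    windows: list[BeatWindow],
    config: DetectionConfig | None = None,
) -> list[float]:
    """Times of EADs: depolarizing reversals inside the repolarization
    window (between the configured APD-level instants) of each beat."""
    if config is None:
        config = DetectionConfig()
    t_ms = np.asarray(t_ms, dtype=float)
    v = np.asarray(v, dtype=float)
    if config.smooth_samples > 1:
        v = _smooth(v, config.smooth_samples)
    dt = t_ms[1] - t_ms[0]
    n_sustain = max(1, int(round(config.ead_sustain_ms / dt)))
    times: list[float] = []
    lo, hi = config.ead_window
    for w in windows:
        up_rel, peak_rel, diastolic, peak = _beat_anatomy(t_ms, v, w)
        t_lo = apd_at_level(t_ms, v, w, lo)
        t_hi = apd_at_level(t_ms, v, w, hi)
        if not (np.isfinite(t_lo) and np.isfinite(t_hi)):
            continue
        t_up = t_ms[w.start + up_rel]
        j0 = int(np.searchsorted(t_ms, t_up + t_lo))
        j1 = int(np.searchsorted(t_ms, t_up + t_hi))
        j1 = min(j1, w.stop)
        if j1 - j0 < n_sustain + 1:
            continue
        dv = np.diff(v[j0:j1]) / dt
        rising = dv > config.ead_rate
        # sustained runs of depolarizing slope
        run = 0
        last_t = -np.inf
        for k, flag in enumerate(rising):
            run = run + 1 if flag else 0
            if run == n_sustain:
                t_ev = float(t_ms[j0 + k])
                if t_ev - last_t > config.merge_window_ms:
                    times.append(t_ev)
                    last_t = t_ev
    return times


def analyze_trace(trace, config: DetectionConfig | None = None) -> EventReport:
    """Full event analysis of a pacing–pause :class:`SimTrace`: pause DADs
    and tAPs plus EADs on the recorded paced beats."""
    if config is None:
        config = DetectionConfig()
    if trace.pause_start_ms is None:
        raise ValueError("trace has no annotated pause")
    report = detect_pause_events(
        trace.t_ms, trace.V_mV, trace.pause_start_ms, config
    )
    stim = trace.stim_times_ms[trace.stim_times_ms < trace.pause_start_ms]
    windows = segment_beats(trace.t_ms, trace.V_mV, stim, config)
    report.ead_times_ms = detect_eads(trace.t_ms, trace.V_mV, windows, config)
    return report
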