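"""Seeded synthetic-data generators with ground truth.

These generators emulate the platform's recordings — optical voltage
trains sampled at 100 Hz for 5 s, arrhythmic trains with missed beats and
sub-threshold refire bumps, heart-period series with arrhythmic bouts,
M-mode diameter signals — plus labeled logistic datasets for regression
recovery studies.  Every generator is a pure function of its spec and
seed and emits the ground truth needed to score downstream detectors.

The stylized action-potential waveform has an instantaneous upstroke, an
exponential early plateau and a sigmoidal repolarization, chosen so that
the APD at every level has a closed form: for repolarization
``s(tau) = 1 / (1 + exp((tau - a)/b))`` the instant of x% repolarization
is ``a + b * ln(x / (100 - x))``, so APD50 = a and the shape parameter b
sets the APD25..APD90 spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import OpticalTrace
from .regression import RegressionDataset


@dataclass(frozen=True)
class TraceGeneratorSpec:
    """Parameters of the synthetic optical AP-train generator."""

    rate_hz: float = 1.0
    apd50_ms: float = 150.0         # sigmoid midpoint a
    apd_shape_ms: float = 25.0      # sigmoid width b
    amplitude: float = 1.0
    upstroke_tau_ms: float = 2.0
    jitter_cv: float = 0.0          # interval jitter (CV of cycle length)
    missed_beat_p: float = 0.0
    refire_p: float = 0.0
    refire_amplitude: float = 0.25  # fraction of beat amplitude
    ead_notch_p: float = 0.0
    ead_notch_amplitude: float = 0.10
    noise_sd: float = 0.02          # fraction of amplitude
    drift_per_s: float = 0.006      # linear drift (fraction of amplitude/s)
    sampling_hz: float = 100.0
    duration_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missed_beat_p", "refire_p", "ead_notch_p"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rate_hz <= 0 or self.sampling_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate, sampling and duration must be positive")
        cycle = 1000.0 / self.rate_hz
        if self.apd_at(90) >= cycle:
            raise ValueError("APD90 must be shorter than the cycle length")

    def apd_at(self, level: float) -> float:
        """Closed-form APD of the ideal waveform at ``level``%."""
        x = level / 100.0
        return self.apd50_ms + self.apd_shape_ms * np.log(x / (1.0 - x))


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    beat_times_ms: list[float] = field(default_factory=list)
    apd_by_level: dict[int, float] = field(default_factory=dict)
    intervals_ms: list[float] = field(default_factory=list)
    events: list[tuple[str, float]] = field(default_factory=list)  # (type, t_ms)


def _ap_shape(tau_ms: np.ndarray, spec: TraceGeneratorSpec) -> np.ndarray:
    """Unit-amplitude AP waveform sampled at times after the upstroke."""
    rise = 1.0 - np.exp(-np.clip(tau_ms, 0, None) / spec.upstroke_tau_ms)
    repol = 1.0 / (1.0 + np.exp((tau_ms - spec.apd50_ms) / spec.apd_shape_ms))
    out = rise * repol
    out[tau_ms < 0] = 0.0
    return out


def synth_ap_train(spec: TraceGeneratorSpec) -> tuple[OpticalTrace, GroundTruth]:
    """Stylized optical AP train with analytic APD ground truth."""
    rng = np.random.default_rng(spec.seed)
    cycle = 1000.0 / spec.rate_hz
    duration_ms = spec.duration_s * 1000.0
    n = int(round(spec.sampling_hz * spec.duration_s))
    t = np.arange(n) * (1000.0 / spec.sampling_hz)

    truth = GroundTruth(
        apd_by_level={lv: float(spec.apd_at(lv)) for lv in (10, 25, 50, 75, 90)}
    )
    v = np.zeros(n)
    beat_times = []
    k = 0
    while True:
        t_beat = k * cycle
        if spec.jitter_cv > 0:
            t_beat += rng.normal(0.0, spec.jitter_cv * cycle)
        k += 1
        if t_beat >= duration_ms - spec.apd50_ms:
            break
        if t_beat < 0:
            t_beat = 0.0
        if rng.random() < spec.missed_beat_p:
            truth.events.append(("missed_beat", float(t_beat)))
            continue
        beat_times.append(float(t_beat))
        v += spec.amplitude * _ap_shape(t - t_beat, spec)
        if rng.random() < spec.refire_p:
            t_re = t_beat + spec.apd_at(90) + 0.35 * (cycle - spec.apd_at(90))
            bump = spec.refire_amplitude * spec.amplitude * _ap_shape(
                t - t_re, replace(spec, apd50_ms=min(60.0, spec.apd50_ms / 2),
                                  apd_shape_ms=10.0)
            )
            v += bump
            truth.events.append(("refire", float(t_re)))
        if rng.random() < spec.ead_notch_p:
            t_ead = t_beat + spec.apd_at(50)
            v += spec.ead_notch_amplitude * spec.amplitude * np.exp(
                -0.5 * ((t - t_ead) / 15.0) ** 2
            )
            truth.events.append(("ead_notch", float(t_ead)))

    truth.beat_times_ms = sorted(beat_times)
    truth.intervals_ms = list(np.diff(truth.beat_times_ms))
    v += spec.drift_per_s * spec.amplitude * (t / 1000.0)
    if spec.noise_sd > 0:
        v += rng.normal(0.0, spec.noise_sd * spec.amplitude, n)
    return OpticalTrace(v, spec.sampling_hz), truth


def synth_arrhythmic_train(spec: TraceGeneratorSpec) -> tuple[OpticalTrace, GroundTruth]:
    """AP train with irregularity enabled (alias emphasizing intent).

    The spec's missed-beat, jitter and refire probabilities drive the
    irregularity; ground truth lists every injected event.
    """
    return synth_ap_train(spec)


def synth_population_apd(
    median_a: float,
    median_b: float,
    spread: float,
    n_per_group: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two labeled APD samples (normal) for KS-distance calibration."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    a = rng.normal(median_a, spread, n_per_group)
    b = rng.normal(median_b, spread, n_per_group)
    return a, b


def synth_heart_periods(
    baseline_hp_ms: float = 800.0,
    n_beats: int = 100,
    cv: float = 0.02,
    bout_fraction: float = 0.0,
    bout_spread: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Heart-period series with optional arrhythmic bouts.

    During a bout (a contiguous run covering ``bout_fraction`` of beats)
    the period jitter is multiplied by ``bout_spread`` and the period
    lengthens transiently.  Returns the series and a ground-truth dict
    with the bout mask.
    """
    if n_beats < 2:
        raise ValueError("need at least two beats")
    rng = np.random.default_rng(seed)
    periods = rng.normal(baseline_hp_ms, cv * baseline_hp_ms, n_beats)
    mask = np.zeros(n_beats, dtype=bool)
    if bout_fraction > 0:
        n_bout = max(1, int(round(bout_fraction * n_beats)))
        start = rng.integers(0, n_beats - n_bout + 1)
        mask[start:start + n_bout] = True
        periods[mask] = rng.normal(
            baseline_hp_ms * bout_spread,
            cv * baseline_hp_ms * bout_spread * 2.0,
            n_bout,
        )
    periods = np.clip(periods, 1.0, None)
    return periods, {"bout_mask": mask, "baseline_hp_ms": baseline_hp_ms}


def synth_mmode(
    hp_ms: float = 800.0,
    si_ms: float = 200.0,
    fractional_shortening: float = 0.4,
    diastolic_diameter: float = 100.0,
    n_beats: int = 10,
    sampling_hz: float = 500.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthetic M-mode diameter signal (square-wave contractions).

    Returns (t_ms, diameter, truth).
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_hz
    n = int(round(n_beats * hp_ms / dt))
    t = np.arange(n) * dt
    d = np.full(n, diastolic_diameter)
    systolic = diastolic_diameter * (1.0 - fractional_shortening)
    for k in range(n_beats):
        on = k * hp_ms + 0.25 * hp_ms
        d[(t >= on) & (t < on + si_ms)] = systolic
    if noise_sd > 0:
        d = d + rng.normal(0, noise_sd, n)
    truth = {"HP_ms": hp_ms, "SI_ms": si_ms, "DI_ms": hp_ms - si_ms,
             "fractional_shortening": fractional_shortening}
    return t, d, truth


def synth_logistic(
    beta: np.ndarray,
    n: int,
    seed: int = 0,
    intercept: float = 0.0,
    feature_names: list[str] | None = None,
) -> tuple[RegressionDataset, dict]:
    """Labeled logistic dataset with known coefficients.

    Features are standard normal; labels Bernoulli(sigmoid(X beta + b0)).
    """
    beta = np.asarray(beta, dtype=float)
    if n < 10 * len(beta):
        raise ValueError("need n >= 10 x number of features")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta)))
    p = 1.0 / (1.0 + np.exp(-(X @ beta + intercept)))
    y = (rng.random(n) < p).astype(float)
    names = feature_names or [f"x{i}" for i in range(len(beta))]
    return RegressionDataset(X, y, names), {"beta": beta, "intercept": intercept}
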