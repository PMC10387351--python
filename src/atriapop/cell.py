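"""Single-cell simulation of the human atrial myocyte model.

The model is a Courtemanche/Luo-Rudy-family membrane formulation (fast Na+,
transient outward, ultra-rapid/rapid/slow delayed rectifier and inward
rectifier K+, plateau K+, Ca2+-activated and background Cl-, L-type and
background Ca2+, background Na+, Na+/K+ pump, Na+/Ca2+ exchanger and
sarcolemmal Ca2+ pump) coupled to a sarcoplasmic-reticulum Ca2+ subsystem:
a SERCA pump with a forward/reverse Hill flux parameterized by Kmf/Kmr/H,
and a three-state ryanodine receptor whose Ca2+ sensitivity grows with SR
load, so that Ca2+ overload produces spontaneous diastolic release — the
substrate for delayed afterdepolarizations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .params import ParameterSet, default_parameters
from .protocol import PacingProtocol

STATE_NAMES: tuple[str, ...] = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "ryr_r", "ryr_o", "ryr_q", "Nai", "Ki",
    "Cai", "Cass", "CaSR",
)

_GATE_SLICE = slice(1, 16)


@dataclass(frozen=True)
class CellState:
    """Full model state.  Concentrations in mM, potential in mV."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (_kernel.NSTATE,):
            raise ValueError(f"state must have {_kernel.NSTATE} entries")
        object.__setattr__(self, "values", v)

    def validate(self) -> None:
        v = self.values
        bad = ~np.isfinite(v)
        if bad.any():
            names = [STATE_NAMES[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"non-finite state variables: {names}")
        gates = v[_GATE_SLICE]
        if (gates < -1e-9).any() or (gates > 1 + 1e-9).any():
            idx = np.flatnonzero((gates < -1e-9) | (gates > 1 + 1e-9)) + 1
            names = [STATE_NAMES[i] for i in idx]
            raise ValueError(f"gating variables outside [0, 1]: {names}")
        if (v[16:] <= 0).any():
            idx = np.flatnonzero(v[16:] <= 0) + 16
            names = [STATE_NAMES[i] for i in idx]
            raise ValueError(f"non-positive concentrations: {names}")

    def __getattr__(self, name: str):
        try:
            return self.values[STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None


def default_initial_state() -> CellState:
    """Resting state near the model's quiescent equilibrium."""
    v = np.zeros(_kernel.NSTATE)
    V = -81.2
    v[0] = V
    ginf = np.empty(_kernel.NSTATE)
    gtau = np.empty(_kernel.NSTATE)
    _kernel.gate_rates(V, ginf, gtau)
    v[1:12] = ginf[1:12]
    v[12] = 1.0          # fca
    v[13] = 1.0          # RyR available
    v[14] = 0.0
    v[15] = 0.0
    v[16] = 11.2         # Nai
    v[17] = 139.0        # Ki
    v[18] = 1.0e-4       # Cai  (0.1 uM)
    v[19] = 1.0e-4       # Cass
    v[20] = 0.5          # CaSR
    return CellState(v)


@dataclass(frozen=True)
class SimTrace:
    """Uniformly sampled voltage/Ca2+ trace with protocol annotations.

    ``t_ms`` is a uniform grid; ``V_mV`` membrane potential; ``Cai_uM``
    bulk cytosolic Ca2+ in uM; ``CaSR_mM`` SR Ca2+.  ``stim_times_ms``
    lists delivered stimulus onsets; ``pause_start_ms`` marks the start of
    the unpaced provocation window (None when the protocol has no pause).
    """

    t_ms: np.ndarray
    V_mV: np.ndarray
    Cai_uM: np.ndarray
    CaSR_mM: np.ndarray | None
    stim_times_ms: np.ndarray
    pause_start_ms: float | None
    final_state: CellState | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("t_ms must be a 1-D grid with >= 2 samples")
        if not (np.diff(t) > 0).all():
            raise ValueError("t_ms must be strictly increasing")
        for name in ("V_mV", "Cai_uM"):
            if len(getattr(self, name)) != len(t):
                raise ValueError(f"{name} length does not match t_ms")
        s = np.asarray(self.stim_times_ms, dtype=float)
        if len(s) and (s.min() < t[0] - 1e-9 or s.max() > t[-1] + 1e-9):
            raise ValueError("stimulus times fall outside the trace")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    def pause_slice(self) -> slice:
        if self.pause_start_ms is None:
            raise ValueError("trace has no annotated pause")
        i0 = int(np.searchsorted(self.t_ms, self.pause_start_ms))
        return slice(i0, len(self.t_ms))

    def to_frame(self):
        import pandas as pd

        cols = {"t_ms": self.t_ms, "V_mV": self.V_mV, "Cai_uM": self.Cai_uM}
        if self.CaSR_mM is not None:
            cols["CaSR_mM"] = self.CaSR_mM
        return pd.DataFrame(cols)


def dstate_dt(
    state: CellState,
    t: float = 0.0,
    params: ParameterSet | None = None,
    applied_stimulus: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full state (per ms).

    ``applied_stimulus`` is the injected current in A/F (negative =
    depolarizing).  The model is autonomous, so ``t`` is accepted for ODE
    library compatibility but unused.
    """
    if params is None:
        params = default_parameters()
    state.validate()
    dy = np.empty(_kernel.NSTATE)
    _kernel.derivatives(state.values, params.to_vector(), applied_stimulus, dy)
    return dy


class SolverError(RuntimeError):
    """Raised when the integrator produced a non-finite solution."""


def _run_segments(y, pvec, protocol: PacingProtocol, record_from_ms: float):
    """Integrate the full protocol, recording from ``record_from_ms`` on."""
    dt = protocol.dt_ms
    sample_every = max(1, int(round(protocol.sample_ms / dt)))
    stim_times = np.asarray(protocol.stimulus_times_ms(), dtype=float)
    total = protocol.total_ms

    # burn-in without recording
    if record_from_ms > 0:
        out0 = np.empty((0, 4))
        n = _kernel.integrate(
            y, pvec, 0.0, record_from_ms, dt, stim_times,
            protocol.stim_amplitude, protocol.stim_duration_ms, 10 ** 9, out0,
        )
        if n < 0:
            raise SolverError(
                f"integration diverged at t = {-n * dt:.3f} ms (burn-in)"
            )
    remaining = total - record_from_ms
    n_samples = int(np.floor(remaining / protocol.sample_ms)) + 1
    out = np.empty((n_samples, 4))
    n = _kernel.integrate(
        y, pvec, record_from_ms, remaining, dt, stim_times,
        protocol.stim_amplitude, protocol.stim_duration_ms, sample_every, out,
    )
    if n < 0:
        raise SolverError(
            f"integration diverged at t = {record_from_ms - n * dt:.3f} ms"
        )
    out = out[:n]
    t = record_from_ms + np.arange(n) * protocol.sample_ms
    return t, out


def simulate(
    params: ParameterSet | None = None,
    protocol: PacingProtocol | None = None,
    initial_state: CellState | None = None,
    record_all: bool = False,
) -> SimTrace:
    """Run the pacing–pause protocol on one cell.

    Returns a :class:`SimTrace` covering the recorded window (the final
    paced beats plus the pause), or the whole run when ``record_all``.
    Bit-reproducible for identical inputs.
    """
    if params is None:
        params = default_parameters()
    if protocol is None:
        protocol = PacingProtocol()
    state = initial_state if initial_state is not None else default_initial_state()
    state.validate()
    y = state.values.copy()
    pvec = params.to_vector()

    record_from = 0.0 if record_all else protocol.recorded_start_ms
    t, out = _run_segments(y, pvec, protocol, record_from)

    final = CellState(y.copy())
    final.validate()
    stim_times = np.asarray(protocol.stimulus_times_ms(), dtype=float)
    stim_times = stim_times[stim_times >= t[0] - 1e-9]
    return SimTrace(
        t_ms=t,
        V_mV=out[:, 0],
        Cai_uM=out[:, 1] * 1e3,
        CaSR_mM=out[:, 3],
        stim_times_ms=stim_times,
        pause_start_ms=protocol.pause_start_ms if protocol.pause_s > 0 else None,
        final_state=final,
    )
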