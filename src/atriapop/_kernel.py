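"""Numba-compiled right-hand side and integrator for the atrial cell model.

State vector layout (float64, length 21)::

    0  V      membrane potential (mV)
    1  m      INa activation
    2  h      INa fast inactivation
    3  j      INa slow inactivation
    4  oa     Ito activation
    5  oi     Ito inactivation
    6  ua     IKur activation
    7  ui     IKur inactivation
    8  xr     IKr activation
    9  xs     IKs activation
    10 d      ICaL activation
    11 f      ICaL voltage inactivation
    12 fca    ICaL Ca-dependent inactivation
    13 r      RyR resting/available fraction
    14 o      RyR open fraction
    15 ii     RyR inactivated fraction   (RI = 1 - r - o - ii)
    16 Nai    intracellular Na+ (mM)
    17 Ki     intracellular K+ (mM)
    18 Cai    bulk cytosolic free Ca2+ (mM)
    19 Cass   junctional-subspace free Ca2+ (mM)
    20 CaSR   SR free Ca2+ (mM)

Parameter vector layout (length 22): the 18 scale factors in
``params.SCALE_FACTOR_NAMES`` order, then effective Kmf (mM), Kmr (mM),
the SERCA Hill coefficient H, and the RyR sensitivity multiplier.

Integration is a fixed-step hybrid scheme: Rush–Larsen exponential
updates for the twelve Hodgkin–Huxley gates, forward Euler for voltage,
RyR states and concentrations.  The default 0.025 ms step is well inside
the stability region of the stiffest non-gate dynamics (subspace Ca2+).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NSTATE = 21
NPARAM = 22

# --- physical constants ---------------------------------------------------
F = 96486.7          # C/mol
RTF = 26.712832      # mV at 310 K

# --- fixed extracellular / geometric constants ----------------------------
NA_O = 140.0         # mM
K_O = 5.4            # mM
CA_O = 1.8           # mM
E_CL = -40.0         # mV
CM = 100.0           # pF
V_CYTO = 13.0        # pL
V_SR = 1.2           # pL
V_SS = 0.02          # pL (junctional cleft)

# --- maximal conductances / rates (baseline, scale factor 1.0) ------------
G_NA = 7.8           # nS/pF
G_TO = 0.1652
G_KR = 0.0294
G_KS = 0.129
G_K1 = 0.09
G_KP = 0.002
G_CLCA = 0.060
KM_CLCA = 0.002      # mM, cytosolic Ca2+ half-activation
G_CLB = 0.0015
G_CAL = 0.1238
G_CAB = 0.00113
G_NAB = 0.000674
V_NAK = 0.59933
KM_NAI = 10.0
KM_KO = 1.5
V_NCX = 1600.0
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
V_PMCA = 0.275
KM_PMCA = 0.0005     # mM

# --- SR Ca2+ handling -----------------------------------------------------
V_SERCA_MAX = 1.5e-3  # mM/ms (cytosolic reference)
KS_REL = 12.0        # /ms, RyR release rate constant (SR reference)
V_LEAK = 3.0e-4      # /ms, passive SR leak (SR reference)

# RyR release is split into two bounded pathways:
#  * triggered (CICR): a release gate opens when subspace Ca2+ crosses a
#    steep (quartic Hill) trigger threshold during the L-type Ca2+ influx,
#    releases with a fixed relaxation time, and recovers slowly
#    (restitution) — graded, refractory, no runaway;
#  * spontaneous: a slow gate tracking a steep Hill function of SR load;
#    Ca2+ overload opens it, the resulting release drains the store below
#    the threshold, the gate closes and SERCA must refill before the next
#    event — a relaxation oscillator producing discrete diastolic release
#    events (the DAD substrate).
RYR_KACT = 0.008     # mM, subspace Ca2+ trigger half-activation
RYR_TAU_ON = 5.0     # ms, triggered-gate opening
RYR_TAU_OFF = 20.0   # ms, triggered-gate closing (release duration)
RYR_TAU_REC = 400.0  # ms, restitution of the available pool
V_REL = 0.3          # /ms, triggered release rate (SR reference)
V_SPON = 0.1         # /ms, spontaneous release rate (SR reference)
SPON_THRESH = 0.75   # mM, SR load threshold igniting spontaneous release
SPON_RESET = 0.55    # mM, release is driven by the load excess over this
SPON_TAU = 50.0      # ms, spontaneous release pulse decay
SPON_REARM = 0.01    # gate must decay below this before re-triggering

# --- Ca2+ buffering (rapid-equilibrium approximation) ---------------------
B_TNC = 0.070        # mM troponin C
K_TNC = 0.0005
B_CAM = 0.050        # mM calmodulin
K_CAM = 0.00238
B_SL = 0.3           # mM subspace/sarcolemmal sites
K_SL = 0.013
B_CSQ = 10.0         # mM calsequestrin
K_CSQ = 0.8

KM_FCA = 0.010       # mM, ICaL Ca-dependent inactivation (subspace)
TAU_FCA = 2.0        # ms
TAU_SS_DIFF = 0.5    # ms, subspace -> bulk transfer

# (mM/ms) per (A/F): Cm[pF]/(z*F[C/mol]*Vol[pL]) — the pico prefixes cancel
# and mol/L/ms from C/ms over C/mol equals mM/ms after the 1e-3/1e-3 of
# (pC/ms)/(pL), so the plain ratio is already in mM/ms.
CONV_CYTO = CM / (2.0 * F * V_CYTO)
CONV_SS = CM / (2.0 * F * V_SS)
CONV_MONO = CM / (F * V_CYTO)


@njit(cache=True)
def _safe_exp(x):
    if x > 80.0:
        x = 80.0
    elif x < -80.0:
        x = -80.0
    return np.exp(x)


@njit(cache=True)
def gate_rates(V, ginf, gtau):
    """Steady states and time constants for the HH gates (indices 1-11).

    ``ginf``/``gtau`` are length-NSTATE scratch arrays; only the gate slots
    are written.  fca is handled separately (Ca-dependent).
    """
    # INa m gate (Luo-Rudy)
    x = V + 47.13
    if abs(x) < 1e-6:
        am = 3.2
    else:
        am = 0.32 * x / (1.0 - _safe_exp(-0.1 * x))
    bm = 0.08 * _safe_exp(-V / 11.0)
    ginf[1] = am / (am + bm)
    gtau[1] = 1.0 / (am + bm)

    # INa h, j gates (Luo-Rudy piecewise)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + _safe_exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * _safe_exp(-2.535e-7 * V) / (1.0 + _safe_exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * _safe_exp(-(V + 80.0) / 6.8)
        bh = 3.56 * _safe_exp(0.079 * V) + 3.1e5 * _safe_exp(0.35 * V)
        aj = (
            (-1.2714e5 * _safe_exp(0.2444 * V) - 3.474e-5 * _safe_exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + _safe_exp(0.311 * (V + 79.23)))
        )
        bj = 0.1212 * _safe_exp(-0.01052 * V) / (1.0 + _safe_exp(-0.1378 * (V + 40.14)))
    ginf[2] = ah / (ah + bh)
    gtau[2] = 1.0 / (ah + bh)
    ginf[3] = aj / (aj + bj)
    gtau[3] = 1.0 / (aj + bj)

    # Ito
    ginf[4] = 1.0 / (1.0 + _safe_exp(-(V + 20.47) / 17.54))
    gtau[4] = 1.0 + 4.0 * _safe_exp(-((V + 25.0) / 35.0) ** 2)
    ginf[5] = 1.0 / (1.0 + _safe_exp((V + 43.1) / 5.3))
    gtau[5] = 15.0 + 30.0 / (1.0 + _safe_exp((V + 45.0) / 8.0))

    # IKur
    ginf[6] = 1.0 / (1.0 + _safe_exp(-(V + 30.3) / 9.6))
    gtau[6] = 1.0 + 3.0 * _safe_exp(-((V + 25.0) / 35.0) ** 2)
    ginf[7] = 1.0 / (1.0 + _safe_exp((V - 99.45) / 27.48))
    gtau[7] = 300.0 + 600.0 / (1.0 + _safe_exp((V + 10.0) / 12.0))

    # IKr
    ginf[8] = 1.0 / (1.0 + _safe_exp(-(V + 14.1) / 6.5))
    gtau[8] = 40.0 + 250.0 * _safe_exp(-((V + 25.0) / 30.0) ** 2)

    # IKs
    ginf[9] = 1.0 / (1.0 + _safe_exp(-(V - 19.9) / 12.7))
    gtau[9] = 200.0 + 400.0 * _safe_exp(-((V - 20.0) / 40.0) ** 2)

    # ICaL
    ginf[10] = 1.0 / (1.0 + _safe_exp(-(V + 10.0) / 8.0))
    gtau[10] = 0.8 + 3.0 * _safe_exp(-((V + 10.0) / 25.0) ** 2)
    ginf[11] = 1.0 / (1.0 + _safe_exp((V + 28.0) / 6.9))
    gtau[11] = 30.0 + 400.0 * _safe_exp(-((V + 10.0) / 30.0) ** 2)


# --- gate-rate lookup tables ----------------------------------------------
# The integrator evaluates the voltage-dependent gate steady states and
# time constants through a dense lookup table (0.05 mV grid, linear
# interpolation); the analytic formulas above remain the single source of
# truth and build the table at import.
V_TAB_MIN = -100.0
V_TAB_MAX = 80.0
V_TAB_STEP = 0.05
_NV = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1


def _build_gate_tables():
    ginf = np.empty(NSTATE)
    gtau = np.empty(NSTATE)
    tab_inf = np.empty((_NV, 12))
    tab_tau = np.empty((_NV, 12))
    for i in range(_NV):
        gate_rates(V_TAB_MIN + i * V_TAB_STEP, ginf, gtau)
        tab_inf[i, 1:12] = ginf[1:12]
        tab_tau[i, 1:12] = gtau[1:12]
    tab_inf[:, 0] = 0.0
    tab_tau[:, 0] = 1.0
    return tab_inf, tab_tau


GINF_TAB, GTAU_TAB = _build_gate_tables()


@njit(cache=True)
def gate_rates_lut(V, ginf, gtau):
    """Table-interpolated gate steady states and time constants."""
    x = (V - V_TAB_MIN) / V_TAB_STEP
    if x < 0.0:
        x = 0.0
    elif x > _NV - 1.001:
        x = _NV - 1.001
    i = int(x)
    f = x - i
    for k in range(1, 12):
        ginf[k] = GINF_TAB[i, k] + f * (GINF_TAB[i + 1, k] - GINF_TAB[i, k])
        gtau[k] = GTAU_TAB[i, k] + f * (GTAU_TAB[i + 1, k] - GTAU_TAB[i, k])


@njit(cache=True)
def nongate_derivs(y, p, i_stim, dy):
    """Derivatives of V, fca, RyR states and concentrations, into ``dy``.

    Gate slots 1-11 of ``dy`` are left untouched.  Returns the membrane
    Ca2+ currents (i_cal, i_ncx, i_bca, i_pmca) in A/F for reuse by the
    Ca-subsystem substeps.
    """
    V = y[0]
    m = y[1]; h = y[2]; jg = y[3]
    oa = y[4]; oi = y[5]; ua = y[6]; ui = y[7]
    xr = y[8]; xs = y[9]; d = y[10]; f = y[11]; fca = y[12]
    r = y[13]; o = y[14]; ii = y[15]
    Nai = y[16]; Ki = y[17]; Cai = y[18]; Cass = y[19]; CaSR = y[20]

    ENa = RTF * np.log(NA_O / Nai)
    EK = RTF * np.log(K_O / Ki)
    ECa = 0.5 * RTF * np.log(CA_O / Cai)

    i_na = p[0] * G_NA * m * m * m * h * jg * (V - ENa)
    i_to = p[1] * G_TO * oa * oa * oa * oi * (V - EK)
    g_kur = 0.005 + 0.05 / (1.0 + _safe_exp(-(V - 15.0) / 13.0))
    i_kur = p[2] * g_kur * ua * ua * ua * ui * (V - EK)
    i_kr = p[3] * G_KR * xr * (V - EK) / (1.0 + _safe_exp((V + 15.0) / 22.4))
    i_ks = p[4] * G_KS * xs * xs * (V - EK)
    i_k1 = p[5] * G_K1 * (V - EK) / (1.0 + _safe_exp(0.07 * (V + 80.0)))
    i_kp = p[6] * G_KP * (V - EK) / (1.0 + _safe_exp((7.488 - V) / 5.98))
    i_clca = p[7] * G_CLCA * (Cai / (Cai + KM_CLCA)) * (V - E_CL)
    i_clb = p[8] * G_CLB * (V - E_CL)
    i_cal = p[9] * G_CAL * d * f * fca * (V - 65.0)
    i_bca = p[10] * G_CAB * (V - ECa)
    i_bna = p[11] * G_NAB * (V - ENa)

    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (
        1.0 + 0.1245 * _safe_exp(-0.1 * V / RTF) + 0.0365 * sigma * _safe_exp(-V / RTF)
    )
    i_nak = (
        p[12] * V_NAK * f_nak
        * (1.0 / (1.0 + (KM_NAI / Nai) ** 1.5))
        * (K_O / (K_O + KM_KO))
    )

    ev = _safe_exp(GAMMA * V / RTF)
    evm = _safe_exp((GAMMA - 1.0) * V / RTF)
    i_ncx = (
        p[13] * V_NCX
        * (ev * Nai ** 3 * CA_O - evm * NA_O ** 3 * Cai)
        / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * evm))
    )

    i_pmca = p[14] * V_PMCA * Cai / (Cai + KM_PMCA)

    i_ion = (
        i_na + i_to + i_kur + i_kr + i_ks + i_k1 + i_kp
        + i_clca + i_clb + i_cal + i_bca + i_bna + i_nak + i_ncx + i_pmca
    )
    dy[0] = -(i_ion + i_stim)

    # material balances; the stimulus charge is carried by K+
    i_k_total = i_to + i_kur + i_kr + i_ks + i_k1 + i_kp
    dy[16] = -(i_na + i_bna + 3.0 * i_nak + 3.0 * i_ncx) * CONV_MONO
    dy[17] = -(i_k_total - 2.0 * i_nak + i_stim) * CONV_MONO

    ca_derivs(y, p, i_cal, i_ncx, i_bca, i_pmca, dy)
    return i_cal, i_ncx, i_bca, i_pmca


@njit(cache=True)
def ca_derivs(y, p, i_cal, i_ncx, i_bca, i_pmca, dy):
    """Derivatives of the fast Ca2+ subsystem (fca, RyR states, Cai, Cass,
    CaSR) with the membrane Ca2+ currents held fixed.  Written into ``dy``
    slots 12-15 and 18-20."""
    fca = y[12]
    r = y[13]; o = y[14]; ii = y[15]
    Cai = y[18]; Cass = y[19]; CaSR = y[20]

    # ICaL Ca-dependent inactivation (senses subspace Ca2+)
    fca_inf = 1.0 / (1.0 + Cass / KM_FCA)
    dy[12] = (fca_inf - fca) / TAU_FCA

    # SERCA forward/reverse Hill flux; Kmf carries the PLN-knockdown scale
    fwd = (Cai / p[18]) ** p[20]
    rev = (CaSR / p[19]) ** p[20]
    j_serca = p[15] * V_SERCA_MAX * (fwd - rev) / (1.0 + fwd + rev)

    # triggered (CICR) release: r = available pool, o = open gate
    s2 = (Cass * p[21] / RYR_KACT) ** 2
    trig = s2 * s2 / (1.0 + s2 * s2)
    dy[13] = (1.0 - r - o) / RYR_TAU_REC - trig * r / RYR_TAU_ON
    dy[14] = trig * r / RYR_TAU_ON - o / RYR_TAU_OFF

    # spontaneous release gate q (slot 15): decaying pulse, re-armed by the
    # SR-load threshold crossing handled in ``step``
    dy[15] = -ii / SPON_TAU

    # RyR sensitization shifts the whole spontaneous-release load curve
    # (ignition threshold and reset level together)
    excess = CaSR - SPON_RESET / np.sqrt(p[21] * p[16])
    if excess < 0.0:
        excess = 0.0
    # the v_RyRrel scale factor acts on the diastolic (spontaneous) release
    # gain; the beat-triggered CICR gain is a fixed property of the dyad
    j_rel = V_REL * o * (CaSR - Cai) + p[16] * V_SPON * ii * excess
    j_leak = p[17] * V_LEAK * (CaSR - Cai)

    beta_i = 1.0 / (
        1.0
        + B_TNC * K_TNC / (K_TNC + Cai) ** 2
        + B_CAM * K_CAM / (K_CAM + Cai) ** 2
    )
    beta_ss = 1.0 / (1.0 + B_SL * K_SL / (K_SL + Cass) ** 2)
    beta_sr = 1.0 / (1.0 + B_CSQ * K_CSQ / (K_CSQ + CaSR) ** 2)

    # RyR release and leak empty into the bulk cytosol; the subspace only
    # senses the ICaL trigger (this keeps diastolic release a slow, buffered
    # avalanche rather than a runaway subspace loop)
    j_diff = (Cass - Cai) / TAU_SS_DIFF
    dy[18] = beta_i * (
        j_diff * (V_SS / V_CYTO)
        + (j_rel + j_leak) * (V_SR / V_CYTO)
        - j_serca
        - (i_bca + i_pmca - 2.0 * i_ncx) * CONV_CYTO
    )
    dy[19] = beta_ss * (-j_diff - i_cal * CONV_SS)
    dy[20] = beta_sr * (j_serca * (V_CYTO / V_SR) - j_rel - j_leak)


@njit(cache=True)
def derivatives(y, p, i_stim, dy):
    """Full ODE right-hand side dy/dt (per ms), written into ``dy``."""
    ginf = np.empty(NSTATE)
    gtau = np.empty(NSTATE)
    gate_rates(y[0], ginf, gtau)
    nongate_derivs(y, p, i_stim, dy)
    for k in range(1, 12):
        dy[k] = (ginf[k] - y[k]) / gtau[k]


N_CA_SUB = 2  # Ca-subsystem substeps per membrane step


@njit(cache=True)
def _spon_trigger(y, p):
    """Arm the spontaneous-release pulse when SR load crosses threshold.

    The pulse gate (slot 15) is set to 1 when SR Ca2+ exceeds the ignition
    threshold and the previous pulse has decayed — the decay time provides
    a natural refractory period, and the released Ca2+ drains the store
    below threshold, giving discrete, repetitive release events under
    sustained overload."""
    thr = SPON_THRESH / np.sqrt(p[21] * p[16])
    if y[20] > thr and y[15] < SPON_REARM:
        y[15] = 1.0


@njit(cache=True)
def _clamp_fast(y):
    for k in range(12, 16):
        if y[k] < 0.0:
            y[k] = 0.0
        elif y[k] > 1.0:
            y[k] = 1.0
    # concentrations stay positive (guards Euler overshoot at sharp release)
    for k in range(16, NSTATE):
        if y[k] < 1e-7:
            y[k] = 1e-7


@njit(cache=True)
def step(y, p, i_stim, dt, ginf, gtau, dy):
    """Advance ``y`` in place by one hybrid step of length ``dt`` (ms).

    Rush–Larsen for the HH gates, forward Euler for voltage and Na+/K+,
    and ``N_CA_SUB`` Euler substeps for the stiff Ca2+/RyR subsystem with
    membrane Ca2+ currents frozen over the step.
    """
    i_cal, i_ncx, i_bca, i_pmca = nongate_derivs(y, p, i_stim, dy)
    gate_rates_lut(y[0], ginf, gtau)
    y[0] += dt * dy[0]
    for k in range(1, 12):
        y[k] = ginf[k] + (y[k] - ginf[k]) * np.exp(-dt / gtau[k])
    y[16] += dt * dy[16]
    y[17] += dt * dy[17]
    h = dt / N_CA_SUB
    for k in range(12, 16):
        y[k] += h * dy[k]
    y[18] += h * dy[18]
    y[19] += h * dy[19]
    y[20] += h * dy[20]
    _clamp_fast(y)
    _spon_trigger(y, p)
    for _ in range(N_CA_SUB - 1):
        ca_derivs(y, p, i_cal, i_ncx, i_bca, i_pmca, dy)
        for k in range(12, 16):
            y[k] += h * dy[k]
        y[18] += h * dy[18]
        y[19] += h * dy[19]
        y[20] += h * dy[20]
        _clamp_fast(y)
        _spon_trigger(y, p)


@njit(cache=True)
def integrate(y, p, t0, duration, dt, stim_times, stim_amp, stim_dur,
              sample_every, out):
    """Integrate for ``duration`` ms, recording every ``sample_every`` steps.

    ``out`` has shape (n_samples, 4): columns V, Cai, Cass, CaSR.  The state
    ``y`` is advanced in place.  Returns the number of samples written, or
    the negated failing step index if a non-finite voltage appeared.
    """
    ginf = np.empty(NSTATE)
    gtau = np.empty(NSTATE)
    dy = np.empty(NSTATE)
    n_steps = int(np.rint(duration / dt))
    n_out = 0
    k_stim = 0
    n_stim = stim_times.shape[0]
    for istep in range(n_steps):
        t = t0 + istep * dt
        if n_out < out.shape[0] and istep % sample_every == 0:
            out[n_out, 0] = y[0]
            out[n_out, 1] = y[18]
            out[n_out, 2] = y[19]
            out[n_out, 3] = y[20]
            n_out += 1
        while k_stim < n_stim and t >= stim_times[k_stim] + stim_dur:
            k_stim += 1
        amp = 0.0
        if k_stim < n_stim and stim_times[k_stim] <= t < stim_times[k_stim] + stim_dur:
            amp = stim_amp
        step(y, p, amp, dt, ginf, gtau, dy)
        if not np.isfinite(y[0]):
            return -(istep + 1)
    return n_out
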