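"""Model parameters and pharmacological/genetic interventions.

A :class:`ParameterSet` carries one multiplicative scale factor per
sensitivity parameter (maximal conductances, transporter rates and Ca2+
handling fluxes) plus the SERCA kinetic constants.  Interventions are pure
functions returning new instances:

* phospholamban (PLN) knockdown — SERCA's apparent affinity for cytosolic
  Ca2+ rises, modelled by multiplying the forward half-saturation constant
  Kmf by a fraction (0.25 corresponds to a 75% reduction in PLN);
* isoproterenol — a multiplicative beta-adrenergic table;
* channel/transporter block — scaling of v_NCX or g_CaL.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

#: The sensitivity parameters varied in population studies, in canonical order.
SCALE_FACTOR_NAMES: tuple[str, ...] = (
    "g_Na",      # fast Na+ current
    "g_to",      # transient outward K+
    "g_Kur",     # ultra-rapid delayed rectifier K+
    "g_Kr",      # rapid delayed rectifier K+
    "g_Ks",      # slow delayed rectifier K+
    "g_K1",      # inward rectifier K+
    "g_Kp",      # plateau K+
    "g_ClCa",    # Ca2+-activated Cl-
    "g_ClB",     # background Cl-
    "g_CaL",     # L-type Ca2+
    "g_CaB",     # background Ca2+
    "g_NaB",     # background Na+
    "v_NaK",     # Na+/K+ pump
    "v_NCX",     # Na+/Ca2+ exchanger
    "v_PMCA",    # sarcolemmal Ca2+ pump
    "v_SERCA",   # SR Ca2+ uptake (SERCA Vmax)
    "v_RyRrel",  # RyR release flux
    "v_RyRleak", # RyR leak flux
)

#: Beta-adrenergic multiplier table applied by :func:`apply_isoproterenol`.
#: Targets are the canonical ones of beta-adrenergic signalling: augmented
#: L-type Ca2+ current, faster repolarization reserve via IKs, enhanced
#: Na+/K+ pump, sensitized RyR release and PLN phosphorylation (a further
#: drop in effective Kmf, floored downstream).
ISO_TABLE: dict[str, float] = {
    "g_CaL": 1.5,
    "g_Ks": 1.8,
    "v_NaK": 1.1,
    "ryr_sens": 1.5,   # multiplies RyR Ca2+ sensitivity, not a conductance
    "kmf_scale": 0.55, # PLN phosphorylation relieves SERCA inhibition
}

#: Effective Kmf never drops below this fraction of baseline, preventing
#: double counting when PLN knockdown and isoproterenol are combined.
KMF_FLOOR_FRACTION = 0.25


@dataclass(frozen=True)
class ParameterSet:
    """Baseline constants of the atrial myocyte model plus scale factors.

    Attributes
    ----------
    scales
        Dimensionless multiplier per sensitivity parameter (baseline 1.0).
    kmf_scale
        Dimensionless multiplier on the SERCA forward half-saturation
        constant; PLN knockdown and isoproterenol lower it.
    ryr_sens
        Dimensionless multiplier on RyR Ca2+ sensitivity (isoproterenol).
    Kmf
        SERCA forward half-saturation for cytosolic Ca2+ (uM).
    Kmr
        SERCA reverse half-saturation for SR Ca2+ (mM).
    H
        SERCA Hill coefficient (dimensionless, >= 1).
    C_m
        Membrane capacitance (pF).
    V_cyto, V_sr, V_ss
        Cytosolic, SR and junctional-subspace volumes (pL).
    Na_o, K_o, Ca_o
        Fixed extracellular concentrations (mM).
    E_Cl
        Fixed chloride reversal potential (mV).
    T
        Temperature (K).
    """

    scales: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in SCALE_FACTOR_NAMES}
    )
    kmf_scale: float = 1.0
    ryr_sens: float = 1.0
    Kmf: float = 0.8       # uM; anti-PLN antibody shifts 0.8 -> 0.2 uM at kmf_scale=0.25
    Kmr: float = 3.5       # mM
    H: float = 1.787
    C_m: float = 100.0     # pF
    V_cyto: float = 13.0   # pL
    V_sr: float = 1.2      # pL
    V_ss: float = 0.05     # pL
    Na_o: float = 140.0    # mM
    K_o: float = 5.4       # mM
    Ca_o: float = 1.8      # mM
    E_Cl: float = -40.0    # mV
    T: float = 310.0       # K

    def __post_init__(self) -> None:
        missing = set(SCALE_FACTOR_NAMES) - set(self.scales)
        if missing:
            raise ValueError(f"missing scale factors: {sorted(missing)}")
        for name, value in self.scales.items():
            if name not in SCALE_FACTOR_NAMES:
                raise ValueError(f"unknown scale factor {name!r}")
            if not value >= 0:
                raise ValueError(f"scale factor {name} must be >= 0, got {value}")
        if not self.kmf_scale > 0:
            raise ValueError("kmf_scale must be > 0")
        if not (self.Kmf > 0 and self.Kmr > 0):
            raise ValueError("Kmf and Kmr must be > 0")
        if self.H < 1:
            raise ValueError("SERCA Hill coefficient H must be >= 1")
        if not self.C_m > 0:
            raise ValueError("C_m must be > 0")

    @property
    def effective_kmf_scale(self) -> float:
        """kmf_scale clipped at the documented floor (evaluated lazily so
        intervention composition is commutative)."""
        return max(self.kmf_scale, KMF_FLOOR_FRACTION)

    @property
    def effective_kmf(self) -> float:
        """Effective SERCA forward half-saturation (uM) after interventions."""
        return self.effective_kmf_scale * self.Kmf

    def with_scales(self, **updates: float) -> "ParameterSet":
        """Return a copy with some scale factors replaced."""
        scales = dict(self.scales)
        scales.update(updates)
        return dataclasses.replace(self, scales=scales)

    def scaled(self, **multipliers: float) -> "ParameterSet":
        """Return a copy with scale factors multiplied."""
        scales = dict(self.scales)
        for name, mult in multipliers.items():
            if name not in scales:
                raise ValueError(f"unknown scale factor {name!r}")
            scales[name] = scales[name] * mult
        return dataclasses.replace(self, scales=scales)

    def to_vector(self) -> np.ndarray:
        """Pack into the flat float64 vector consumed by the ODE kernel.

        Layout: 18 scale factors in :data:`SCALE_FACTOR_NAMES` order, then
        effective Kmf (mM), Kmr (mM), H, ryr_sens.
        """
        vec = np.empty(22, dtype=np.float64)
        for i, name in enumerate(SCALE_FACTOR_NAMES):
            vec[i] = self.scales[name]
        vec[18] = self.effective_kmf * 1e-3  # uM -> mM
        vec[19] = self.Kmr
        vec[20] = self.H
        vec[21] = self.ryr_sens
        return vec

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        d = json.loads(text)
        return cls(**d)


def default_parameters() -> ParameterSet:
    """Baseline parameter set: every scale factor (and kmf_scale) is 1.0.

    The baseline Kmf of 0.8 uM is chosen so that a kmf_scale of 0.25
    (maximal PLN knockdown) reproduces the experimentally observed affinity
    shift from 0.8 uM to 0.2 uM.
    """
    return ParameterSet()


def apply_pln_kd(params: ParameterSet, kmf_fraction: float) -> ParameterSet:
    """Simulate phospholamban knockdown by scaling the SERCA Kmf.

    Parameters
    ----------
    kmf_fraction
        Remaining fraction of Kmf, in (0, 1].  0.25 models a 75% reduction
        in PLN (high knockdown); 0.75 a mild one.
    """
    if not (0.0 < kmf_fraction <= 1.0):
        raise ValueError(
            f"kmf_fraction must lie in (0, 1], got {kmf_fraction}"
        )
    return dataclasses.replace(params, kmf_scale=params.kmf_scale * kmf_fraction)


def apply_isoproterenol(params: ParameterSet, on: bool = True) -> ParameterSet:
    """Apply the beta-adrenergic multiplier table (:data:`ISO_TABLE`).

    Pure multipliers, so composition with :func:`apply_pln_kd` commutes;
    the effective Kmf is floored at ``KMF_FLOOR_FRACTION`` of baseline when
    the kernel parameter vector is built.
    """
    if not on:
        return params
    mults = {k: v for k, v in ISO_TABLE.items() if k in SCALE_FACTOR_NAMES}
    out = params.scaled(**mults)
    return dataclasses.replace(
        out,
        kmf_scale=out.kmf_scale * ISO_TABLE["kmf_scale"],
        ryr_sens=out.ryr_sens * ISO_TABLE["ryr_sens"],
    )


#: Valid targets for :func:`apply_block` and the scale factor each maps to.
BLOCK_TARGETS: dict[str, str] = {"NCX": "v_NCX", "LTCC": "g_CaL"}


def apply_block(
    params: ParameterSet, target: str, remaining_fraction: float
) -> ParameterSet:
    """Scale a transporter/channel down to ``remaining_fraction``.

    ``target`` is ``"NCX"`` (Na+/Ca2+ exchanger knockdown) or ``"LTCC"``
    (L-type Ca2+ channel block, the verapamil analogue).
    """
    if target not in BLOCK_TARGETS:
        raise ValueError(
            f"unknown block target {target!r}; valid targets: "
            f"{sorted(BLOCK_TARGETS)}"
        )
    if not (0.0 <= remaining_fraction <= 1.0):
        raise ValueError(
            f"remaining_fraction must lie in [0, 1], got {remaining_fraction}"
        )
    return params.scaled(**{BLOCK_TARGETS[target]: remaining_fraction})
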