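# Methods

`atriapop` couples a deterministic human atrial myocyte model to a
population-of-models workflow, arrhythmic-event detection, a logistic
sensitivity analysis, and a monodomain 2D tissue model. This note
documents the model, its assumptions, the numerical choices, and what the
synthetic data do and do not establish.

## The cell model

The membrane formulation is a Courtemanche/Luo–Rudy-family human atrial
model: fast Na⁺ current (Luo–Rudy m³hj kinetics), transient outward,
ultra-rapid, rapid and slow delayed-rectifier K⁺ currents, inward
rectifier, plateau K⁺, Ca²⁺-activated and background Cl⁻ currents, L-type
and background Ca²⁺ currents, background Na⁺, Na⁺/K⁺ pump, Na⁺/Ca²⁺
exchanger (NCX) and sarcolemmal Ca²⁺ pump. Each of the 18 maximal
conductances/transport rates carries a dimensionless scale factor
(baseline 1.0); these are the handles for population variability and for
the regression analysis. Intracellular Na⁺ and K⁺ are dynamic; the
stimulus charge is assigned to K⁺ so long runs do not drift.

Ca²⁺ handling uses four compartments: bulk cytosol, a junctional
subspace that senses the L-type Ca²⁺ influx, and the SR, with
rapid-equilibrium buffering (troponin/calmodulin in the cytosol,
sarcolemmal sites in the subspace, calsequestrin in the SR). SERCA
follows the reversible Hill form

    J_up = Vmax · [(Cai/Kmf)^H − (CaSR/Kmr)^H] / [1 + (Cai/Kmf)^H + (CaSR/Kmr)^H]

with Kmf = 0.8 µM, Kmr = 3.5 mM, H = 1.787. Phospholamban knockdown is a
multiplicative reduction of Kmf (kmf_scale 0.75/0.5/0.25 for
low/moderate/high knockdown); a kmf_scale of 0.25 reproduces the
experimentally observed affinity shift from 0.8 µM to 0.2 µM.

RyR release is split into two bounded pathways:

* **Triggered (CICR).** A release gate opens when subspace Ca²⁺ crosses a
  steep quartic-Hill trigger during the L-type influx, releases with a
  ~20 ms relaxation time into the bulk cytosol, and the available pool
  recovers with a 400 ms restitution constant. This produces the
  beat-locked Ca²⁺ transient; it is graded, refractory, and has no
  runaway mode.
* **Spontaneous.** When the SR free Ca²⁺ exceeds an ignition threshold
  (0.75 mM at baseline sensitivity) a release pulse is armed; it decays
  with a 50 ms time constant, its flux scales with the load excess over a
  reset level (0.55 mM), and the gate cannot re-arm until it has decayed —
  a relaxation oscillator that converts sustained Ca²⁺ overload into
  discrete diastolic release events. The resulting cytosolic Ca²⁺ hump
  drives inward NCX and Ca²⁺-activated Cl⁻ current: a delayed
  afterdepolarization, or a triggered AP when it reaches the Na⁺
  threshold. β-adrenergic RyR sensitization and the RyR-release scale
  factor shift the whole load curve (threshold and reset together), so
  sensitization changes event frequency without collapsing event
  amplitude.

This split design is a deliberate departure from a single Markov RyR
scheme: deterministic common-pool models with load-sensitized Markov RyRs
either smolder (a stable elevated-leak equilibrium that depolarizes the
diastolic membrane) or dump the whole store each beat. The two-pathway
form keeps paced beats and overload-driven diastolic events separately
well behaved, at the cost of not modeling release-gain effects on the
paced transient (the RyR-release scale factor deliberately acts on the
diastolic pathway only).

Known quantitative limitations: the Ca²⁺ transient amplitude is a few µM
(high by atrial standards) because the lumped cytosolic buffer capacity
is modest; baseline APD90 at 2 Hz is ~380 ms (upper physiologic range),
which in tissue at 2 Hz produces intermittent capture at normal coupling.
Neither affects the directional comparisons the package is built for, and
all constants are module-level and documented.

### Interventions

* PLN knockdown: kmf_scale × {0.75, 0.5, 0.25}.
* Isoproterenol (β-adrenergic table; the study does not publish one):
  g_CaL ×1.5, g_Ks ×2.0, v_NaK ×1.25, RyR sensitivity ×1.5, kmf_scale
  ×0.55, with the effective Kmf floored at 0.25× baseline so PLN
  knockdown and isoproterenol are not double-counted. Applications are
  pure multipliers, so intervention order is immaterial.
* NCX knockdown and L-type block (verapamil analogue): multiplicative
  scaling of v_NCX / g_CaL.

### Calibration

Exact kinetics of the study's base model are not published, so the SR
constants were calibrated once, during model construction, against the
study's stated operating points: the spontaneous-release threshold sits
at the population-median SR load under moderate (Kmf 50%) knockdown, so
that roughly half of a heterogeneous population produces DADs there,
with control populations nearly quiet and deep knockdown nearly always
active. No constant is adjusted per run.

## Numerics

Fixed-step hybrid integration: Rush–Larsen exponential updates for the
eleven Hodgkin–Huxley gates (steady states and time constants read from a
0.05 mV lookup table built from the analytic formulas at import), forward
Euler for voltage and Na⁺/K⁺, and two substeps for the stiff
Ca²⁺/RyR subsystem with the membrane Ca²⁺ currents frozen across the
step. The default step is 0.025 ms. Fixed stepping makes every run
bit-reproducible, which the population and tissue determinism contracts
rely on; halving the step changes baseline APD90 by well under 1%.

Tissue uses first-order operator splitting: the same cell kernel per node
(0.025 ms substeps) followed by an explicit 5-point-Laplacian diffusion
step (0.05 ms) with no-flux boundaries. At the study values D = 0.1485
mm²/ms and dx = 0.25 mm the von Neumann bound is dx²/4D ≈ 0.105 ms, so
the default PDE step has a 2× margin; the spec constructor refuses
unstable steps. The tissue stimulus (−40 A/F × 3 ms, left-most 3 columns)
is stronger than the single-cell stimulus (−12 A/F × 2 ms) because the
injected charge diffuses into the unstimulated bulk. Conduction velocity
is measured on the first paced beat (a clean planar wave from uniform
rest) as the inverse slope of per-column median activation time over the
central 60% of the grid; at normal coupling it is ≈0.53 mm/ms, within
the experimental atrial range, and scales approximately as √D.

## Populations and scale

Populations multiply each of the 18 scale factors by independent
lognormal draws (median 1, σ = 0.2; the study value). Kmf is never in
the random set — it changes only through interventions. The full-scale
study conditions (600 variants, 290 s pre-pacing, 120×125 tissue) are
reachable through the `paper` preset; the package's defaults are
desk-scale (100 variants, 30 pre-pacing beats — enough for beat-to-beat
APD drift below 1% — 30×30 tissue), and the test-suite/acceptance runs
use 40–150 variants, 20×20–30×30 grids and 3–6 s tissue protocols so the
whole pipeline completes on one CPU in minutes. Incidence estimates at
these sizes carry binomial noise of a few percentage points, which is
inside every directional margin asserted.

## Event detection

APD_x/CTD_x are measured from the maximum-upstroke instant to x%
repolarization of the beat amplitude with linear interpolation (robust
for triangular atrial APs). Default thresholds (the study publishes
none): a pause deflection is a tAP if it crosses −40 mV or rises faster
than 10 mV/ms, otherwise a DAD if it exceeds 5 mV; deflections closer
than 50 ms merge. Deflection amplitude is measured against a 2 s
running-median baseline, so slow diastolic drift in depolarization-prone
variants is not misread as one long afterdepolarization. EADs are
depolarizing reversals (dV/dt > 0.05 mV/ms sustained 10 ms) between the
APD40 and APD90 instants — the lower bound sits at 40% rather than 30%
because the atrial spike-notch-dome morphology transiently recrosses the
30% level and the physiologic dome would otherwise count as an EAD. With
`relative=True` all thresholds become amplitude fractions, which makes
detection invariant under affine rescaling (optical traces).

For the regression label and incidence figures, a triggered AP counts as
DAD-positive: it is a DAD that reached threshold, and the study's
incidence panel groups the two.

## Regression

Features are z-scored natural logs of the per-cell scale factors; the
fit is IRLS on the Bernoulli log-likelihood with a 10⁻⁴ ridge on the
slopes (not the intercept) to tame quasi-separation in small
populations; quasi-separation (|β| > 20 or non-convergence) is flagged on
the results object. Bootstrap percentile intervals (200 resamples,
seeded) are available. The implementation is cross-checked in the tests
against a derivative-free likelihood maximizer and scikit-learn.

## Synthetic data

The optical-trace generator emulates the imaging platform (100 Hz, 5 s):
stylized APs with an instantaneous rise, exponential early plateau and
sigmoidal repolarization, so every APD level has a closed form
(APD_x = a + b·ln(x/(100−x)) for midpoint a and width b); configurable
interval jitter, missed beats, sub-threshold refire bumps, EAD notches,
2%-amplitude Gaussian noise and slow drift. Heart-period series emulate
the fly recordings with optional arrhythmic bouts. These generators make
every detector and metric testable closed-loop against exact ground
truth; passing those tests establishes correctness of the measurement
code on clean, stylized waveforms, not performance on real optical data
with motion artifacts, photobleaching nonlinearity or cell-to-cell
amplitude variation.

The arrhythmia index is the coefficient of variation of peak-to-peak
intervals in percent (sample SD), with AI > 20 classifying a train as
irregular; the exact formula behind the published cutoff is not stated,
and this definition is isolated in one function so it can be swapped.
MAD uses k = 1.4826 = 1/Φ⁻¹(0.75); nMAD divides by the median heart
period. KS-D is the standard two-sample Kolmogorov–Smirnov statistic.

## Degenerate inputs and tie-breaks

Constant optical traces refuse normalization; fewer than two peaks or
intervals yield empty results with warnings rather than fabricated
values; unreached repolarization levels are NaN, never extrapolated;
zero-variance regression columns are dropped with a warning;
single-class labels are an error. Concentrations are floored at 10⁻⁷ mM
against Euler overshoot during sharp release; RyR/gate fractions are
clamped to [0, 1].
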