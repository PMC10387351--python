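"""Shared fixtures.

The heavy population and tissue computations are session-scoped so the
acceptance checks that share a condition (incidence ladder, regression
population, tissue runs) compute it once.
"""

from __future__ import annotations

import numpy as np
import pytest

import atriapop as ap
from atriapop import population, tissue
from atriapop.population import apply_interventions

#: deterministic seed for the shared study-condition fixtures
SEED = 1

KD = lambda f: {"kind": "pln_kd", "kmf_fraction": f}
ISO = {"kind": "isoproterenol"}


def _chain(kmf=None, iso=False, block=None):
    chain = []
    if kmf is not None:
        chain.append(KD(kmf))
    if iso:
        chain.append(ISO)
    if block is not None:
        chain.append({"kind": "block", "target": block[0],
                      "remaining_fraction": block[1]})
    return tuple(chain)


@pytest.fixture(scope="session")
def baseline_trace():
    """Baseline cell at 2 Hz with the desk-scale protocol."""
    return ap.simulate(protocol=ap.PacingProtocol(n_prebeats=30))


@pytest.fixture(scope="session")
def incidence_ladder():
    """Summaries of the 8-condition pacing–pause grid (n=40 per condition)."""
    out = {}
    for iso in (False, True):
        for frac in (None, 0.75, 0.5, 0.25):
            tag = f"kmf{int((frac or 1.0) * 100)}{'_iso' if iso else ''}"
            spec = population.PopulationSpec(
                n_cells=40, seed=SEED, interventions=_chain(frac, iso)
            )
            run = population.run_population(spec)
            out[tag] = {"summary": population.summarize(run), "run": run}
    return out


@pytest.fixture(scope="session")
def kmf50_population():
    """Moderate-knockdown population (n=150) for prevalence + regression."""
    spec = population.PopulationSpec(
        n_cells=150, seed=SEED + 1, interventions=_chain(0.5)
    )
    return population.run_population(spec)


@pytest.fixture(scope="session")
def block_populations():
    """NCX-knockdown and LTCC-block populations on the Kmf-50% background."""
    out = {}
    for tag, block in (("ncx", ("NCX", 0.5)), ("ltcc", ("LTCC", 0.5))):
        spec = population.PopulationSpec(
            n_cells=100, seed=SEED + 1, interventions=_chain(0.5, block=block)
        )
        out[tag] = population.run_population(spec)
    return out


def tissue_variants(n, seed, chain=()):
    base = ap.default_parameters()
    factors = population.sample_scale_factors(
        population.PopulationSpec(n_cells=n, seed=seed)
    )
    return [
        apply_interventions(base.with_scales(**row.to_dict()), chain)
        for _, row in factors.iterrows()
    ]


@pytest.fixture(scope="session")
def tissue_coupling_runs():
    """30x30 tissue at 1 Hz over coupling scales (plus global-stimulus
    uncoupled reference) for CV and APD-dispersion checks."""
    variants = tissue_variants(36, SEED)
    runs = {}
    for cs, cols in ((0.0, 30), (0.25, 3), (1.0, 3), (2.0, 3)):
        spec = tissue.TissueSpec(
            nx=30, ny=30, pace_hz=1.0, pace_s=2.0, pause_s=0.5,
            coupling_scale=cs, stim_cols=cols, seed=SEED,
        )
        runs[cs] = tissue.integrate_tissue(spec, variants)
    return runs


@pytest.fixture(scope="session")
def tissue_event_runs():
    """20x20 pacing–pause tissue over perturbation combinations."""
    kd25 = 0.25
    conds = {
        "kmf25": (_chain(kd25), 1.0),
        "iso": (_chain(None, True), 1.0),
        "reduced": ((), 0.25),
        "combined": (_chain(kd25, True), 0.25),
    }
    totals = {}
    for tag, (chain, cs) in conds.items():
        spec = tissue.TissueSpec(
            nx=20, ny=20, pace_s=3.0, pause_s=6.0, coupling_scale=cs, seed=SEED,
        )
        run = tissue.integrate_tissue(spec, tissue_variants(16, SEED, chain))
        _, tot = tissue.count_tissue_events(run)
        totals[tag] = tot
    return totals
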