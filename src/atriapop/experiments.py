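"""Config-driven reproduction of the study's computational experiments.

Each experiment id maps to a stage chain at a chosen scale preset:

* ``apd_shift_pln`` — control vs maximal PLN-knockdown populations at
  2 Hz; APD90/CTD distributions and their KS distance.
* ``incidence_grid`` — DAD/tAP/EAD incidence over PLN-knockdown levels
  (Kmf 100/75/50/25%), each with and without simulated isoproterenol.
* ``regression_kmf50`` — logistic regression of DAD incidence on the
  moderate-knockdown (Kmf 50%) population.
* ``tissue_events`` — 2D tissue pacing–pause runs over perturbation
  combinations; spatial event maps and totals.
* ``trace_metrics_demo`` — synthetic optical trains scored with the
  rhythm metrics (AI, KS-D, MAD/nMAD).

The ``desk`` preset keeps every run within a desk-scale budget
(n = 100 cells, 30-beat pre-pacing, 30x30 tissue); the ``paper`` preset
restores the full-scale study settings (n = 600, 290 s pre-pacing,
120x125 tissue).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as aio
from . import synth
from .events import DetectionConfig
from .metrics import MetricsConfig, arrhythmia_index, ks_distance, mad, nmad, peak_intervals
from .params import default_parameters
from .population import PopulationSpec, run_population, sample_scale_factors, summarize
from .protocol import PacingProtocol
from .regression import DadLogit
from .tissue import TissueSpec, apd_dispersion, count_tissue_events, integrate_tissue, measure_cv

EXPERIMENTS = (
    "apd_shift_pln",
    "incidence_grid",
    "regression_kmf50",
    "tissue_events",
    "trace_metrics_demo",
)

PRESETS = {
    "desk": {"n_cells": 100, "n_prebeats": 30, "tissue_nx": 30, "tissue_ny": 30,
             "tissue_pace_s": 4.0, "tissue_pause_s": 4.0},
    "paper": {"n_cells": 600, "n_prebeats": 576, "tissue_nx": 120, "tissue_ny": 125,
              "tissue_pace_s": 10.0, "tissue_pause_s": 10.0},
}


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    preset: str = "desk"
    seed: int = 0
    out_dir: str = "results"
    overrides: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid ids: "
                f"{list(EXPERIMENTS)}"
            )
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; valid: {list(PRESETS)}")


def _pop_spec(cfg: ExperimentConfig, interventions=(), seed_offset=0, **kw) -> PopulationSpec:
    p = PRESETS[cfg.preset]
    protocol = PacingProtocol(n_prebeats=p["n_prebeats"])
    return PopulationSpec(
        n_cells=kw.pop("n_cells", p["n_cells"]),
        seed=cfg.seed + seed_offset,
        protocol=protocol,
        interventions=tuple(interventions),
        **kw,
    )


def _kd_chain(kmf_fraction: float | None, iso: bool):
    chain = []
    if kmf_fraction is not None and kmf_fraction < 1.0:
        chain.append({"kind": "pln_kd", "kmf_fraction": kmf_fraction})
    if iso:
        chain.append({"kind": "isoproterenol"})
    return tuple(chain)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute an experiment's stage chain and write its result bundle."""
    manifest = aio.RunManifest(config.out_dir, seed=config.seed)
    fn = {
        "apd_shift_pln": _run_apd_shift,
        "incidence_grid": _run_incidence_grid,
        "regression_kmf50": _run_regression,
        "tissue_events": _run_tissue_events,
        "trace_metrics_demo": _run_trace_metrics,
    }[config.experiment]
    bundle = fn(config, manifest)
    manifest.write()
    return bundle


def _run_apd_shift(cfg: ExperimentConfig, manifest: aio.RunManifest) -> dict:
    """Control vs Kmf-25% population APD/CTD distributions (2 Hz)."""
    results = {}
    feats = {}
    for tag, frac in (("control", None), ("kmf25", 0.25)):
        spec = _pop_spec(cfg, _kd_chain(frac, iso=False))
        run = run_population(spec)
        ok = run.features[run.features["failed"] == 0]
        feats[tag] = ok
        results[tag] = summarize(run)
        p = aio.write_table(ok, manifest.out_dir / f"features_{tag}.tsv")
        manifest.add(p)
        manifest.stage_done(tag)
    results["ks_d_apd90"] = ks_distance(
        feats["control"]["APD90"].dropna(), feats["kmf25"]["APD90"].dropna()
    )
    results["ks_d_ctd50"] = ks_distance(
        feats["control"]["CTD50"].dropna(), feats["kmf25"]["CTD50"].dropna()
    )
    p = aio.write_config(results, manifest.out_dir / "apd_shift_summary.json")
    manifest.add(p)
    return results


def _run_incidence_grid(cfg: ExperimentConfig, manifest: aio.RunManifest) -> dict:
    """Incidence of DADs/tAPs/EADs over the Kmf ladder, with/without ISO."""
    rows = []
    runs = {}
    for iso in (False, True):
        for frac in (None, 0.75, 0.5, 0.25):
            tag = f"kmf{int((frac or 1.0) * 100)}{'_iso' if iso else ''}"
            spec = _pop_spec(cfg, _kd_chain(frac, iso))
            run = run_population(spec)
            s = summarize(run)
            s.update({"condition": tag, "kmf_fraction": frac or 1.0, "iso": iso})
            rows.append(s)
            runs[tag] = run
            manifest.stage_done(tag)
    table = pd.DataFrame(rows).set_index("condition")
    p = aio.write_table(table, manifest.out_dir / "incidence_grid.tsv")
    manifest.add(p)
    return {"table": table, "runs": runs}


def _run_regression(cfg: ExperimentConfig, manifest: aio.RunManifest) -> dict:
    """Logistic regression of DAD incidence at moderate PLN knockdown."""
    spec = _pop_spec(cfg, _kd_chain(0.5, iso=False))
    run = run_population(spec)
    ok = run.features["failed"] == 0
    labels = run.features.loc[ok, "has_dad"].astype(float)
    model = DadLogit.from_tables(run.scale_factors.loc[ok.values], labels.to_numpy())
    res = model.fit()
    res.bootstrap(n_boot=100, seed=cfg.seed + 1)
    table = res.summary()
    p = aio.write_table(table, manifest.out_dir / "dad_regression.tsv")
    manifest.add(p)
    manifest.stage_done("regression")
    return {"results": res, "table": table,
            "dad_incidence": float(labels.mean())}


def _tissue_variants(cfg: ExperimentConfig, chain):
    from .population import apply_interventions

    p = PRESETS[cfg.preset]
    n_blocks = (p["tissue_nx"] // 5) * (p["tissue_ny"] // 5)
    pop = PopulationSpec(n_cells=n_blocks, seed=cfg.seed)
    factors = sample_scale_factors(pop)
    base = default_parameters()
    variants = []
    for _, row in factors.iterrows():
        params = base.with_scales(**row.to_dict())
        variants.append(apply_interventions(params, chain))
    return variants


def _run_tissue_events(cfg: ExperimentConfig, manifest: aio.RunManifest) -> dict:
    """Tissue pacing–pause runs over perturbation combinations."""
    p = PRESETS[cfg.preset]
    conditions = {
        "control": (None, False, 1.0),
        "kmf25": (0.25, False, 1.0),
        "iso": (None, True, 1.0),
        "reduced_coupling": (None, False, 0.25),
        "kmf25_iso": (0.25, True, 1.0),
        "kmf25_iso_reduced": (0.25, True, 0.25),
    }
    rows = {}
    for tag, (frac, iso, coupling) in conditions.items():
        spec = TissueSpec(
            nx=p["tissue_nx"], ny=p["tissue_ny"], coupling_scale=coupling,
            pace_s=p["tissue_pace_s"], pause_s=p["tissue_pause_s"],
            seed=cfg.seed,
        )
        run = integrate_tissue(spec, _tissue_variants(cfg, _kd_chain(frac, iso)))
        table, totals = count_tissue_events(run)
        try:
            totals["cv_mm_per_ms"] = measure_cv(run)
        except ValueError:
            totals["cv_mm_per_ms"] = float("nan")
        rows[tag] = totals
        pth = aio.write_table(table, manifest.out_dir / f"tissue_events_{tag}.tsv")
        manifest.add(pth)
        manifest.stage_done(tag)
    table = pd.DataFrame(rows).T
    pth = aio.write_table(table, manifest.out_dir / "tissue_totals.tsv")
    manifest.add(pth)
    return {"totals": table}


def _run_trace_metrics(cfg: ExperimentConfig, manifest: aio.RunManifest) -> dict:
    """Synthetic optical trains scored with the rhythm metrics."""
    mcfg = MetricsConfig()
    regular = synth.TraceGeneratorSpec(seed=cfg.seed)
    irregular = synth.TraceGeneratorSpec(
        seed=cfg.seed + 1, missed_beat_p=0.3, jitter_cv=0.05, refire_p=0.2
    )
    rows = []
    for tag, spec in (("regular", regular), ("irregular", irregular)):
        trace, truth = synth.synth_ap_train(spec)
        iv, rate = peak_intervals(trace, mcfg)
        ai = arrhythmia_index(iv, mcfg)
        rows.append({
            "condition": tag, "beat_rate_hz": rate, "AI": ai,
            "irregular": ai > mcfg.ai_threshold,
            "n_true_beats": len(truth.beat_times_ms),
        })
    periods_reg, _ = synth.synth_heart_periods(seed=cfg.seed)
    periods_arr, _ = synth.synth_heart_periods(seed=cfg.seed, bout_fraction=0.3)
    table = pd.DataFrame(rows).set_index("condition")
    out = {
        "table": table,
        "nmad_regular": nmad(periods_reg),
        "nmad_bouts": nmad(periods_arr),
        "mad_bouts": mad(periods_arr),
        "ks_d_periods": ks_distance(periods_reg, periods_arr),
    }
    p = aio.write_table(table, manifest.out_dir / "trace_metrics.tsv")
    manifest.add(p)
    p = aio.write_config(
        {k: v for k, v in out.items() if not isinstance(v, pd.DataFrame)},
        manifest.out_dir / "trace_metrics_summary.json",
    )
    manifest.add(p)
    manifest.stage_done("trace_metrics")
    return out
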