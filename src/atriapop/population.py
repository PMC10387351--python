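"""Populations of atrial-myocyte model variants.

Cell-to-cell variability is emulated by multiplying each sensitivity
parameter by an independent lognormal factor with median 1 (shape sigma,
study value 0.2).  Each variant is equilibrated and run through the
pacing–pause protocol after applying an intervention chain (PLN
knockdown, isoproterenol, NCX/LTCC block), and per-cell beat features and
arrhythmic events are collected.  The Kmf scale is never part of the
random variation — it is exclusively an intervention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from .cell import SolverError, simulate
from .params import (
    ParameterSet,
    SCALE_FACTOR_NAMES,
    apply_block,
    apply_isoproterenol,
    apply_pln_kd,
    default_parameters,
)
from .protocol import PacingProtocol


def apply_interventions(params: ParameterSet, chain) -> ParameterSet:
    """Apply a declarative intervention chain.

    Each element is a dict with a ``kind`` of ``pln_kd`` (needs
    ``kmf_fraction``), ``isoproterenol`` or ``block`` (needs ``target``
    and ``remaining_fraction``).
    """
    for step in chain:
        kind = step["kind"]
        if kind == "pln_kd":
            params = apply_pln_kd(params, step["kmf_fraction"])
        elif kind == "isoproterenol":
            params = apply_isoproterenol(params, step.get("on", True))
        elif kind == "block":
            params = apply_block(
                params, step["target"], step["remaining_fraction"]
            )
        else:
            raise ValueError(f"unknown intervention kind {kind!r}")
    return params


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a heterogeneous population run."""

    n_cells: int = 100
    sigma: float = 0.2
    varied: tuple[str, ...] = SCALE_FACTOR_NAMES
    seed: int = 0
    protocol: PacingProtocol = field(default_factory=lambda: PacingProtocol(n_prebeats=30))
    interventions: tuple = ()
    base_params: ParameterSet = field(default_factory=default_parameters)
    detection: ev.DetectionConfig = field(default_factory=ev.DetectionConfig)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        unknown = set(self.varied) - set(SCALE_FACTOR_NAMES)
        if unknown:
            raise ValueError(
                f"varied parameters must be scale factors; unknown: {sorted(unknown)}"
            )

    @property
    def spec_hash(self) -> str:
        payload = json.dumps(
            {
                "n_cells": self.n_cells,
                "sigma": self.sigma,
                "varied": list(self.varied),
                "seed": self.seed,
                "protocol": dataclasses.asdict(self.protocol),
                "interventions": list(self.interventions),
            },
            sort_keys=True, default=str,
        )
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclass
class PopulationRun:
    """Results of a population run: per-cell factors, features and events."""

    spec: PopulationSpec
    scale_factors: pd.DataFrame
    features: pd.DataFrame
    reports: list
    failed_cells: list[int]

    @property
    def n_ok(self) -> int:
        return len(self.features) - len(self.failed_cells)


class PopulationRunError(RuntimeError):
    """Raised when too many variants fail to integrate."""


def sample_scale_factors(spec: PopulationSpec) -> pd.DataFrame:
    """Per-cell lognormal scale factors (median 1, shape sigma).

    Reproducible from the spec seed; sigma = 0 degenerates to exact ones.
    """
    if len(spec.varied) == 0 and spec.sigma > 0:
        raise ValueError("varied parameter list is empty but sigma > 0")
    rng = np.random.default_rng(spec.seed)
    if spec.sigma == 0:
        mat = np.ones((spec.n_cells, len(spec.varied)))
    else:
        mat = rng.lognormal(0.0, spec.sigma, (spec.n_cells, len(spec.varied)))
    return pd.DataFrame(mat, columns=list(spec.varied))


def run_cell(
    scales: dict[str, float], spec: PopulationSpec
):
    """Simulate one variant: returns (features row dict, EventReport)."""
    params = spec.base_params.with_scales(**scales)
    params = apply_interventions(params, spec.interventions)
    trace = simulate(params, spec.protocol)
    report = ev.analyze_trace(trace, spec.detection)
    table = ev.features_table(trace, spec.detection)
    row = {}
    for col in ("APD50", "APD75", "APD90", "CTD50", "CTD75"):
        row[col] = float(table[col].median()) if col in table else float("nan")
    row.update(report.to_row())
    return row, report


def run_population(spec: PopulationSpec, progress: bool = False) -> PopulationRun:
    """Run every variant through the protocol; failures are recorded.

    More than 10% solver failures abort the run with per-cell diagnostics.
    """
    factors = sample_scale_factors(spec)
    rows = []
    reports = []
    failed = []
    iterator = factors.iterrows()
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc="population")
    for cell_id, fr in iterator:
        try:
            row, report = run_cell(fr.to_dict(), spec)
        except (SolverError, ValueError) as exc:
            failed.append(int(cell_id))
            rows.append({"failed": 1, "error": str(exc)})
            reports.append(None)
            continue
        row["failed"] = 0
        rows.append(row)
        reports.append(report)
    features = pd.DataFrame(rows)
    features.index.name = "cell"
    if len(failed) > 0.1 * spec.n_cells:
        raise PopulationRunError(
            f"{len(failed)}/{spec.n_cells} variants failed: cells {failed}"
        )
    return PopulationRun(spec, factors, features, reports, failed)


def summarize(run: PopulationRun) -> dict:
    """Population summary: event incidences and feature distributions.

    Incidences are fractions of successfully simulated cells with at least
    one event of the type.
    """
    ok = run.features[run.features["failed"] == 0]
    if len(ok) == 0:
        raise ValueError("population run contains no successful cells")
    n = len(ok)
    out = {
        "n_cells": n,
        "dad_incidence": float((ok["dad_count"] >= 1).mean()),
        "tap_incidence": float((ok["tap_count"] >= 1).mean()),
        "dad_or_tap_incidence": float(
            ((ok["dad_count"] >= 1) | (ok["tap_count"] >= 1)).mean()
        ),
        "ead_incidence": float((ok["ead_count"] >= 1).mean()),
    }
    for col in ("APD50", "APD75", "APD90", "CTD50", "CTD75"):
        vals = ok[col].dropna()
        if len(vals):
            out[f"{col}_median"] = float(vals.median())
            out[f"{col}_iqr"] = float(vals.quantile(0.75) - vals.quantile(0.25))
    return out
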