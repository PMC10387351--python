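"""Table/config export with provenance manifests.

Traces and feature tables are exchanged as delimited (TSV) tables,
configs as JSON; every experiment writes a run manifest listing each
emitted file with its checksum, the seeds used and the software version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Deterministic TSV export (sorted columns stay in given order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path

def read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_config(obj, path: str | Path) -> Path:
    """JSON export of a dataclass config (nested dataclasses supported)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"cannot serialize {type(o)}")

    payload = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=enc))
    return path


def write_trace(trace, path: str | Path) -> Path:
    """SimTrace as a TSV (t_ms, V_mV, Cai_uM[, CaSR_mM]) plus a sidecar
    JSON with stimulus times and the pause start."""
    path = Path(path)
    write_table(trace.to_frame(), path, index=False)
    sidecar = path.with_suffix(".annotations.json")
    sidecar.write_text(json.dumps({
        "stim_times_ms": list(map(float, trace.stim_times_ms)),
        "pause_start_ms": trace.pause_start_ms,
    }, indent=2))
    return path


def write_tissue_snapshots(run, path: str | Path) -> Path:
    """Voltage snapshots of a tissue run as an HDF5 container.

    Datasets: ``t_ms`` (time index), ``V`` (time x ny x nx, mV),
    ``block_map`` and ``activation_ms``.
    """
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("t_ms", data=run.snap_t_ms)
        f.create_dataset("V", data=run.snapshots, compression="gzip")
        f.create_dataset("block_map", data=run.block_map)
        f.create_dataset("activation_ms", data=run.activation_ms)
        f.attrs["dx_mm"] = run.spec.dx_mm
        f.attrs["pause_start_ms"] = run.spec.pause_start_ms
    return path


class RunManifest:
    """Collects emitted files and writes manifest.json at the end."""

    def __init__(self, out_dir: str | Path, config_hash: str = "", seed: int | None = None):
        from . import __version__

        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.entries: list[dict] = []
        self.meta = {
            "software_version": __version__,
            "config_hash": config_hash,
            "seed": seed,
            "stages": {},
        }
        self._t0 = time.time()

    def add(self, path: Path) -> None:
        self.entries.append({
            "file": str(path.relative_to(self.out_dir)),
            "md5": _checksum(path),
        })

    def stage_done(self, name: str) -> None:
        self.meta["stages"][name] = round(time.time() - self._t0, 3)

    def write(self) -> Path:
        payload = dict(self.meta, files=sorted(self.entries, key=lambda e: e["file"]))
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path
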