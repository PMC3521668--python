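"""Config loading, trace serialization, run manifests.

Formats: YAML run configs (units embedded in key names where amounts are
given in paper units, e.g. ``pulse_amplitude_pA``), ``.npz`` trace containers
with a JSON metadata sidecar, and plain CSV for small runs / external traces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _version
from .cell import CellParams
from .network import NetworkSpec, build_grid
from .simulate import SimulationResult, StimulusProtocol

__all__ = [
    "RunManifest",
    "load_config",
    "dump_config",
    "config_from_dict",
    "write_trace",
    "read_trace",
    "write_csv",
    "read_voltage_csv",
]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-exactly."""

    config_hash: str
    seed: int | None
    version: str
    integrator: str
    dt: float
    created: str
    outputs: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash_dict(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=float).encode()).hexdigest()[:16]


def config_from_dict(cfg: dict) -> dict:
    """Materialize a run config: network, cell params, protocol, sim settings.

    All defaults are filled in so the returned dict is complete (nothing
    implicit).  Recognized sections: ``network``, ``cell``, ``protocol``,
    ``simulation``.
    """
    net_cfg = dict(cfg.get("network", {}))
    rows = int(net_cfg.pop("rows", 1))
    cols = int(net_cfg.pop("cols", 1))
    network = build_grid(rows, cols, **net_cfg)
    cell = CellParams(**cfg.get("cell", {}))
    elements = []
    for e in cfg.get("protocol", []):
        e = dict(e)
        kw = {
            "cells": tuple(e.pop("cells")),
            "compartment": e.pop("compartment", "dend"),
            "kind": e.pop("kind", "block_pulse"),
            "onset": float(e.pop("onset_ms", 0.0)),
            "duration": float(e.pop("duration_ms", 0.0)),
            "frequency": float(e.pop("frequency_Hz", 0.0)),
            "phase": float(e.pop("phase_rad", 0.0)),
        }
        if "amplitude_pA" in e:
            kw["amplitude"] = float(e.pop("amplitude_pA"))
            kw["offset"] = float(e.pop("offset_pA", 0.0))
            kw["unit"] = "pA"
        else:
            kw["amplitude"] = float(e.pop("amplitude_uA_per_cm2", 0.0))
            kw["offset"] = float(e.pop("offset_uA_per_cm2", 0.0))
            kw["unit"] = "uA/cm2"
        if e:
            raise ValueError(f"unknown protocol keys: {sorted(e)}")
        from .simulate import StimulusElement

        elements.append(StimulusElement(**kw))
    sim = {"duration": 1000.0, "dt": 0.025, "record_every": 2,
           "store_state": False, "seed": None}
    sim.update(cfg.get("simulation", {}))
    return {"network": network, "cell": cell,
            "protocol": StimulusProtocol(elements), "simulation": sim,
            "hash": _hash_dict(cfg)}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(cfg)


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_trace(result: SimulationResult, path: str | Path) -> RunManifest:
    """Store a run as <path>.npz (arrays) + <path>.json (metadata sidecar)."""
    path = Path(path)
    arrays = {"t": result.t, "v": result.v, "final_state": result.final_state,
              "g_cal": result.g_cal}
    if result.state is not None:
        arrays["state"] = result.state
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "metadata": result.metadata,
        "dt": result.dt,
        "dt_rec": result.dt_rec,
        "network": result.network.to_dict(),
        "cell": result.base_params.to_dict(),
        "protocol": result.protocol.to_dict(),
        "version": _version,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=float)
    manifest = RunManifest(
        config_hash=result.metadata.get("params_hash", ""),
        seed=result.metadata.get("seed"),
        version=_version,
        integrator=result.metadata.get("integrator", "rk4"),
        dt=result.dt,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=[str(path.with_suffix(".npz")), str(path.with_suffix(".json"))],
    )
    return manifest


def read_trace(path: str | Path) -> SimulationResult:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return SimulationResult(
        t=arrays["t"], v=arrays["v"], final_state=arrays["final_state"],
        dt=meta["dt"], dt_rec=meta["dt_rec"],
        network=NetworkSpec.from_dict(meta["network"]),
        base_params=CellParams.from_dict(meta["cell"]),
        g_cal=arrays["g_cal"],
        protocol=StimulusProtocol.from_dict(meta["protocol"]),
        state=arrays.get("state"),
        metadata=meta["metadata"],
    )


def write_csv(result: SimulationResult, path: str | Path) -> None:
    """Long-format CSV export: time_ms, cell, compartment, v_mV."""
    comp_names = ("dend", "soma", "axon")
    with open(path, "w") as fh:
        fh.write("time_ms,cell,compartment,v_mV\n")
        for ci in range(result.n_cells):
            for k, cname in enumerate(comp_names):
                col = result.v[:, ci, k]
                for ti, vv in zip(result.t, col):
                    fh.write(f"{ti:.6g},{ci},{cname},{vv:.6f}\n")


def read_voltage_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a plain two-column (time_ms, v_mV) CSV with a header row.

    Raises a descriptive error (with line number) on malformed input.
    """
    times, volts = [], []
    with open(path) as fh:
        header = fh.readline().strip()
        cols = [c.strip().lower() for c in header.split(",")]
        if len(cols) < 2:
            raise ValueError(f"{path}:1: expected two comma-separated columns, "
                             f"got {header!r}")
        for ln, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 2 fields, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                volts.append(float(parts[1]))
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric value in {line!r}") from None
    t = np.asarray(times)
    v = np.asarray(volts)
    if len(t) < 2:
        raise ValueError(f"{path}: fewer than two samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time base is not uniform")
    return t, v
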