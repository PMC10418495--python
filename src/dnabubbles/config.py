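"""Structured run configuration (YAML) wiring all stages together.

A config file may override any subset of the packaged defaults.  Keys:

- ``units.energy_scale`` — multiplies ``ecr.*`` and ``forcing.F0`` so they
  can be quoted in the conventional 1e-22 N·m units (default 1e-22).
- ``inertia.{A,T,G,C}``, ``radius.*``, ``torsion.K`` (or per-letter),
  ``dissipation.*``, ``bond.{AT,GC}``, ``ecr.{AT,GC}``, ``kD``.
- ``forcing.F0``, ``forcing.omega``.
- ``integrate.T``, ``integrate.tau``, ``integrate.record_stride``.
- ``model.mode`` (conservative|literal), ``model.delta_gates_both``,
  ``model.break_energy`` (relative|full).
- ``energies`` — list of grid values or a "start:stop:step" string, in
  energy_scale units.
- ``regions`` — list of [name, start, end] (1-based inclusive).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .dynamics import ForcingSpec, IntegrationSpec, ModelOptions
from .duplex import DEFAULT_REGIONS, RegionPartition
from .mechanics import BaseMechanics, base_mechanics_from_dict
from .scan import EnergyGrid

__all__ = ["RunConfig", "load_config", "default_config_dict"]


def default_config_dict() -> dict:
    text = resources.files("dnabubbles.data").joinpath("base_mechanics.yaml").read_text()
    cfg = yaml.safe_load(text)
    cfg.setdefault("forcing", {"F0": 0.526, "omega": 0.4e12})
    cfg.setdefault("integrate", {"T": 3.0e-10, "tau": 1.0e-14, "record_stride": 1})
    cfg.setdefault("model", {})
    cfg.setdefault("energies", "0.250:0.600:0.050")
    return cfg


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class RunConfig:
    base_mech: BaseMechanics
    kD: float
    forcing: ForcingSpec
    integ: IntegrationSpec
    options: ModelOptions
    grid: EnergyGrid
    partition: RegionPartition
    raw: dict = field(default_factory=dict, compare=False)

    def config_hash(self) -> str:
        """Stable hash of the merged configuration, for run manifests."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Merge defaults <- file <- overrides into a validated RunConfig."""
    cfg = default_config_dict()
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)

    scale = float(cfg.get("units", {}).get("energy_scale", 1.0))
    base_mech = base_mechanics_from_dict(cfg)
    f = cfg["forcing"]
    forcing = ForcingSpec(F0=float(f["F0"]) * scale, omega=float(f["omega"]))
    it = cfg["integrate"]
    integ = IntegrationSpec(
        T=float(it["T"]), tau=float(it["tau"]), record_stride=int(it.get("record_stride", 1))
    )
    mo = cfg["model"]
    options = ModelOptions(
        mode=mo.get("mode", "conservative"),
        delta_gates_both=bool(mo.get("delta_gates_both", True)),
        break_energy=mo.get("break_energy", "relative"),
    )
    energies = cfg["energies"]
    if isinstance(energies, str):
        grid = EnergyGrid.from_spec(energies, scale=scale)
    else:
        grid = EnergyGrid(values=tuple(float(x) for x in energies), scale=scale)
    if "regions" in cfg:
        partition = RegionPartition.from_bounds(
            [(str(n), int(s), int(e)) for n, s, e in cfg["regions"]]
        )
    else:
        partition = DEFAULT_REGIONS
    return RunConfig(
        base_mech=base_mech,
        kD=float(cfg.get("kD", 1.05)),
        forcing=forcing,
        integ=integ,
        options=options,
        grid=grid,
        partition=partition,
        raw=cfg,
    )
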