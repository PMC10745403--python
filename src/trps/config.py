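"""Experiment configuration: one YAML file per experiment.

The loader validates everything before any simulation starts, fills in
defaults, and exposes the fully resolved dictionary (plus its hash) so
every output file can record exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import yaml

from .dynamics import EngineConfig
from .equilibrium import TSRegion
from .landscapes import make_double_well
from .path_ensemble import CutPlanes
from .systems import ChainSystem, ContinuousSystem


class ConfigError(ValueError):
    """Invalid or incomplete experiment configuration."""


_DEFAULTS = {
    "engine": {"dt": 1e-3, "temperature": 1.0, "friction": 1.0, "mass": 1.0},
    "umbrella": {"n_windows": 15, "spring": 40.0,
                 "steps_per_window": 100_000, "bins": 121},
    "shoots": {"n_shoots": 2000, "max_steps": 1_000_000},
    "first_passage": {"n_runs": 200, "max_steps": 10_000_000},
}


def _require(mapping, key, where):
    if key not in mapping:
        raise ConfigError(f"missing {key!r} in {where}")
    return mapping[key]


@dataclass
class ExperimentConfig:
    system: object
    engine: EngineConfig
    planes: CutPlanes
    ts: TSRegion
    umbrella: dict
    shoots: dict
    first_passage: dict
    temperatures: list
    seed: int
    resolved: dict

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved, sort_keys=True).encode()).hexdigest()[:16]


def build_system(spec: dict):
    kind = _require(spec, "kind", "system")
    if kind == "double_well":
        pot = make_double_well(
            barrier=float(_require(spec, "barrier", "system")),
            x_min_sep=float(_require(spec, "x_min_sep", "system")),
            tilt=float(spec.get("tilt", 0.0)),
            domain=tuple(spec["domain"]) if "domain" in spec else None,
        )
        return ContinuousSystem(pot, engine=spec.get("engine", "overdamped"))
    if kind == "chain":
        if "energies" in spec:
            energies = np.asarray(spec["energies"], dtype=float)
        elif "potential" in spec:
            p = spec["potential"]
            pot = make_double_well(float(_require(p, "barrier", "potential")),
                                   float(_require(p, "x_min_sep", "potential")),
                                   float(p.get("tilt", 0.0)))
            a = pot.params["a"]
            span = spec.get("span", [-1.5 * a, 1.5 * a])
            lo, hi = (float(span[0]), float(span[1]))
            n = int(_require(spec, "n_states", "system"))
            energies = pot.energy(np.linspace(lo, hi, n))
        else:
            raise ConfigError("chain system needs 'energies' or 'potential'")
        if energies.size < 3:
            raise ConfigError("chain needs at least 3 states")
        return ChainSystem(energies)
    if kind == "go_model":
        raise ConfigError(
            "protein (go_model) experiments are driven through the Python "
            "API (trps.go_model); the CLI covers the synthetic systems")
    raise ConfigError(f"unknown system kind {kind!r}")


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    resolved = {}
    for section, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        merged.update(raw.get(section, {}) or {})
        resolved[section] = merged
    for key in ("system", "planes", "ts_region"):
        if key not in raw:
            raise ConfigError(f"missing top-level section {key!r}")
        resolved[key] = raw[key]
    resolved["temperatures"] = [float(t) for t in np.atleast_1d(
        raw.get("temperatures", [resolved["engine"]["temperature"]]))]
    resolved["seed"] = int(raw.get("seed", 0))

    system = build_system(resolved["system"])
    eng = resolved["engine"]
    try:
        engine = EngineConfig(dt=float(eng["dt"]),
                              temperature=float(eng["temperature"]),
                              friction=float(eng["friction"]),
                              mass=float(eng["mass"]),
                              seed=resolved["seed"])
        planes = CutPlanes(qa=float(_require(resolved["planes"], "qa", "planes")),
                           qb=float(_require(resolved["planes"], "qb", "planes")))
        ts = TSRegion(lower=float(_require(resolved["ts_region"], "lower",
                                           "ts_region")),
                      upper=float(_require(resolved["ts_region"], "upper",
                                           "ts_region")))
    except (ValueError, TypeError) as err:
        raise ConfigError(str(err)) from err
    if not (planes.lo < ts.lower and ts.upper < planes.hi):
        raise ConfigError("the TS region must lie strictly between the "
                          "cutting planes")
    return ExperimentConfig(system=system, engine=engine, planes=planes,
                            ts=ts, umbrella=resolved["umbrella"],
                            shoots=resolved["shoots"],
                            first_passage=resolved["first_passage"],
                            temperatures=resolved["temperatures"],
                            seed=resolved["seed"], resolved=resolved)
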