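"""Run configuration: one human-editable YAML mapping with a versioned schema.

Unknown keys are errors, not warnings — a typo in a therapy schedule
must never silently change a simulated course.  A run is reproducible
from the config file (plus any input CSV) alone.

Schema (version 1)::

    schema_version: 1
    seed: 1                      # optional; used wherever noise is drawn
    growth: {a: 0.054, k: 0.0164, N0: 50, unit: "mm^3"}
    therapy:                     # optional; any sub-block may be absent
      t0: 0.0
      alpha: 0.3
      beta: 0.03
      schedule: [{day: 9, dose_Gy: 8}, {day: 10, dose_Gy: 8}]
      it: {mode: exponential, gamma: 0.01, I0: 1.0, rho: 0.1}
      synergy: {delta: 1.0, tau: 2.0, lag: 2.0, Y0: 0.2, t_in: 9.0}
    grid: {start: 0, stop: 25, step: 1}    # or  grid: {days: [0, 1, ...]}
    noise: {kind: multiplicative_lognormal, sd: 0.05}   # optional
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .growth import GompertzParams
from .synthetic import NoiseModel
from .therapy import (
    ImmunotherapyProfile,
    RadiationSchedule,
    SynergyParams,
    TherapyCourse,
)

__all__ = ["RunConfig", "load_run_config", "parse_run_config"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    gp: GompertzParams
    course: TherapyCourse | None
    days: np.ndarray
    noise: NoiseModel | None
    seed: int


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _require(block: dict, keys: tuple, where: str) -> None:
    missing = [k for k in keys if k not in block]
    if missing:
        raise ConfigError(f"missing key(s) in {where}: {missing}")


def parse_run_config(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(doc, {"schema_version", "seed", "growth", "therapy", "grid", "noise"},
                "config")
    _require(doc, ("schema_version", "growth", "grid"), "config")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {doc['schema_version']!r}")
    seed = int(doc.get("seed", 0))

    g = doc["growth"]
    _check_keys(g, {"a", "k", "N0", "unit"}, "growth")
    _require(g, ("a", "k", "N0"), "growth")
    gp = GompertzParams(a=float(g["a"]), k=float(g["k"]), N0=float(g["N0"]),
                        unit_label=str(g.get("unit", "mm^3")))

    course = None
    if "therapy" in doc and doc["therapy"] is not None:
        th = doc["therapy"]
        _check_keys(th, {"t0", "alpha", "beta", "schedule", "it", "synergy"}, "therapy")
        rt = None
        if th.get("schedule"):
            if "alpha" not in th or "beta" not in th:
                raise ConfigError("therapy.schedule requires alpha and beta")
            times, doses = [], []
            for i, fx in enumerate(th["schedule"]):
                _check_keys(fx, {"day", "dose_Gy"}, f"therapy.schedule[{i}]")
                _require(fx, ("day", "dose_Gy"), f"therapy.schedule[{i}]")
                times.append(float(fx["day"]))
                doses.append(float(fx["dose_Gy"]))
            rt = RadiationSchedule(tuple(times), tuple(doses),
                                   float(th["alpha"]), float(th["beta"]))
        it = None
        if th.get("it"):
            b = th["it"]
            _check_keys(b, {"mode", "gamma", "I0", "rho"}, "therapy.it")
            _require(b, ("gamma", "I0"), "therapy.it")
            rho = float(b.get("rho", 0.0))
            mode = b.get("mode")
            if mode is not None:
                if mode not in ("constant", "exponential"):
                    raise ConfigError(f"therapy.it.mode must be constant|exponential, got {mode!r}")
                if (mode == "constant") != (rho == 0.0):
                    raise ConfigError("therapy.it: mode=constant requires rho=0 and vice versa")
            it = ImmunotherapyProfile(gamma=float(b["gamma"]), I0=float(b["I0"]), rho=rho)
        syn = None
        if th.get("synergy"):
            b = th["synergy"]
            _check_keys(b, {"delta", "tau", "lag", "Y0", "t_in"}, "therapy.synergy")
            _require(b, ("delta", "tau", "Y0"), "therapy.synergy")
            syn = SynergyParams(
                delta=float(b["delta"]), tau=float(b["tau"]), Y0=float(b["Y0"]),
                lag=(float(b["lag"]) if "lag" in b else None),
                t_in=float(b.get("t_in", 0.0)),
            )
        course = TherapyCourse(it=it, rt=rt, synergy=syn, t0=float(th.get("t0", 0.0)))

    gr = doc["grid"]
    _check_keys(gr, {"start", "stop", "step", "days"}, "grid")
    if "days" in gr:
        days = np.asarray([float(d) for d in gr["days"]])
    else:
        _require(gr, ("start", "stop", "step"), "grid")
        days = np.arange(float(gr["start"]), float(gr["stop"]) + 1e-12, float(gr["step"]))
    if days.size < 2 or np.any(np.diff(days) <= 0):
        raise ConfigError("grid must yield at least 2 strictly increasing days")

    noise = None
    if "noise" in doc and doc["noise"] is not None:
        b = doc["noise"]
        _check_keys(b, {"kind", "sd", "seed"}, "noise")
        noise = NoiseModel(
            kind=str(b.get("kind", "multiplicative_lognormal")),
            sd=float(b.get("sd", 0.05)),
            seed=int(b.get("seed", seed)),
        )

    return RunConfig(gp=gp, course=course, days=days, noise=noise, seed=seed)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_run_config(doc)
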