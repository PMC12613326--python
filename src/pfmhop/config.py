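"""YAML run-configuration parsing and validation.

A run configuration ties together a model (preset name or parameter table),
the integrator, the decoherence variant, the ensemble size/seed and the
initial electronic state.  Times may be given in fs and the energy-drift
threshold in eV; everything is converted to atomic units on load.  Unknown
keys are rejected with a close-match suggestion.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decoherence import DecoherenceConfig
from .engine import IntegratorConfig
from .models import DiabaticModel, build_model
from .units import FS_TO_AU
from .wigner import width_parameters

__all__ = ["RunConfig", "parse_config"]

_SECTIONS = {"model", "integrator", "decoherence", "ensemble", "initial", "output"}
_KEYS = {
    "model": {"preset", "name", "masses", "masses_in_amu", "states", "couplings",
              "grid"},
    "integrator": {"dt_fs", "substeps", "interpolation", "hop_scheme", "t_final_fs"},
    "decoherence": {"variant", "eta", "kappa", "c", "sigma", "mu", "omega", "n_d"},
    "ensemble": {"n_traj", "seed", "e_drift_ev", "record_stride"},
    "initial": {"amplitudes", "basis", "state", "x0", "p0", "sigma_x"},
    "output": {"prefix", "directory"},
}


def _reject_unknown(section: str, given: dict, allowed: set[str]):
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            msg = f"unknown key {key!r} in section {section!r}"
            if hint:
                msg += f"; did you mean {hint[0]!r}?"
            raise ValueError(msg)


@dataclass
class RunConfig:
    """Validated configuration with defaults applied."""

    model: DiabaticModel
    integrator: IntegratorConfig
    n_traj: int = 1000
    seed: int = 1
    e_drift_ev: float = 1.0
    record_stride: int = 1
    amplitudes: np.ndarray | None = None  # normalized complex, len n_states
    basis: str = "diabatic"
    t_final_fs: float | None = None
    initial_extras: dict = field(default_factory=dict)
    output_prefix: str = "pfmhop"
    output_dir: str = "."
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _parse_amplitudes(spec, n_states: int) -> np.ndarray:
    amp = np.zeros(n_states, dtype=complex)
    for j, entry in enumerate(spec):
        if isinstance(entry, (list, tuple)):
            amp[j] = complex(entry[0], entry[1] if len(entry) > 1 else 0.0)
        else:
            amp[j] = complex(entry)
    norm = np.linalg.norm(amp)
    if norm == 0:
        raise ValueError("initial amplitudes must not all be zero")
    return amp / norm


def parse_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a run configuration from YAML (path or dict)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        data = yaml.safe_load(path.read_text())
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    _reject_unknown("<root>", data, _SECTIONS)
    for section, keys in _KEYS.items():
        if section in data and isinstance(data[section], dict):
            _reject_unknown(section, data[section], keys)

    msec = data.get("model", {})
    if isinstance(msec, str):
        model = build_model(msec)
    elif "preset" in msec:
        model = build_model(msec["preset"])
    else:
        model = build_model({k: v for k, v in msec.items() if k != "grid"})
    if isinstance(msec, dict) and "grid" in msec:
        model.meta = dict(model.meta or {}, grid=dict(msec["grid"]))

    meta = model.meta or {}
    isec = dict(data.get("integrator", {}))
    default_dt = meta.get("dt_fs", 0.1 if model.n_dof == 1 else 0.2)
    dt = float(isec.get("dt_fs", default_dt)) * FS_TO_AU

    dsec = dict(data.get("decoherence", {}))
    variant = dsec.get("variant", "fmi" if model.n_dof == 1 else "pfmi")
    dkw = dict(variant=variant,
               eta=float(dsec.get("eta", 1e-4)),
               kappa=float(dsec.get("kappa", 1e-9)),
               C=float(dsec.get("c", 0.1)))
    if variant in ("fm", "fmi"):
        # sigma defaults to None here; the run entry points fill it from the
        # sampled initial ensemble (width_parameters) before propagating
        sigma = dsec.get("sigma")
        dkw["sigma"] = None if sigma is None else float(sigma)
        dkw["mu"] = float(dsec.get("mu", model.masses[0]))
    if variant in ("pfm", "pfmi"):
        if "omega" in dsec:
            dkw["omega"] = float(dsec["omega"])
            dkw["n_d"] = int(dsec.get("n_d", model.n_dof))
        elif model.normal_modes is not None:
            spec = width_parameters(model.normal_modes)
            dkw["omega"], dkw["n_d"] = spec.omega, spec.n_d
        else:
            raise ValueError("PFM decoherence requires 'omega' or model normal modes")
    dcfg = DecoherenceConfig(**dkw)

    integrator = IntegratorConfig(
        dt=dt,
        n_substeps=int(isec.get("substeps", 51)),
        interpolation=isec.get("interpolation", "linear"),
        hop_scheme=isec.get("hop_scheme", "density_flux"),
        decoherence=dcfg,
    )

    esec = dict(data.get("ensemble", {}))
    init = dict(data.get("initial", {}))
    basis = init.get("basis", meta.get("initial", {}).get("basis", "diabatic"))
    amplitudes = None
    if "amplitudes" in init:
        amplitudes = _parse_amplitudes(init["amplitudes"], model.n_states)
    elif "state" in init or "state" in meta.get("initial", {}):
        state = int(init.get("state", meta.get("initial", {}).get("state", 0)))
        amplitudes = np.zeros(model.n_states, dtype=complex)
        amplitudes[state] = 1.0

    osec = dict(data.get("output", {}))
    return RunConfig(
        model=model,
        integrator=integrator,
        n_traj=int(esec.get("n_traj", 1000)),
        seed=int(esec.get("seed", 1)),
        e_drift_ev=float(esec.get("e_drift_ev", 1.0)),
        record_stride=int(esec.get("record_stride", 1)),
        amplitudes=amplitudes,
        basis=basis,
        t_final_fs=isec.get("t_final_fs", meta.get("t_final_fs")),
        initial_extras={k: init[k] for k in ("x0", "p0", "sigma_x") if k in init},
        output_prefix=osec.get("prefix", "pfmhop"),
        output_dir=osec.get("directory", "."),
        raw=data,
    )
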