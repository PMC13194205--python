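"""Run configuration: a flat, sectioned YAML file.

A config either names a reference scenario (``scenario: {figure: fig1,
q: 0.1}``) or spells out a model explicitly.  Unknown keys are rejected by
name; every omitted field is materialized with its default and echoed to
the log, so a written-back config reproduces the run exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .experiments import (
    DEFAULT_HALF_WIDTH, DEFAULT_N_NODES, Scenario, build_scenario,
)
from .grid import SpatialGrid
from .habitat import (
    KernelSpec, ModelSpec, beverton_holt, linear_birth, linear_reaction,
    logistic_mortality, logistic_nonmonotone, plateau_profile,
    periodic_profile,
)

logger = logging.getLogger("streampop")

_SCHEMA = {
    "scenario": {"figure", "q", "mu", "sigma", "m", "initial"},
    "model": {"D", "q", "tau", "reaction", "birth", "kernel"},
    "grid": {"half_width", "n_nodes"},
    "run": {"n_gens", "dt", "record_every", "initial"},
    "spectral": {"radii", "plateau_tol", "method"},
    "output": {"directory", "formats"},
}
_SUBSCHEMA = {
    "reaction": {"family", "profile", "scale", "theta0"},
    "birth": {"family", "profile", "scale", "eta0"},
    "kernel": {"family", "mean", "sd"},
}

_DEFAULTS = {
    "grid": {"half_width": DEFAULT_HALF_WIDTH, "n_nodes": DEFAULT_N_NODES},
    "run": {"n_gens": 500, "dt": None, "record_every": 10, "initial": "u1"},
    "spectral": {"radii": None, "plateau_tol": 1e-3, "method": "auto"},
    "output": {"directory": "out", "formats": ["csv", "json"]},
}


@dataclass
class RunConfig:
    scenario: Optional[dict] = None
    model: Optional[dict] = None
    grid: dict = dc_field(default_factory=dict)
    run: dict = dc_field(default_factory=dict)
    spectral: dict = dc_field(default_factory=dict)
    output: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for name in ("scenario", "model", "grid", "run", "spectral", "output"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    # -- materialization ---------------------------------------------------

    def make_grid(self) -> SpatialGrid:
        return SpatialGrid(self.grid["half_width"], self.grid["n_nodes"])

    def _build_profile(self, section: dict, role: str):
        prof = section.get("profile", "plateau")
        scale = section.get("scale", 10.0 if role == "reproduction" else 5.0)
        if prof == "plateau":
            return plateau_profile(role, scale)
        if prof == "periodic":
            return periodic_profile(role, scale)
        raise ConfigError(f"unknown profile kind {prof!r}")

    def make_model(self) -> ModelSpec:
        m = self.model
        reaction_cfg = m.get("reaction", {"family": "logistic_mortality"})
        fam = reaction_cfg.get("family", "logistic_mortality")
        if fam == "logistic_mortality":
            reaction = logistic_mortality(
                self._build_profile(reaction_cfg, "mortality"))
        elif fam == "linear":
            reaction = linear_reaction(reaction_cfg.get("theta0", 0.0))
        else:
            raise ConfigError(f"unknown reaction family {fam!r}")
        birth_cfg = m.get("birth", {"family": "beverton_holt"})
        bfam = birth_cfg.get("family", "beverton_holt")
        if bfam == "beverton_holt":
            birth = beverton_holt(self._build_profile(birth_cfg, "reproduction"))
        elif bfam == "logistic_nonmonotone":
            birth = logistic_nonmonotone(
                self._build_profile(birth_cfg, "reproduction"))
        elif bfam == "linear":
            birth = linear_birth(birth_cfg.get("eta0", 1.0))
        else:
            raise ConfigError(f"unknown birth family {bfam!r}")
        kernel_cfg = m.get("kernel", {})
        kernel = KernelSpec(
            kernel_cfg.get("family", "gaussian"),
            kernel_cfg.get("mean", 0.0), kernel_cfg.get("sd", 2.0),
        )
        return ModelSpec(m.get("D", 1.0), m.get("q", 0.0), m.get("tau", 1.0),
                         reaction, birth, kernel)

    def make_scenario(self) -> Scenario:
        if self.scenario is not None:
            kw = dict(self.scenario)
            figure = kw.pop("figure")
            return build_scenario(
                figure,
                half_width=self.grid["half_width"],
                n_nodes=self.grid["n_nodes"],
                n_gens=self.run["n_gens"],
                initial=kw.pop("initial", self.run["initial"]),
                dt=self.run["dt"],
                **kw,
            )
        if self.model is None:
            raise ConfigError("config needs either a 'scenario' or a 'model' section")
        return Scenario(
            name="custom", model=self.make_model(), grid=self.make_grid(),
            initial=self.run["initial"], n_gens=self.run["n_gens"],
            dt=self.run["dt"], notes="custom config",
        )


def _check_keys(section_name: str, data: dict, allowed: set) -> None:
    for key in data:
        if key not in allowed:
            raise ConfigError(
                f"unknown key {key!r} in section {section_name!r} "
                f"(allowed: {sorted(allowed)})"
            )


def read_config(path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of sections")
    _check_keys("<top level>", raw, set(_SCHEMA))
    cfg = RunConfig()
    for name, allowed in _SCHEMA.items():
        data = raw.get(name)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        _check_keys(name, data, allowed)
        for sub, sub_allowed in _SUBSCHEMA.items():
            if sub in data:
                if not isinstance(data[sub], dict):
                    raise ConfigError(f"key {sub!r} must be a mapping")
                _check_keys(f"model.{sub}", data[sub], sub_allowed)
        merged = dict(_DEFAULTS.get(name, {}))
        merged.update(data)
        for key, val in merged.items():
            if key not in data and name in _DEFAULTS:
                logger.info("config default: %s.%s = %r", name, key, val)
        if name in ("scenario", "model"):
            setattr(cfg, name, data if data else None)
        else:
            setattr(cfg, name, merged)
    if cfg.scenario is None and cfg.model is None:
        raise ConfigError("config needs either a 'scenario' or a 'model' section")
    # basic type checks on the numeric leaves
    for name in ("grid", "run"):
        for key, val in cfg.__dict__[name].items():
            if val is not None and key not in ("initial", "formats") and \
                    not isinstance(val, (int, float, list)):
                raise ConfigError(f"{name}.{key} must be numeric, got {val!r}")
    return cfg
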