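"""Run configuration: one YAML file drives a full exploration run.

The file has four sections — space, surface, exploration, output — and is
validated on load with messages naming the offending key.  A loaded
configuration serializes back to YAML canonically, so load -> save -> load
is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import yaml

from .explorer import ExplorationConfig
from .space import KB_KJ_PER_MOL_K, ReactionSpace
from .surfaces import (AnalyticSurface, double_well_1d, quadratic_surface,
                       toy_dipeptide_surface)


class ConfigError(ValueError):
    pass


_EXPLORATION_FIELDS = {f.name for f in dataclasses.fields(ExplorationConfig)}


class RunConfig:
    """Validated in-memory form of a run configuration file."""

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        self.data = data
        self._validate()

    # -- construction --------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                data = yaml.safe_load(fh)
            except yaml.YAMLError as e:
                raise ConfigError(f"{path}: invalid YAML: {e}") from e
        return cls(data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            fh.write(self.canonical_yaml())

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True,
                              default_flow_style=False)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()

    # -- validation ----------------------------------------------------------
    def _req(self, section, key, types, where=None):
        src = where if where is not None else self.data
        if key not in src:
            raise ConfigError(f"missing key '{section}.{key}'"
                              if section else f"missing key '{key}'")
        v = src[key]
        if not isinstance(v, types):
            raise ConfigError(
                f"key '{section + '.' if section else ''}{key}' has type "
                f"{type(v).__name__}, expected {types}")
        return v

    def _validate(self):
        sp = self._req("", "space", dict)
        dim = self._req("space", "dim", int, sp)
        if dim < 1:
            raise ConfigError("space.dim must be >= 1")
        if "temperature" in sp and sp["temperature"] <= 0:
            raise ConfigError("space.temperature must be > 0")
        surf = self._req("", "surface", dict)
        name = self._req("surface", "name", str, surf)
        if name not in ("quadratic", "double_well_1d", "toy_dipeptide"):
            raise ConfigError(f"surface.name '{name}' unknown (choose "
                              f"quadratic, double_well_1d, toy_dipeptide)")
        exp = self.data.get("exploration", {})
        if not isinstance(exp, dict):
            raise ConfigError("exploration must be a mapping")
        unknown = set(exp) - _EXPLORATION_FIELDS
        if unknown:
            raise ConfigError(
                f"unknown exploration keys: {', '.join(sorted(unknown))}")
        self._req("", "initial_center", list)
        if len(self.data["initial_center"]) != dim:
            raise ConfigError(
                f"initial_center has {len(self.data['initial_center'])} "
                f"components, space.dim is {dim}")

    # -- factories -----------------------------------------------------------
    def make_space(self) -> ReactionSpace:
        sp = self.data["space"]
        dim = sp["dim"]
        periodic = tuple(sp.get("periodic", [True] * dim))
        period = tuple(sp.get("period", [2 * np.pi] * dim))
        if "beta" in sp:
            beta = float(sp["beta"])
        else:
            beta = 1.0 / (KB_KJ_PER_MOL_K * float(sp.get("temperature",
                                                         298.0)))
        return ReactionSpace(dim=dim, periodic=periodic, period=period,
                             beta=beta,
                             energy_unit=sp.get("energy_unit", "kJ/mol"))

    def make_surface(self) -> AnalyticSurface:
        surf = self.data["surface"]
        params = dict(surf.get("params", {}))
        name = surf["name"]
        if name == "quadratic":
            return quadratic_surface(np.asarray(params.get("H", [1.0])),
                                     np.asarray(params.get("mu", [0.0])),
                                     space=self.make_space())
        if name == "double_well_1d":
            return double_well_1d(float(params.get("barrier", 10.0)),
                                  float(params.get("asymmetry", 0.0)),
                                  space=self.make_space())
        if name == "toy_dipeptide":
            kwargs = {}
            if "well_depths" in params:
                kwargs["well_depths"] = np.asarray(params["well_depths"])
            if "well_centers" in params:
                kwargs["well_centers"] = np.asarray(params["well_centers"])
            if "kappa" in params:
                kwargs["kappa"] = float(params["kappa"])
            kwargs["temperature"] = float(
                self.data["space"].get("temperature", 298.0))
            return toy_dipeptide_surface(**kwargs)
        raise ConfigError(f"surface.name '{name}' unknown")

    def make_exploration_config(self, seed=None) -> ExplorationConfig:
        exp = dict(self.data.get("exploration", {}))
        for key in ("wham_ranges",):
            if key in exp and exp[key] is not None:
                exp[key] = tuple(tuple(r) for r in exp[key])
        if "default_force_constant" in exp and \
                isinstance(exp["default_force_constant"], list):
            exp["default_force_constant"] = tuple(
                exp["default_force_constant"])
        if seed is not None:
            exp["rng_seed"] = int(seed)
        elif "seed" in self.data:
            exp.setdefault("rng_seed", int(self.data["seed"]))
        return ExplorationConfig(**exp)

    @property
    def initial_center(self) -> np.ndarray:
        return np.asarray(self.data["initial_center"], dtype=float)

    @property
    def output_dir(self) -> str:
        return self.data.get("output_dir", "uiexplore_out")
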