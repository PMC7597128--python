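"""Declarative run configuration (YAML or JSON) -> validated RunSpec.

Omitted fields fall back to the reference study conditions: 1:1 salt at
0.15 mol/L, sigma = -0.25 As/m^2, T = 298 K, water 55 mol/L, n = 1.33,
p0 = 3.1 Debye.  Unknown keys are rejected (typo protection) and schema
violations are reported with their field path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .constants import mol_per_L_to_per_m3
from .physics import ElectrolyteModel, SurfaceCharge
from .solver import GridSpec, SolverOptions
from .steric import StericParams

__all__ = ["RunSpec", "ConfigError", "load_config", "save_config", "run_spec_from_dict"]

_DEFAULT_SIGMA = -0.25


class ConfigError(ValueError):
    """Configuration schema violation, carrying the offending field path."""


def _require_keys(d: dict, allowed: set[str], path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at {path!r}")


def _get_number(d: dict, key: str, default, path: str):
    val = d.get(key, default)
    if not isinstance(val, (int, float)) or isinstance(val, bool):
        raise ConfigError(f"field {path}.{key} must be a number, got {val!r}")
    return float(val)


@dataclass
class RunSpec:
    """Full declarative description of one solve."""

    geometry: str = "planar"
    model: ElectrolyteModel = field(default_factory=ElectrolyteModel)
    sigma: SurfaceCharge = field(default_factory=lambda: SurfaceCharge(_DEFAULT_SIGMA))
    R_nm: Optional[float] = None
    steric: Optional[StericParams] = None
    grid: GridSpec = field(default_factory=GridSpec)
    solver: SolverOptions = field(default_factory=SolverOptions)
    output_path: str = "profile.csv"
    output_format: str = "csv"

    def __post_init__(self) -> None:
        if self.geometry not in ("planar", "cylinder"):
            raise ConfigError(f"geometry must be 'planar' or 'cylinder', got {self.geometry!r}")
        if self.geometry == "cylinder" and self.R_nm is None:
            raise ConfigError("geometry 'cylinder' requires R_nm")
        if self.steric is not None and self.geometry != "planar":
            raise ConfigError("the steric model is available in planar geometry only")
        if self.output_format not in ("csv", "json"):
            raise ConfigError(f"output format must be 'csv' or 'json', got {self.output_format!r}")

    def to_dict(self) -> dict:
        from .constants import Cm_to_debye, per_m3_to_mol_per_L

        d: dict[str, Any] = {
            "geometry": self.geometry,
            "model": {
                "n0_mol_per_L": per_m3_to_mol_per_L(self.model.n0),
                "T": self.model.T,
                "p0_debye": Cm_to_debye(self.model.p0),
                "nw_mol_per_L": per_m3_to_mol_per_L(self.model.nw),
                "n": self.model.n,
            },
            "sigma": self.sigma.sigma,
            "grid": {
                "n_points": self.grid.n_points,
                "domain_length_nm": (
                    "auto" if self.grid.domain_length == "auto" else self.grid.domain_length * 1e9
                ),
                "grading": self.grid.grading,
            },
            "solver": {
                "residual_tol": self.solver.residual_tol,
                "max_newton_iters": self.solver.max_newton_iters,
                "min_damping": self.solver.min_damping,
                "continuation_steps": self.solver.continuation_steps,
                "picard_relaxation": self.solver.picard_relaxation,
            },
            "output": {"path": self.output_path, "format": self.output_format},
        }
        if self.R_nm is not None:
            d["R_nm"] = self.R_nm
        if self.steric is not None:
            d["steric"] = {
                "alpha_plus": self.steric.alpha_plus,
                "alpha_minus": self.steric.alpha_minus,
                "ns_mol_per_L": per_m3_to_mol_per_L(self.steric.ns),
            }
        return d


def run_spec_from_dict(data: dict) -> RunSpec:
    """Validate a raw mapping (parsed YAML/JSON) into a RunSpec."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    _require_keys(
        data, {"geometry", "model", "sigma", "R_nm", "steric", "grid", "solver", "output"}, "<root>"
    )
    geometry = data.get("geometry", "planar")

    mdl = data.get("model", {}) or {}
    if not isinstance(mdl, dict):
        raise ConfigError("'model' must be a mapping")
    _require_keys(mdl, {"n0_mol_per_L", "T", "p0_debye", "nw_mol_per_L", "n"}, "model")
    try:
        model = ElectrolyteModel.from_concentrations(
            n0_mol_per_L=_get_number(mdl, "n0_mol_per_L", 0.15, "model"),
            T=_get_number(mdl, "T", 298.0, "model"),
            p0_debye=_get_number(mdl, "p0_debye", 3.1, "model"),
            nw_mol_per_L=_get_number(mdl, "nw_mol_per_L", 55.0, "model"),
            n=_get_number(mdl, "n", 1.33, "model"),
        )
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc

    sigma = SurfaceCharge(_get_number(data, "sigma", _DEFAULT_SIGMA, "<root>"))

    R_nm = data.get("R_nm")
    if R_nm is not None and (not isinstance(R_nm, (int, float)) or isinstance(R_nm, bool)):
        raise ConfigError("R_nm must be a number (nanometres)")

    steric = None
    if "steric" in data and data["steric"] is not None:
        st = data["steric"]
        if not isinstance(st, dict):
            raise ConfigError("'steric' must be a mapping")
        _require_keys(st, {"alpha_plus", "alpha_minus", "ns_mol_per_L"}, "steric")
        try:
            steric = StericParams(
                alpha_plus=_get_number(st, "alpha_plus", 1.0, "steric"),
                alpha_minus=_get_number(st, "alpha_minus", 1.0, "steric"),
                ns=mol_per_L_to_per_m3(_get_number(st, "ns_mol_per_L", 55.0, "steric")),
            )
        except ValueError as exc:
            raise ConfigError(f"steric: {exc}") from exc

    gr = data.get("grid", {}) or {}
    if not isinstance(gr, dict):
        raise ConfigError("'grid' must be a mapping")
    _require_keys(gr, {"n_points", "domain_length_nm", "grading"}, "grid")
    length = gr.get("domain_length_nm", "auto")
    if length != "auto":
        if not isinstance(length, (int, float)) or isinstance(length, bool):
            raise ConfigError("grid.domain_length_nm must be a number or 'auto'")
        length = float(length) * 1e-9
    try:
        grid = GridSpec(
            n_points=int(_get_number(gr, "n_points", 1024, "grid")),
            domain_length=length,
            grading=_get_number(gr, "grading", 1.02, "grid"),
        )
    except ValueError as exc:
        raise ConfigError(f"grid: {exc}") from exc

    so = data.get("solver", {}) or {}
    if not isinstance(so, dict):
        raise ConfigError("'solver' must be a mapping")
    _require_keys(
        so,
        {"residual_tol", "max_newton_iters", "min_damping", "continuation_steps",
         "picard_relaxation"},
        "solver",
    )
    try:
        solver = SolverOptions(
            residual_tol=_get_number(so, "residual_tol", 1e-8, "solver"),
            max_newton_iters=int(_get_number(so, "max_newton_iters", 30, "solver")),
            min_damping=_get_number(so, "min_damping", 1e-6, "solver"),
            continuation_steps=int(_get_number(so, "continuation_steps", 10, "solver")),
            picard_relaxation=_get_number(so, "picard_relaxation", 0.5, "solver"),
        )
    except ValueError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    out = data.get("output", {}) or {}
    if not isinstance(out, dict):
        raise ConfigError("'output' must be a mapping")
    _require_keys(out, {"path", "format"}, "output")

    return RunSpec(
        geometry=geometry,
        model=model,
        sigma=sigma,
        R_nm=float(R_nm) if R_nm is not None else None,
        steric=steric,
        grid=grid,
        solver=solver,
        output_path=str(out.get("path", "profile.csv")),
        output_format=str(out.get("format", "csv")),
    )


def load_config(path: str | Path) -> RunSpec:
    """Parse and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return run_spec_from_dict(data)


def save_config(spec: RunSpec, path: str | Path) -> None:
    """Write a RunSpec back to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
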