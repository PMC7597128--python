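"""Profile serialization: CSV tables in presentation units + JSON metadata.

User-facing units follow the field's presentation conventions: nm for
position, mV for potential, mol/L for ion densities, As/m^2 for surface
charge.  Full SI is retained in the JSON sidecar.  All output is
deterministic: identical inputs give bit-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import Cm_to_debye, per_m3_to_mol_per_L
from .profiles import SolutionProfile

__all__ = ["profile_frame", "write_profile", "read_profile", "profile_metadata"]

_CSV_COLUMNS = [
    "r_nm",
    "phi_mV",
    "E_V_per_m",
    "eps_r",
    "rho_free_C_per_m3",
    "n_plus_mol_per_L",
    "n_minus_mol_per_L",
    "mean_cos_omega",
]


def profile_frame(profile: SolutionProfile) -> pd.DataFrame:
    """Tabulate a profile in presentation units (nm, mV, mol/L)."""
    return pd.DataFrame(
        {
            "r_nm": profile.coord * 1e9,
            "phi_mV": profile.phi * 1e3,
            "E_V_per_m": profile.E,
            "eps_r": profile.eps_r,
            "rho_free_C_per_m3": profile.rho_free,
            "n_plus_mol_per_L": per_m3_to_mol_per_L(profile.n_plus),
            "n_minus_mol_per_L": per_m3_to_mol_per_L(profile.n_minus),
            "mean_cos_omega": profile.mean_cos,
        }
    )


def profile_metadata(profile: SolutionProfile) -> dict:
    """Run metadata for the JSON sidecar (model echo, convergence, provenance)."""
    from . import __version__

    m = profile.model
    meta = {
        "geometry": profile.geometry,
        "sigma_As_per_m2": profile.sigma.sigma,
        "model": {
            "n0_mol_per_L": per_m3_to_mol_per_L(m.n0),
            "T_K": m.T,
            "p0_debye": Cm_to_debye(m.p0),
            "nw_mol_per_L": per_m3_to_mol_per_L(m.nw),
            "refractive_index": m.n,
            "eps_bulk": m.eps_bulk,
            "n0_per_m3": m.n0,
            "nw_per_m3": m.nw,
            "p0_Cm": m.p0,
        },
        "converged": bool(profile.converged),
        "residual": float(profile.residual),
        "iterations": int(profile.iterations),
        "warnings": list(profile.warnings),
        "package_version": __version__,
        "provenance": "deterministic solve; no randomness anywhere in the pipeline",
    }
    if profile.R is not None:
        meta["R_nm"] = profile.R * 1e9
    return meta


def write_profile(profile: SolutionProfile, path: str | Path, format: str = "csv") -> None:
    """Write a profile as CSV (+ JSON sidecar) or as a single JSON document.

    CSV values carry 17 significant digits so a written-then-read profile
    reproduces the arrays to full double precision.
    """
    path = Path(path)
    frame = profile_frame(profile)
    meta = profile_metadata(profile)
    try:
        if format == "csv":
            frame.to_csv(path, index=False, float_format="%.17g")
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")
        elif format == "json":
            doc = {"metadata": meta, "columns": {c: frame[c].tolist() for c in _CSV_COLUMNS}}
            path.write_text(json.dumps(doc, indent=2) + "\n")
        else:
            raise ValueError(f"unknown output format {format!r} (use 'csv' or 'json')")
    except OSError as exc:
        raise OSError(f"failed to write profile to {path}: {exc}") from exc


def read_profile(path: str | Path) -> pd.DataFrame:
    """Read back a profile table written by :func:`write_profile`."""
    path = Path(path)
    try:
        if path.suffix == ".json":
            doc = json.loads(path.read_text())
            return pd.DataFrame({c: np.asarray(v) for c, v in doc["columns"].items()})
        return pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"failed to read profile from {path}: {exc}") from exc
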