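"""Structured outputs: profile CSV, observables JSON, field checkpoint, XYZ."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chain import dump_xyz  # re-export                     # noqa: F401
from .field import DensityField, FieldGrid, build_orientation_grid
from .observables import BrushProfile

__all__ = [
    "write_profile_csv",
    "read_profile_csv",
    "write_observables_json",
    "write_field_checkpoint",
    "read_field_checkpoint",
    "write_trace_json",
    "dump_xyz",
]


def write_profile_csv(path, profile: BrushProfile, L: float) -> None:
    """Columns: z, z_over_L, rho, S, end_dist (full float precision)."""
    df = pd.DataFrame({
        "z": profile.z_centers,
        "z_over_L": profile.z_centers / L,
        "rho": profile.rho_z,
        "S": profile.S_z,
        "end_dist": profile.end_dist,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_profile_csv(path) -> pd.DataFrame:
    # pandas' fast float parser is 1-ulp sloppy; ask for exact round trip
    return pd.read_csv(path, float_precision="round_trip")


def write_observables_json(path, observables: dict) -> None:
    """Scalar observables (h, psi, P1, P2, stderr fields); absent -> null."""
    clean = {}
    for k, v in observables.items():
        if v is None:
            clean[k] = None
        elif isinstance(v, (np.floating, np.integer)):
            clean[k] = v.item()
        elif isinstance(v, float) and np.isnan(v):
            clean[k] = None
        else:
            clean[k] = v
    Path(path).write_text(json.dumps(clean, indent=2) + "\n")


def write_field_checkpoint(path, field: FieldGrid,
                           density: DensityField = None) -> None:
    """Flat CSV checkpoint: z, theta, phi, omega (and rho when given)."""
    og = field.orientation
    zc = field.z_centers
    theta = np.arccos(np.clip(og.directions[:, 2], -1, 1))
    phi = np.mod(np.arctan2(og.directions[:, 1], og.directions[:, 0]),
                 2 * np.pi)
    nz, nb = field.omega.shape
    data = {
        "z": np.repeat(zc, nb),
        "theta": np.tile(theta, nz),
        "phi": np.tile(phi, nz),
        "omega": field.omega.ravel(),
    }
    if density is not None:
        data["rho"] = density.rho.ravel()
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_field_checkpoint(path, ntheta: int, nphi: int) -> FieldGrid:
    """Rebuild a FieldGrid from a flat CSV checkpoint."""
    df = pd.read_csv(path, float_precision="round_trip")
    zc = np.unique(df["z"].to_numpy())
    nb = ntheta * nphi
    nz = zc.size
    if nz * nb != len(df):
        raise ValueError("checkpoint shape does not match ntheta*nphi")
    dz = zc[1] - zc[0] if nz > 1 else 2 * zc[0]
    edges = np.concatenate([[zc[0] - dz / 2], zc + dz / 2])
    edges[0] = 0.0
    grid = build_orientation_grid(ntheta, nphi)
    omega = df["omega"].to_numpy().reshape(nz, nb)
    return FieldGrid(edges, grid, omega)


def write_xyz_with_sidecar(confs, path, params, seed,
                           comment: str = "") -> None:
    """XYZ dump plus a JSON sidecar recording chain parameters and seed."""
    dump_xyz(confs, path, comment=comment)
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps(
        {"N": params.N, "Nm": params.Nm, "epsilon": params.epsilon,
         "bond_length": params.bond_length, "seed": seed}, indent=2) + "\n")


def write_trace_json(path, trace, extra: dict = None) -> None:
    payload = {"trace": trace}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
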