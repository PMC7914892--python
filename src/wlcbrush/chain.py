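"""Discrete worm-like chain: geometry, bending energetics, consistency checks.

The chain is an inextensible space curve discretized into ``Nm`` bonds of
length ``b = L/Nm``, with unit tangent vectors ``u_1..u_Nm`` and node
positions ``r_0..r_Nm`` linked by ``r_i = r_{i-1} + b u_i``.  All lengths are
measured in Kuhn lengths (``a = 2 l_p = 1``), so the contour length equals the
reduced polymerization ``N = L/a``.  The bending Hamiltonian of a conformation
is

    beta H_0 = eps * sum_{i=1}^{Nm-1} |u_{i+1} - u_i|^2,     eps = Nm / (4 N),

which recovers the continuous worm-like chain as ``Nm -> infinity``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ChainParams",
    "AzoState",
    "Conformation",
    "init_conformation",
    "bending_energy",
    "rebuild_positions",
    "orientations_from_positions",
    "end_to_end",
    "dump_xyz",
]

#: tolerance for the unit-bond and position-consistency invariants
GEOM_TOL = 1e-9


@dataclass(frozen=True)
class ChainParams:
    """Dimensionless worm-like-chain description.

    Parameters
    ----------
    N : float
        Contour length in Kuhn lengths, ``N = L/a`` (the flexibility
        parameter; small N = rigid, large N = flexible).
    Nm : int
        Number of bonds used to discretize the contour (``Nm >= 2``).
    """

    N: float
    Nm: int

    def __post_init__(self) -> None:
        if self.Nm < 2:
            raise ValueError(f"Nm must be >= 2, got {self.Nm}")
        if not self.N > 0:
            raise ValueError(f"N = L/a must be positive, got {self.N}")

    @property
    def epsilon(self) -> float:
        """Discrete bending stiffness ``eps = Nm/(4N)`` (kT units)."""
        return self.Nm / (4.0 * self.N)

    @property
    def bond_length(self) -> float:
        """Bond length ``b = L/Nm`` in Kuhn-length units."""
        return self.N / self.Nm

    @property
    def contour_length(self) -> float:
        """Total contour length L (equals N in a-units)."""
        return float(self.N)


@dataclass(frozen=True)
class AzoState:
    """Photoswitchable kink on the chain.

    ``joint`` is the joint index j (between bonds j and j+1, 1-based bond
    numbering: joint j couples u_j and u_{j+1}); ``isomer`` is ``"trans"`` or
    ``"cis"``; ``alpha`` is the chemical bond angle (pi for trans = straight,
    pi/3 for cis).  The geometric angle between consecutive tangents is
    ``pi - alpha`` (0 for trans under the straight-bond-angle convention).
    """

    joint: int
    isomer: str = "trans"
    alpha: float = np.pi

    @property
    def kink_angle(self) -> float:
        return float(np.pi - self.alpha)


@dataclass
class Conformation:
    """A grafted discrete chain: node positions plus unit bond orientations.

    Orientations are authoritative; positions are the cumulative sum
    ``r_i = r_{i-1} + b u_i`` anchored at ``graft_point``.
    """

    graft_point: np.ndarray
    positions: np.ndarray      # (Nm+1, 3)
    orientations: np.ndarray   # (Nm, 3), unit vectors
    bond_length: float
    azo: Optional[AzoState] = field(default=None)

    @property
    def Nm(self) -> int:
        return self.orientations.shape[0]

    def copy(self) -> "Conformation":
        return Conformation(
            graft_point=self.graft_point.copy(),
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            bond_length=self.bond_length,
            azo=self.azo,
        )

    def validate(self, tol: float = GEOM_TOL) -> None:
        """Raise ValueError if any geometric invariant is violated."""
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > tol):
            raise ValueError(
                f"non-unit bond orientation (max drift "
                f"{np.abs(norms - 1.0).max():.2e} > {tol:.0e})"
            )
        if not np.allclose(self.positions[0], self.graft_point, atol=tol):
            raise ValueError("r_0 differs from graft point")
        rebuilt = rebuild_positions(
            self.orientations, self.graft_point, self.bond_length
        )
        if np.max(np.abs(rebuilt - self.positions)) > tol:
            raise ValueError("positions inconsistent with orientations")


def init_conformation(
    params: ChainParams, graft_point=(0.0, 0.0, 0.0)
) -> Conformation:
    """Straight chain pointing along +z from the graft point."""
    graft = np.asarray(graft_point, dtype=np.float64)
    u = np.zeros((params.Nm, 3))
    u[:, 2] = 1.0
    pos = rebuild_positions(u, graft, params.bond_length)
    return Conformation(graft, pos, u, params.bond_length)


def rebuild_positions(
    orientations: np.ndarray, graft_point, bond_length: float
) -> np.ndarray:
    """Cumulative-sum positions ``r_i = r_{i-1} + b u_i`` from the graft."""
    u = np.asarray(orientations, dtype=np.float64)
    pos = np.empty((u.shape[0] + 1, 3))
    pos[0] = np.asarray(graft_point, dtype=np.float64)
    np.cumsum(u * bond_length, axis=0, out=pos[1:])
    pos[1:] += pos[0]
    return pos


def orientations_from_positions(
    positions: np.ndarray, bond_length: float
) -> np.ndarray:
    """Inverse of :func:`rebuild_positions` (finite differences / b)."""
    d = np.diff(np.asarray(positions, dtype=np.float64), axis=0)
    return d / bond_length


def bending_energy(conf: Conformation, params: ChainParams) -> float:
    """``eps * sum_i |u_{i+1} - u_i|^2`` in kT units; zero iff straight."""
    u = conf.orientations
    norms = np.linalg.norm(u, axis=1)
    if np.any(np.abs(norms - 1.0) > GEOM_TOL):
        raise ValueError("non-unit bond orientation in bending_energy")
    d = u[1:] - u[:-1]
    return float(params.epsilon * np.einsum("ij,ij->", d, d))


def end_to_end(conf: Conformation) -> np.ndarray:
    """End-to-end vector ``r_Nm - r_0``; magnitude bounded by L."""
    return conf.positions[-1] - conf.positions[0]


def dump_xyz(confs, path, comment: str = "") -> None:
    """Write conformations as multi-frame XYZ (element tag C per monomer)."""
    if isinstance(confs, Conformation):
        confs = [confs]
    with open(path, "w") as fh:
        for conf in confs:
            fh.write(f"{conf.positions.shape[0]}\n{comment}\n")
            for r in conf.positions:
                fh.write(f"C {r[0]:.10g} {r[1]:.10g} {r[2]:.10g}\n")
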