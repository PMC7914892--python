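"""Brush observables: density profile, order parameters, heights, P1, P2.

All profile observables derive from the orientation-resolved density
``rho(z, u)`` or from the sampler's per-stream accumulators.  Scalar
observables carry Monte Carlo standard errors estimated over sub-ensemble
streams (jackknife for the non-linear tilt order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .field import DensityField

__all__ = [
    "BrushProfile",
    "density_profile",
    "brush_height",
    "nematic_order",
    "tilt_order_psi",
    "tilt_order_from_stats",
    "end_distribution",
    "brush_profile",
    "p1_ratio",
    "p2_overlap",
]

HORIZONTAL_TOL = 1e-8


@dataclass
class BrushProfile:
    """Orientation-integrated brush profile and its scalar summaries."""

    z_centers: np.ndarray
    rho_z: np.ndarray
    S_z: np.ndarray
    end_dist: np.ndarray
    height: float


def density_profile(rho: DensityField) -> np.ndarray:
    """Orientation-integrated density ``rho_z[k] = sum_b rho[k,b] w_b``."""
    return rho.rho @ rho.orientation.weights


def brush_height(z_centers: np.ndarray, rho_z: np.ndarray,
                 method: str = "first_moment") -> float:
    """Brush height from a z-density profile.

    ``first_moment``: h = 2 <z> (exact for a step profile);
    ``mass98``: height below which 98% of the monomer mass sits.
    """
    rho_z = np.asarray(rho_z, dtype=float)
    total = rho_z.sum()
    if total <= 0:
        raise ValueError("zero total density")
    if method == "first_moment":
        return float(2.0 * (z_centers @ rho_z) / total)
    if method == "mass98":
        cum = np.cumsum(rho_z) / total
        k = int(np.searchsorted(cum, 0.98))
        return float(z_centers[min(k, len(z_centers) - 1)])
    raise ValueError(f"unknown height method {method!r}")


def nematic_order(source) -> np.ndarray:
    """Per-slab second-Legendre order vs the wall normal, S(z) in [-1/2, 1].

    Accepts a DensityField (orientation-binned estimate) or an EnsembleStats
    (exact per-bond accumulators).  Empty slabs are NaN, not zero.
    """
    if isinstance(source, DensityField):
        cos2 = source.orientation.directions[:, 2] ** 2
        p2 = 1.5 * cos2 - 0.5
        w = source.orientation.weights
        num = source.rho @ (p2 * w)
        den = source.rho @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return out
    # EnsembleStats-like: merged sz accumulators
    sz_sum = sum(s.sz_sum for s in source.streams)
    sz_cnt = sum(s.sz_cnt for s in source.streams)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sz_cnt > 0, sz_sum / np.where(sz_cnt > 0, sz_cnt, 1.0),
                        np.nan)


def _collect_bonds(samples) -> np.ndarray:
    rows = []
    for s in samples:
        u = getattr(s, "orientations", s)
        rows.append(np.atleast_2d(np.asarray(u, dtype=float)))
    return np.concatenate(rows, axis=0)


def tilt_order_psi(samples, axis=None) -> float:
    """Azimuthal tilt order psi = <2 cos^2 phi - 1> = <cos 2 phi>.

    ``phi`` is the azimuth of each bond's horizontal projection, measured
    from ``axis`` when given, otherwise from the emergent tilt direction
    (principal horizontal eigenvector of the bond-projection second-moment
    tensor), which makes psi well defined without an externally imposed
    direction.  Bonds with negligible horizontal projection are excluded;
    if every bond is vertical the order parameter is undefined.
    """
    u = _collect_bonds(samples)
    h2 = u[:, 0] ** 2 + u[:, 1] ** 2
    mask = h2 > HORIZONTAL_TOL ** 2
    if not np.any(mask):
        raise ValueError("tilt order undefined: all bonds are vertical")
    ux, uy, h2 = u[mask, 0], u[mask, 1], h2[mask]
    C = float(np.mean((ux ** 2 - uy ** 2) / h2))   # <cos 2 phi_raw>
    S = float(np.mean(2.0 * ux * uy / h2))         # <sin 2 phi_raw>
    if axis is None:
        return math.hypot(C, S)
    ax = np.asarray(axis, dtype=float)
    alpha = math.atan2(ax[1], ax[0])
    return C * math.cos(2 * alpha) + S * math.sin(2 * alpha)


def tilt_order_from_stats(stats):
    """(psi, stderr) from per-stream accumulators; jackknife over streams."""
    C = np.array([s.acc[4] for s in stats.streams])
    S = np.array([s.acc[5] for s in stats.streams])
    n = np.array([s.acc[6] for s in stats.streams])
    if n.sum() <= 0:
        raise ValueError("tilt order undefined: all bonds are vertical")
    psi = math.hypot(C.sum() / n.sum(), S.sum() / n.sum())
    K = len(stats.streams)
    if K < 2:
        return psi, float("nan")
    loo = []
    for k in range(K):
        m = np.arange(K) != k
        loo.append(math.hypot(C[m].sum() / n[m].sum(),
                              S[m].sum() / n[m].sum()))
    loo = np.array(loo)
    var = (K - 1) / K * np.sum((loo - loo.mean()) ** 2)
    return psi, float(math.sqrt(var))


def end_distribution(source, nz: Optional[int] = None,
                     z_edges: Optional[np.ndarray] = None) -> np.ndarray:
    """Normalized free-end z-histogram (sums to 1).

    Accepts an EnsembleStats (merged endz histogram) or an iterable of
    conformations together with ``z_edges``.
    """
    if hasattr(source, "streams"):
        h = sum(s.endz for s in source.streams).astype(float)
    else:
        if z_edges is None:
            raise ValueError("z_edges required for explicit conformations")
        ends = np.array([getattr(c, "positions")[-1, 2] for c in source])
        h, _ = np.histogram(ends, bins=z_edges)
        h = h.astype(float)
    total = h.sum()
    return h / total if total > 0 else h


def brush_profile(density: DensityField, stats=None,
                  height_method: str = "first_moment") -> BrushProfile:
    """Bundle the standard profile observables of a converged brush."""
    rho_z = density_profile(density)
    S_z = nematic_order(stats if stats is not None else density)
    end = (end_distribution(stats) if stats is not None
           else np.full_like(rho_z, np.nan))
    h = brush_height(density.z_centers, rho_z, method=height_method)
    return BrushProfile(density.z_centers, rho_z, S_z, end, h)


def p1_ratio(profile_uv_on: BrushProfile,
             profile_uv_off: BrushProfile) -> float:
    """Brush-height ratio P1 = h(UV on, cis) / h(UV off, trans)."""
    if profile_uv_off.height == 0:
        raise ValueError("reference brush height is zero")
    return profile_uv_on.height / profile_uv_off.height


def p2_overlap(end_I: np.ndarray, end_II: np.ndarray, dz: float) -> float:
    """End-overlap statistic P2 = integral dz phi_end,I(z) phi_end,II(z).

    Both distributions are normalized histograms on a common uniform grid
    spanning [0, D]; brush II is grafted at z = D, so its end distribution
    is mirrored (z -> D - z) before the discretized overlap
    ``sum_k end_I[k] end_II_mirrored[k] / dz`` is taken.
    """
    end_I = np.asarray(end_I, dtype=float)
    end_II = np.asarray(end_II, dtype=float)
    if end_I.shape != end_II.shape:
        raise ValueError("end-distribution binning mismatch")
    return float(np.sum(end_I * end_II[::-1]) / dz)
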