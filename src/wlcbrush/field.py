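"""Auxiliary field, density, Onsager kernel, and the self-consistent loop.

The brush is laterally homogeneous, so the auxiliary field and the density
depend on height z and bond orientation u only.  Both are tabulated on a
product grid: ``Nz`` uniform z-slabs on ``[0, z_max]`` times an orientation
grid on the unit sphere (Gauss-Legendre nodes in cos(theta) crossed with
uniform midpoints in phi; the quadrature weights sum to 4*pi exactly and
integrate the second Legendre polynomial exactly, which the band-midpoint rule
does not).

The excluded-volume coupling between bond orientations takes Onsager's form
``|u x u'| = sin(gamma)``; at the mean-field saddle point the (real) field is

    omega(z, u) = (2d/a^2) * integral du' |u x u'| rho(z, u'),

discretized as a matrix-vector product per slab.  For the planar brush only
the dimensionless combination ``2 d a sigma`` is physical, so the grafting
density is fixed at sigma = 1 internally and the kernel prefactor carries the
whole coupling.

The self-consistent loop alternates Monte Carlo sampling of the single
grafted chain in the frozen field with a density re-estimate and a simple
linear field mixing, judged by the relative max-norm field residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .chain import ChainParams

__all__ = [
    "OrientationGrid",
    "FieldGrid",
    "DensityField",
    "OnsagerKernel",
    "build_orientation_grid",
    "build_onsager_kernel",
    "update_field",
    "accumulate_density",
    "density_from_counts",
    "lookup_field",
    "mix_fields",
    "scf_iterate",
    "compression_sweep",
    "SCFResult",
    "SCFDivergence",
]

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class OrientationGrid:
    """Quadrature grid on the unit sphere.

    ``directions`` is ``(Ntheta*Nphi, 3)`` with bin b = itheta*Nphi + iphi;
    ``weights`` are the matching solid-angle weights (Gauss-Legendre in
    cos(theta) times ``2 pi / Nphi``), summing to 4*pi.
    """

    directions: np.ndarray
    weights: np.ndarray
    ntheta: int
    nphi: int
    cos_nodes: np.ndarray
    cos_inner_edges: np.ndarray  # boundaries between adjacent theta bands

    @property
    def n_bins(self) -> int:
        return self.directions.shape[0]

    def inversion_map(self) -> np.ndarray:
        """Bin permutation implementing u -> -u (requires even Nphi)."""
        if self.nphi % 2:
            raise ValueError("u -> -u closure requires an even Nphi")
        b = np.arange(self.n_bins)
        it, ip = divmod(b, self.nphi)
        return (self.ntheta - 1 - it) * self.nphi \
            + (ip + self.nphi // 2) % self.nphi

    def bin_index(self, u) -> np.ndarray:
        """Nearest-bin assignment of unit vector(s) u (vectorized)."""
        u = np.atleast_2d(np.asarray(u, dtype=np.float64))
        it = np.searchsorted(self.cos_inner_edges, u[:, 2])
        phi = np.arctan2(u[:, 1], u[:, 0])
        phi = np.where(phi < 0, phi + 2 * np.pi, phi)
        ip = np.minimum((phi * self.nphi / (2 * np.pi)).astype(np.intp),
                        self.nphi - 1)
        out = it * self.nphi + ip
        return out if out.size > 1 else out[0]


def build_orientation_grid(ntheta: int, nphi: int) -> OrientationGrid:
    """Gauss-Legendre (cos theta) x uniform-midpoint (phi) sphere grid."""
    if ntheta < 2 or nphi < 4:
        raise ValueError("need ntheta >= 2 and nphi >= 4")
    nodes, wts = np.polynomial.legendre.leggauss(ntheta)
    order = np.argsort(nodes)          # ascending in cos(theta)
    nodes, wts = nodes[order], wts[order]
    phis = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
    sin_t = np.sqrt(np.clip(1.0 - nodes ** 2, 0.0, None))
    dirs = np.empty((ntheta * nphi, 3))
    w = np.empty(ntheta * nphi)
    for i in range(ntheta):
        sl = slice(i * nphi, (i + 1) * nphi)
        dirs[sl, 0] = sin_t[i] * np.cos(phis)
        dirs[sl, 1] = sin_t[i] * np.sin(phis)
        dirs[sl, 2] = nodes[i]
        w[sl] = wts[i] * 2 * np.pi / nphi
    inner = 0.5 * (nodes[:-1] + nodes[1:])
    return OrientationGrid(dirs, w, ntheta, nphi, nodes, inner)


@dataclass
class FieldGrid:
    """Auxiliary field omega(z, u) on the z x orientation grid (kT units)."""

    z_edges: np.ndarray            # (Nz+1,), uniform, starting at 0
    orientation: OrientationGrid
    omega: np.ndarray              # (Nz, Norient)

    @property
    def nz(self) -> int:
        return self.z_edges.shape[0] - 1

    @property
    def dz(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    @property
    def z_max(self) -> float:
        return float(self.z_edges[-1])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @classmethod
    def zeros(cls, nz: int, z_max: float, grid: OrientationGrid) -> "FieldGrid":
        edges = np.linspace(0.0, z_max, nz + 1)
        return cls(edges, grid, np.zeros((nz, grid.n_bins)))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("non-finite field values")
        if self.omega.shape != (self.nz, self.orientation.n_bins):
            raise ValueError("field shape mismatch")


@dataclass
class DensityField:
    """Density rho(z, u), monomers per (volume x solid angle), A = 1."""

    rho: np.ndarray                # (Nz, Norient)
    z_edges: np.ndarray
    orientation: OrientationGrid
    sigma: float = 1.0
    area: float = 1.0

    @property
    def dz(self) -> float:
        return float(self.z_edges[1] - self.z_edges[0])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def total(self) -> float:
        """sum rho dz dOmega; equals sigma*N for a valid estimate."""
        return float(self.rho.sum(axis=0) @ self.orientation.weights * self.dz)


@dataclass(frozen=True)
class OnsagerKernel:
    """K[a, b] = prefactor * |u_a x u_b| * w_b, prefactor = 2d/a^2 / sigma-fold.

    Only the product 2*d*a*sigma is physical for the planar brush; with a = 1
    and sigma = 1 the prefactor equals the effective grafting density.
    """

    matrix: np.ndarray
    prefactor: float


def build_onsager_kernel(grid: OrientationGrid,
                         prefactor: float) -> OnsagerKernel:
    """Precompute the orientation-coupling matrix sin(gamma_ab) w_b."""
    d = grid.directions
    cross = np.cross(d[:, None, :], d[None, :, :])
    singamma = np.sqrt(np.einsum("abk,abk->ab", cross, cross))
    np.fill_diagonal(singamma, 0.0)
    return OnsagerKernel(prefactor * singamma * grid.weights[None, :],
                         prefactor)


def update_field(rho: DensityField, kernel: OnsagerKernel) -> np.ndarray:
    """omega[k, a] = sum_b K[a, b] rho[k, b]; linear and non-negative."""
    if rho.rho.shape[1] != kernel.matrix.shape[1]:
        raise ValueError("density / kernel orientation-bin mismatch")
    return rho.rho @ kernel.matrix.T


def density_from_counts(counts: np.ndarray, z_edges: np.ndarray,
                        grid: OrientationGrid, sigma: float,
                        params: ChainParams, n_samples: int) -> DensityField:
    """Scale a raw (z, orientation) midpoint histogram to a density.

    Each of the ``n_samples * Nm`` binned bond midpoints carries weight
    ``sigma N / (M Nm)`` (the Eq.-style single-chain estimator), divided by
    the cell volume ``dz * w_b`` so that sum rho dz dOmega = sigma*N exactly.
    """
    if n_samples < 1:
        raise ValueError("need at least one recorded sample")
    dz = z_edges[1] - z_edges[0]
    scale = sigma * params.N / (n_samples * params.Nm)
    rho = counts * (scale / dz) / grid.weights[None, :]
    return DensityField(rho, z_edges, grid, sigma)


def accumulate_density(samples, z_edges, grid: OrientationGrid, sigma: float,
                       params: ChainParams) -> DensityField:
    """Histogram bond midpoints of explicit conformations into a density."""
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one recorded conformation")
    nz = z_edges.shape[0] - 1
    dz = z_edges[1] - z_edges[0]
    counts = np.zeros((nz, grid.n_bins))
    for conf in samples:
        mid = 0.5 * (conf.positions[:-1] + conf.positions[1:])
        if np.any(mid[:, 2] >= z_edges[-1]):
            raise ValueError("monomer above z_max; enlarge the grid")
        kb = np.clip((mid[:, 2] / dz).astype(np.intp), 0, nz - 1)
        ob = np.atleast_1d(grid.bin_index(conf.orientations))
        np.add.at(counts, (kb, ob), 1.0)
    return density_from_counts(counts, z_edges, grid, sigma, params,
                               len(samples))


def lookup_field(fieldgrid: FieldGrid, position, orientation) -> float:
    """omega at a point: linear interpolation in z, nearest orientation bin."""
    z = float(np.asarray(position, dtype=float).reshape(-1)[-1]) \
        if np.ndim(position) else float(position)
    if z < 0 or z > fieldgrid.z_max:
        raise ValueError(f"z = {z} outside the field grid [0, {fieldgrid.z_max}]")
    ob = int(fieldgrid.orientation.bin_index(orientation))
    nz, dz = fieldgrid.nz, fieldgrid.dz
    x = z / dz - 0.5
    if x <= 0.0:
        return float(fieldgrid.omega[0, ob])
    if x >= nz - 1:
        return float(fieldgrid.omega[nz - 1, ob])
    i0 = int(x)
    f = x - i0
    return float(fieldgrid.omega[i0, ob] * (1 - f)
                 + fieldgrid.omega[i0 + 1, ob] * f)


def mix_fields(omega_old: np.ndarray, omega_new: np.ndarray, lam: float):
    """Linear mixing; residual = max|new - old| / max|new| (0 if both zero)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("mixing parameter must be in [0, 1]")
    diff = np.max(np.abs(omega_new - omega_old))
    scale = max(np.max(np.abs(omega_new)), np.max(np.abs(omega_old)))
    residual = diff / scale if scale > 0 else 0.0
    return (1.0 - lam) * omega_old + lam * omega_new, residual


class SCFDivergence(RuntimeError):
    """Raised when the field residual grows persistently; carries the trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class SCFResult:
    field: FieldGrid
    density: DensityField
    stats: "EnsembleStats"          # noqa: F821  (sampler.EnsembleStats)
    trace: list
    status: str                     # "converged" | "max_iter"
    chains: Optional[list] = dc_field(default=None, repr=False)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def scf_iterate(params: ChainParams, brush, grids, schedule, seeds=None,
                base_seed: int = 0, warm_field: Optional[np.ndarray] = None,
                warm_chains=None, callback=None) -> SCFResult:
    """Self-consistent alternation of sampling, density estimate, and mixing.

    Parameters
    ----------
    brush : sampler.BrushConfig
    grids : FieldGrid (used for its z/orientation layout; its omega is the
        starting field unless ``warm_field`` overrides it)
    schedule : dict-like with keys m_per_iter (cap M), lam, tol, max_iter,
        and optionally m_start (initial M, doubled per iteration up to the
        cap), streams, burn_in, burn_in_warm, stride, max_angle, and n_avg
        (report the density and observables merged over the last n_avg
        iterations instead of the final one alone; near the fixed point this
        averages sampling noise and any residual under-damped field
        oscillation out of the reported profile).
    """
    from .sampler import sample_ensemble, stream_seeds  # cycle-free at runtime

    m_max = int(schedule["m_per_iter"])
    lam = float(schedule.get("lam", 0.2))
    tol = float(schedule.get("tol", 1e-3))
    max_iter = int(schedule.get("max_iter", 60))
    m_start = int(schedule.get("m_start", max(1, m_max // 8)))
    K = int(schedule.get("streams", 4))
    samp_kw = {
        "burn_in": int(schedule.get("burn_in", 100)),
        "stride": float(schedule.get("stride", 1.0)),
        "max_angle": float(schedule.get("max_angle", np.pi / 2)),
    }
    burn_warm = int(schedule.get("burn_in_warm",
                                 max(10, samp_kw["burn_in"] // 5)))
    n_avg = int(schedule.get("n_avg", 1))

    kernel = build_onsager_kernel(grids.orientation, brush.sigma_eff)
    omega = grids.omega.copy() if warm_field is None else warm_field.copy()
    chains = warm_chains
    trace = []
    resid0 = None
    n_grow = 0
    status = "max_iter"
    density = stats = None
    window = []                # trailing (stats, m) for the reported density
    for it in range(max_iter):
        m_it = min(m_max, m_start * (2 ** it))
        kw = dict(samp_kw)
        if chains is not None:
            kw["burn_in"] = burn_warm
        fg = FieldGrid(grids.z_edges, grids.orientation, omega)
        it_seeds = (seeds if seeds is not None
                    else stream_seeds(base_seed, it, K))
        density, stats, chains = sample_ensemble(
            fg, params, brush, m_it, seeds=it_seeds, init_chains=chains,
            **kw)
        rho_eff = density
        if getattr(brush, "opposing_D", None) is not None:
            # symmetric opposing brush at z = D: its mirrored density
            # (z -> D - z, u -> -u) adds to the excluded-volume field
            inv = grids.orientation.inversion_map()
            mirrored = density.rho[::-1][:, inv]
            rho_eff = DensityField(density.rho + mirrored, density.z_edges,
                                   density.orientation, density.sigma)
        omega_new = update_field(rho_eff, kernel)
        omega, residual = mix_fields(omega, omega_new, lam)
        noise = stats.field_noise_proxy(kernel)
        trace.append({"iter": it, "m": m_it, "residual": residual,
                      "noise": noise,
                      "acceptance": stats.acceptance_ratio})
        if callback is not None:
            callback(trace[-1])
        if resid0 is None:
            resid0 = residual
        if residual > 10.0 * max(resid0, 1e-30):
            n_grow += 1
            if n_grow >= 5:
                raise SCFDivergence(
                    f"field residual diverged at iteration {it}", trace)
        else:
            n_grow = 0
        window.append(stats)
        if len(window) > n_avg:
            window.pop(0)
        if residual < tol and m_it >= m_max:
            status = "converged"
            break
    if n_avg > 1 and len(window) > 1:
        from .sampler import EnsembleStats
        merged_streams = [s for st in window for s in st.streams]
        stats = EnsembleStats(merged_streams, grids.z_edges,
                              grids.orientation, params)
        density = stats.density()
    final = FieldGrid(grids.z_edges, grids.orientation, omega)
    return SCFResult(final, density, stats, trace, status, chains)


def compression_sweep(params: ChainParams, brush, grids, schedule,
                      H_schedule, base_seed: int = 0, callback=None):
    """Warm-started chain of SCF solves along a compression/relaxation path.

    ``H_schedule`` is traversed in order (descending then ascending for a
    hysteresis loop); each solve warm-starts from the previous converged
    field and chain states.  ``schedule`` is either one schedule dict shared
    by all points or a sequence with one dict per H.  Returns a list of
    records ``{"H", "result", "psi", "psi_err", "height"}`` in schedule
    order.
    """
    from dataclasses import replace as dc_replace

    from .observables import brush_profile, tilt_order_from_stats

    if isinstance(schedule, dict):
        schedules = [schedule] * len(H_schedule)
    else:
        schedules = list(schedule)
        if len(schedules) != len(H_schedule):
            raise ValueError("one schedule per H value required")
    records = []
    warm_field = None
    warm_chains = None
    for i, H in enumerate(H_schedule):
        b = dc_replace(brush, compression_H=(None if H is None else float(H)))
        res = scf_iterate(params, b, grids, schedules[i],
                          base_seed=base_seed + 7919 * i,
                          warm_field=warm_field, warm_chains=warm_chains,
                          callback=callback)
        warm_field = res.field.omega
        # chains from a different H may violate the new wall; re-check and
        # drop offenders (they are re-initialized inside the sampler)
        warm_chains = res.chains
        psi, psi_err = tilt_order_from_stats(res.stats)
        prof = brush_profile(res.density, res.stats)
        records.append({"H": H, "result": res, "psi": psi,
                        "psi_err": psi_err, "height": prof.height})
    return records
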