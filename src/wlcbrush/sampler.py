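"""Metropolis pivot Monte Carlo for a grafted worm-like chain in a field.

A trial move picks a pivot monomer uniformly, a rotation axis uniformly on
the sphere, and a rotation angle uniformly in ``(-max_angle, max_angle]``,
then rotates every bond between the pivot and the free end rigidly
(Rodrigues' formula).  The move is accepted with probability
``min{1, exp(-dE)}`` where ``dE`` combines the bending-energy change at the
single altered joint and the auxiliary-field change of the rotated tail.
The impenetrable grafting wall (and the optional compression wall at z = H)
is enforced by rejecting violating proposals, which is equivalent to an
infinite wall potential inside the Metropolis rule.

Sampling is organised into independent sub-ensembles ("streams"), each with
its own seeded generator; merging is a pure reduction of histograms and
counters, so results are bit-reproducible for fixed seeds and stream count.

This module keeps a pure-Python reference implementation of every step
(`pivot_move`, `delta_energy`, `metropolis_accept`, ...) alongside the
compiled production path; both consume identical uniform variates, which the
tests exploit for exact cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import _core
from .chain import (ChainParams, Conformation, bending_energy,
                    rebuild_positions)
from .field import (DensityField, FieldGrid, OrientationGrid,
                    density_from_counts, lookup_field)

__all__ = [
    "AzoConfig",
    "BrushConfig",
    "SamplerState",
    "StreamStats",
    "EnsembleStats",
    "rotation_matrix",
    "pivot_move",
    "propose",
    "field_energy",
    "delta_energy",
    "metropolis_accept",
    "check_constraints",
    "azo_pivot",
    "re_kink",
    "switch_isomer",
    "stream_seeds",
    "sample_ensemble",
    "sample_free_chain",
]

ANGLE_TOL = 1e-9


@dataclass(frozen=True)
class AzoConfig:
    """Photoswitchable azo joint at relative contour position f.

    ``alpha_trans``/``alpha_cis`` are the chemical bond angles of the two
    isomers (pi = straight under the chemistry convention adopted here, so
    the geometric kink between consecutive tangents is ``pi - alpha``).
    """

    f: float
    state: str = "trans"
    alpha_trans: float = math.pi
    alpha_cis: float = math.pi / 3

    def __post_init__(self):
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"azo position f must be in (0,1), got {self.f}")
        if self.state not in ("trans", "cis"):
            raise ValueError(f"azo state must be trans|cis, got {self.state}")

    @property
    def alpha(self) -> float:
        return self.alpha_trans if self.state == "trans" else self.alpha_cis

    @property
    def kink_angle(self) -> float:
        """Angle between the tangents flanking the azo joint."""
        return math.pi - self.alpha

    def bond_index(self, Nm: int) -> int:
        """Array index of the bond *after* the azo joint (1..Nm-1)."""
        return int(np.clip(round(self.f * Nm), 1, Nm - 1))

    def switched(self) -> "AzoConfig":
        other = "cis" if self.state == "trans" else "trans"
        return replace(self, state=other)


@dataclass(frozen=True)
class BrushConfig:
    """Planar-brush parameters: coupling, walls, optional azo joint."""

    sigma_eff: float                       # effective grafting density 2*d*a*sigma
    compression_H: Optional[float] = None  # upper wall height
    azo: Optional[AzoConfig] = None
    opposing_D: Optional[float] = None     # separation for two-brush runs

    def __post_init__(self):
        if not self.sigma_eff >= 0:
            raise ValueError("sigma_eff must be non-negative")
        if self.compression_H is not None and not self.compression_H > 0:
            raise ValueError("compression_H must be positive")
        if self.opposing_D is not None and not self.opposing_D > 0:
            raise ValueError("opposing_D must be positive")

    @property
    def upper_wall(self) -> float:
        """Effective upper wall (inf when uncompressed)."""
        H = np.inf
        if self.compression_H is not None:
            H = min(H, self.compression_H)
        if self.opposing_D is not None:
            H = min(H, self.opposing_D)
        return H

    def active_azo_index(self, Nm: int) -> int:
        """Kernel-facing azo bond index, or -1 when unconstrained.

        A trans joint with a zero kink imposes no geometric constraint, so
        the sampler treats the chain exactly like an unmodified one (the
        compiled path is then bit-identical to the plain brush for equal
        seeds).
        """
        if self.azo is None or abs(self.azo.kink_angle) < ANGLE_TOL:
            return -1
        return self.azo.bond_index(Nm)


@dataclass
class SamplerState:
    """Bookkeeping for one Metropolis stream."""

    current: Conformation
    rng_stream: object = None
    n_proposed: int = 0
    n_accepted: int = 0
    burn_in: int = 100
    stride: float = 5.0
    max_pivot_angle: float = math.pi / 2

    @property
    def acceptance_ratio(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else np.nan


# ---------------------------------------------------------------------------
# reference (pure Python) operations
# ---------------------------------------------------------------------------

def rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    n = np.asarray(axis, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("rotation axis must be a unit vector")
    ct, st = math.cos(angle), math.sin(angle)
    K = np.array([[0.0, -n[2], n[1]],
                  [n[2], 0.0, -n[0]],
                  [-n[1], n[0], 0.0]])
    return ct * np.eye(3) + (1.0 - ct) * np.outer(n, n) + st * K


def pivot_move(conf: Conformation, pivot_index: int, axis,
               angle: float) -> Conformation:
    """Rotate bonds ``pivot_index..Nm`` (1-based) about node r_{pivot-1}.

    Returns a new conformation; the input is not mutated.
    """
    Nm = conf.Nm
    if not 1 <= pivot_index <= Nm:
        raise ValueError(f"pivot_index must be in 1..{Nm}")
    R = rotation_matrix(axis, angle)
    p = pivot_index - 1
    u = conf.orientations.copy()
    tail = u[p:] @ R.T
    tail /= np.linalg.norm(tail, axis=1, keepdims=True)
    u[p:] = tail
    new = conf.copy()
    new.orientations = u
    new.positions = rebuild_positions(u, conf.graft_point, conf.bond_length)
    return new


def propose(conf: Conformation, params: ChainParams, rng,
            max_angle: float = math.pi / 2,
            azo_idx: int = -1):
    """Draw one pivot proposal (same variate layout as the compiled kernel).

    Returns ``(proposed, meta)`` with meta = dict(pivot_index, axis, angle,
    accept_uniform).
    """
    r = rng.random(5)
    p = min(int(r[0] * params.Nm), params.Nm - 1)
    if azo_idx >= 0 and p == azo_idx:
        axis = conf.orientations[p - 1].copy()
    else:
        cz = 2.0 * r[1] - 1.0
        s = math.sqrt(max(0.0, 1.0 - cz * cz))
        aphi = 2.0 * math.pi * r[2]
        axis = np.array([s * math.cos(aphi), s * math.sin(aphi), cz])
    angle = (2.0 * r[3] - 1.0) * max_angle
    proposed = pivot_move(conf, p + 1, axis, angle)
    meta = {"pivot_index": p + 1, "axis": axis, "angle": angle,
            "accept_uniform": r[4]}
    return proposed, meta


def field_energy(conf: Conformation, fieldgrid: FieldGrid,
                 params: ChainParams) -> float:
    """``(N/Nm) sum_i omega(z_i, u_i)`` with positions taken at bond
    midpoints (the same pairing the density estimator uses)."""
    mid = 0.5 * (conf.positions[:-1] + conf.positions[1:])
    total = 0.0
    for z, u in zip(mid[:, 2], conf.orientations):
        total += lookup_field(fieldgrid, z, u)
    return params.N / params.Nm * total


def delta_energy(current: Conformation, proposed: Conformation,
                 fieldgrid: Optional[FieldGrid],
                 params: ChainParams) -> float:
    """Bending + field energy difference of a trial move."""
    dE = bending_energy(proposed, params) - bending_energy(current, params)
    if fieldgrid is not None:
        dE += (field_energy(proposed, fieldgrid, params)
               - field_energy(current, fieldgrid, params))
    return dE


def metropolis_accept(deltaE: float, rng) -> bool:
    """Accept with probability min{1, exp(-dE)}; always consumes one uniform
    so parallel decision paths stay stream-aligned."""
    if math.isnan(deltaE):
        raise ValueError("NaN energy change in Metropolis step")
    r = rng.random()
    if deltaE <= 0.0:
        return True
    if math.isinf(deltaE):
        return False
    return r < math.exp(-deltaE)


def check_constraints(conf: Conformation, brush: BrushConfig) -> str:
    """Classify a conformation: 'ok' | 'wall' | 'compression' | 'azo'.

    The graft node sits at z = 0 and is exempt from the wall test.
    """
    z = conf.positions[1:, 2]
    if np.any(z <= 0.0):
        return "wall"
    H = brush.upper_wall
    if np.isfinite(H) and np.any(z >= H):
        return "compression"
    if brush.azo is not None:
        j = brush.azo.bond_index(conf.Nm)
        cosang = float(np.dot(conf.orientations[j - 1], conf.orientations[j]))
        target = math.cos(brush.azo.kink_angle)
        if abs(cosang - target) > 1e-7:
            return "azo"
    return "ok"


def azo_pivot(conf: Conformation, brush: BrushConfig, rng,
              max_angle: float = math.pi) -> Conformation:
    """Kink-preserving pivot at the azo joint: rotation about the preceding
    bond re-orients the tail on the cone of fixed kink angle."""
    if brush.azo is None:
        raise ValueError("azo joint not configured")
    j = brush.azo.bond_index(conf.Nm)
    axis = conf.orientations[j - 1] / np.linalg.norm(conf.orientations[j - 1])
    angle = (2.0 * rng.random() - 1.0) * max_angle
    return pivot_move(conf, j + 1, axis, angle)


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    c = float(np.clip(np.dot(a, b), -1.0, 1.0))
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-12:
            perp = np.cross(a, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        return rotation_matrix(perp, math.pi)
    return rotation_matrix(axis / n, math.atan2(n, c))


def re_kink(conf: Conformation, brush: BrushConfig,
            azimuth: float = 0.0) -> Conformation:
    """Deterministically set the azo-joint angle to the configured kink.

    The bond after the joint is placed on the cone of the target kink angle
    about the preceding bond at the given azimuth; all later bonds follow
    rigidly (their mutual angles are preserved).
    """
    if brush.azo is None:
        raise ValueError("azo joint not configured")
    j = brush.azo.bond_index(conf.Nm)
    u_prev = conf.orientations[j - 1]
    # deterministic cone frame: e1 perpendicular to u_prev
    e1 = np.cross(u_prev, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.cross(u_prev, [1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u_prev, e1)
    k = brush.azo.kink_angle
    target = (math.cos(k) * u_prev
              + math.sin(k) * (math.cos(azimuth) * e1
                               + math.sin(azimuth) * e2))
    R = _align_rotation(conf.orientations[j] /
                        np.linalg.norm(conf.orientations[j]), target)
    u = conf.orientations.copy()
    tail = u[j:] @ R.T
    tail /= np.linalg.norm(tail, axis=1, keepdims=True)
    u[j:] = tail
    new = conf.copy()
    new.orientations = u
    new.positions = rebuild_positions(u, conf.graft_point, conf.bond_length)
    return new


def switch_isomer(conf: Conformation, brush: BrushConfig):
    """Trans<->cis switch: flip the configured isomer state and re-kink the
    joint deterministically (several cone azimuths are tried until the walls
    are satisfied).  Returns ``(new_conf, new_brush)``; the caller is expected
    to re-equilibrate afterwards."""
    if brush.azo is None:
        raise ValueError("azo joint not configured")
    new_brush = replace(brush, azo=brush.azo.switched())
    for azimuth in np.linspace(0.0, 2 * math.pi, 16, endpoint=False):
        cand = re_kink(conf, new_brush, azimuth=azimuth)
        if check_constraints(cand, new_brush) == "ok":
            return cand, new_brush
    raise RuntimeError("could not re-kink without violating the walls")


# ---------------------------------------------------------------------------
# production sampling (compiled path)
# ---------------------------------------------------------------------------

def stream_seeds(base_seed: int, iteration: int, K: int):
    """Deterministic per-stream seed material (SeedSequence keys)."""
    return [np.random.SeedSequence((int(base_seed), int(iteration), k))
            for k in range(K)]


@dataclass
class StreamStats:
    """Raw accumulators of one sub-ensemble stream."""

    counts: np.ndarray          # (Nz, Norient) midpoint histogram
    endz: np.ndarray            # (Nz,) free-end histogram
    sz_sum: np.ndarray
    sz_cnt: np.ndarray
    acc: np.ndarray             # scalar accumulators (see _core.run_mc)
    n_samples: int
    n_proposed: int
    n_accepted: int
    max_angle: float
    joint_series: Optional[np.ndarray] = None
    end_series: Optional[np.ndarray] = None

    @property
    def acceptance_ratio(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else np.nan


@dataclass
class EnsembleStats:
    """Merged sub-ensemble accumulators plus per-stream detail.

    Merging is a pure reduction (sums of histograms and counters), so the
    pooled result is independent of how samples were split across streams.
    """

    streams: list
    z_edges: np.ndarray
    orientation: OrientationGrid
    params: ChainParams
    sigma: float = 1.0

    # -- merged raw arrays -------------------------------------------------
    @property
    def counts(self) -> np.ndarray:
        return sum(s.counts for s in self.streams)

    @property
    def endz(self) -> np.ndarray:
        return sum(s.endz for s in self.streams)

    @property
    def n_samples(self) -> int:
        return int(sum(s.n_samples for s in self.streams))

    @property
    def acceptance_ratio(self) -> float:
        nprop = sum(s.n_proposed for s in self.streams)
        nacc = sum(s.n_accepted for s in self.streams)
        return nacc / nprop if nprop else np.nan

    @property
    def acceptance_per_stream(self):
        return [s.acceptance_ratio for s in self.streams]

    # -- scalar observables with stream-level errors -----------------------
    def _stream_means(self, idx: int) -> np.ndarray:
        return np.array([s.acc[idx] / s.acc[7] for s in self.streams])

    def bond_correlation(self, lag: int = 1):
        """(mean, stderr) of the contour-averaged bond correlation
        <u_i . u_{i+lag}> for lag in {1, 2, 3}."""
        idx = {1: 0, 2: 8, 3: 9}[lag]
        m = self._stream_means(idx)
        return float(np.mean(m)), float(np.std(m, ddof=1) / math.sqrt(len(m))
                                        if len(m) > 1 else np.nan)

    def end_to_end_sq(self):
        """(mean, stderr) of the squared end-to-end distance."""
        m = self._stream_means(2)
        return float(np.mean(m)), float(np.std(m, ddof=1) / math.sqrt(len(m))
                                        if len(m) > 1 else np.nan)

    def joint_series(self) -> np.ndarray:
        parts = [s.joint_series for s in self.streams
                 if s.joint_series is not None]
        if not parts:
            raise ValueError("joint-angle series was not recorded")
        return np.concatenate(parts)

    def density(self) -> DensityField:
        return density_from_counts(self.counts, self.z_edges,
                                   self.orientation, self.sigma,
                                   self.params, self.n_samples)

    def end_autocorrelation_time(self, max_lag: int = 200) -> float:
        """Integrated autocorrelation time (in recorded samples) of the
        free-end height, averaged over streams; 0.5 means uncorrelated."""
        taus = []
        for s in self.streams:
            x = s.end_series
            if x is None or x.size < 10:
                continue
            x = x - x.mean()
            var = float(x @ x) / x.size
            if var <= 0:
                continue
            tau = 0.5
            for lag in range(1, min(max_lag, x.size // 2)):
                c = float(x[:-lag] @ x[lag:]) / ((x.size - lag) * var)
                if c <= 0:
                    break
                tau += c
            taus.append(tau)
        return float(np.mean(taus)) if taus else float("nan")

    def field_noise_proxy(self, kernel) -> float:
        """Sampling-noise floor estimate for the field residual: relative
        max-difference between fields from the two half-ensembles."""
        K = len(self.streams)
        if K < 2:
            return float("nan")
        half = K // 2
        args = (self.z_edges, self.orientation, self.sigma, self.params)
        cA = sum(s.counts for s in self.streams[:half])
        cB = sum(s.counts for s in self.streams[half:])
        nA = sum(s.n_samples for s in self.streams[:half])
        nB = sum(s.n_samples for s in self.streams[half:])
        dA = density_from_counts(cA, *args[:2], self.sigma, self.params, nA)
        dB = density_from_counts(cB, *args[:2], self.sigma, self.params, nB)
        oA = dA.rho @ kernel.matrix.T
        oB = dB.rho @ kernel.matrix.T
        scale = max(np.max(np.abs(oA + oB)) / 2.0, 1e-300)
        return float(np.max(np.abs(oA - oB)) / (2.0 * scale))


def _init_orientations(params: ChainParams, brush: Optional[BrushConfig]):
    """Constraint-satisfying initial chain: straight up, or a tilted rod that
    fits under the upper wall, with the azo kink imposed when configured."""
    u = np.zeros((params.Nm, 3))
    u[:, 2] = 1.0
    H = brush.upper_wall if brush is not None else np.inf
    if np.isfinite(H) and params.contour_length >= H:
        ct = 0.9 * H / params.contour_length
        st = math.sqrt(1.0 - ct * ct)
        u[:, 0] = st
        u[:, 2] = ct
    if brush is not None and brush.active_azo_index(params.Nm) >= 0:
        conf = Conformation(np.zeros(3),
                            rebuild_positions(u, np.zeros(3),
                                              params.bond_length),
                            u, params.bond_length)
        for azimuth in np.linspace(0.0, 2 * math.pi, 16, endpoint=False):
            cand = re_kink(conf, brush, azimuth=azimuth)
            if check_constraints(cand, brush) == "ok":
                return cand.orientations
        raise RuntimeError("no wall-respecting kinked initial chain found")
    return u


def _run_stream(omega: np.ndarray, dz: float, nz: int,
                grid: OrientationGrid, params: ChainParams,
                use_wall: bool, H: float, azo_idx: int, use_field: bool,
                m_rec: int, burn_in_sweeps: int, stride_pivots: int,
                max_angle: float, seed, init_u=None, joint_idx: int = -1,
                adapt: bool = True) -> StreamStats:
    rng = np.random.default_rng(seed)
    Nm = params.Nm
    b = params.bond_length
    eps = params.epsilon
    fscale = params.N / params.Nm
    u = np.array(init_u, dtype=np.float64, copy=True)
    pos = rebuild_positions(u, np.zeros(3), b)
    unew = np.empty_like(u)
    nbins = grid.n_bins
    dens = np.zeros((nz, nbins))
    endz = np.zeros(nz)
    sz_sum = np.zeros(nz)
    sz_cnt = np.zeros(nz)
    acc = np.zeros(10)
    joint_series = (np.empty(m_rec) if joint_idx >= 0
                    else np.empty(1))
    end_series = np.empty(m_rec)
    common = (u, pos, unew, b, eps, fscale, use_field, omega, dz, nz,
              grid.cos_inner_edges, grid.nphi, use_wall, H, azo_idx)
    # burn-in with acceptance-targeted angle adaptation (30-50%), then the
    # cap is frozen so recording obeys detailed balance
    block = 5 * Nm
    n_blocks = max(1, -(-burn_in_sweeps * Nm // block))
    for _ in range(n_blocks):
        rnd = rng.random((block, 5))
        na = _core.run_mc(*common, max_angle, rnd, block + 1, False,
                          dens, endz, sz_sum, sz_cnt, acc,
                          joint_series, -1, end_series)
        if adapt:
            ratio = na / block
            if ratio > 0.5:
                max_angle = min(math.pi, max_angle * 1.25)
            elif ratio < 0.3:
                max_angle = max(1e-3, max_angle * 0.8)
    n_prop = 0
    n_acc = 0
    done = 0
    chunk_cap = max(1, 500_000 // max(stride_pivots, 1))
    while done < m_rec:
        nrec = min(m_rec - done, chunk_cap)
        rnd = rng.random((nrec * stride_pivots, 5))
        js = joint_series[done:done + nrec] if joint_idx >= 0 else joint_series
        na = _core.run_mc(*common, max_angle, rnd, stride_pivots, True,
                          dens, endz, sz_sum, sz_cnt, acc, js, joint_idx,
                          end_series[done:done + nrec])
        n_prop += rnd.shape[0]
        n_acc += na
        done += nrec
    return StreamStats(dens, endz, sz_sum, sz_cnt, acc, m_rec, n_prop,
                       n_acc, max_angle,
                       joint_series if joint_idx >= 0 else None,
                       end_series), u


def sample_ensemble(fieldgrid: FieldGrid, params: ChainParams,
                    brush: Optional[BrushConfig], M: int,
                    seeds: Sequence, init_chains=None,
                    burn_in: int = 100, stride: float = 5.0,
                    max_angle: float = math.pi / 2,
                    joint_idx: int = -1):
    """Sample M conformations split over one stream per seed.

    Returns ``(DensityField, EnsembleStats, final_orientations)``; the final
    per-stream orientations allow warm-starting the next field iteration.
    """
    seeds = list(seeds)
    K = len(seeds)
    if K == 0:
        raise ValueError("empty seed list")
    if M < K:
        raise ValueError(f"M = {M} smaller than the number of streams {K}")
    fieldgrid.validate()
    use_wall = brush is not None
    H = brush.upper_wall if use_wall else np.inf
    reachable = min(params.contour_length, H)
    if fieldgrid.z_max < reachable:
        raise ValueError("field grid must cover the reachable height "
                         f"(z_max = {fieldgrid.z_max} < {reachable})")
    azo_idx = brush.active_azo_index(params.Nm) if use_wall else -1
    use_field = bool(np.any(fieldgrid.omega))
    stride_pivots = max(1, int(round(stride * params.Nm)))
    per = [M // K + (1 if k < M % K else 0) for k in range(K)]
    default_u = _init_orientations(params, brush)
    streams = []
    finals = []
    for k, seed in enumerate(seeds):
        init_u = default_u
        if init_chains is not None and init_chains[k] is not None:
            cand = init_chains[k]
            conf = Conformation(np.zeros(3),
                                rebuild_positions(cand, np.zeros(3),
                                                  params.bond_length),
                                np.asarray(cand), params.bond_length)
            if not use_wall or check_constraints(conf, brush) == "ok":
                init_u = cand
        st, u_final = _run_stream(
            fieldgrid.omega, fieldgrid.dz, fieldgrid.nz,
            fieldgrid.orientation, params, use_wall, H, azo_idx, use_field,
            per[k], burn_in, stride_pivots, max_angle, seed,
            init_u=init_u, joint_idx=joint_idx)
        streams.append(st)
        finals.append(u_final)
    stats = EnsembleStats(streams, fieldgrid.z_edges, fieldgrid.orientation,
                          params)
    return stats.density(), stats, finals


def sample_free_chain(params: ChainParams, M: int, seeds: Sequence,
                      burn_in: int = 100, stride: float = 5.0,
                      stride_pivots: Optional[int] = None,
                      max_angle: float = math.pi / 2,
                      joint_idx: Optional[int] = None) -> EnsembleStats:
    """Zero-field, wall-free sampling of the bare worm-like chain.

    Used for the closed-form cross-checks: tangent correlations, the squared
    end-to-end distance, and the single-joint angle distribution
    (``joint_idx`` selects the recorded joint; default = middle).
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("empty seed list")
    if M < len(seeds):
        raise ValueError("M smaller than the number of streams")
    if joint_idx is None:
        joint_idx = params.Nm // 2 - 1
    grid = build_free_grid(params)
    if stride_pivots is None:
        stride_pivots = max(1, int(round(stride * params.Nm)))
    K = len(seeds)
    per = [M // K + (1 if k < M % K else 0) for k in range(K)]
    u0 = np.zeros((params.Nm, 3))
    u0[:, 2] = 1.0
    streams = []
    for k, seed in enumerate(seeds):
        st, _ = _run_stream(
            grid.omega, grid.dz, grid.nz, grid.orientation, params,
            False, np.inf, -1, False, per[k], burn_in, stride_pivots,
            max_angle, seed, init_u=u0, joint_idx=joint_idx)
        streams.append(st)
    return EnsembleStats(streams, grid.z_edges, grid.orientation, params)


def build_free_grid(params: ChainParams) -> FieldGrid:
    """Minimal zero-field grid covering the reachable space of a free chain."""
    from .field import build_orientation_grid
    grid = build_orientation_grid(2, 4)
    return FieldGrid.zeros(4, 1.2 * params.contour_length + 1.0, grid)
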