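"""Canonical study protocols at the package's standard problem sizes.

These bundle the parameter regimes exercised throughout the documentation
and the reproduction script: the planar-brush density-profile regimes at
L/a = 30 (grafting densities spanning mushroom to strongly stretched), the
free-chain calibration runs, and the compression/relaxation hysteresis loop
of the semiflexible nematic brush.

Problem sizes here are deliberately reduced relative to production runs
(Nm = 50 instead of 100-1000, 1e5 conformations per field update instead of
1e7) so a full reproduction finishes on a single core in minutes; the
methods note discusses what the reduction does and does not change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chain import ChainParams
from .field import FieldGrid, SCFResult, build_orientation_grid, scf_iterate
from .observables import BrushProfile, brush_profile, tilt_order_from_stats
from .sampler import BrushConfig

__all__ = [
    "planar_regime_run",
    "profile_shape_flags",
    "hysteresis_run",
    "opposing_brush_p2",
    "stretched_field_guess",
]


def stretched_field_guess(grids: FieldGrid, sigma_eff: float, N: float,
                          L: float, edge_frac: float = 0.9,
                          edge_width: float = 1.0) -> np.ndarray:
    """Strong-stretching initial field: the Onsager field of a smoothed step
    density of height sigma N / h up to the brush edge h = edge_frac * L
    (isotropic angular average of |u x u'| is pi/4).

    The edge must sit inside the reachable region: only the field's
    gradients act on the chain (a constant shift cancels in every Metropolis
    energy difference), so an edge at z >= L would be dynamically inert.
    Starting the dense-brush iteration here instead of at zero removes the
    slow amplitude ramp-up; the fixed point is unchanged.
    """
    zc = grids.z_centers
    h = edge_frac * L
    rho0 = N / h
    prof = rho0 * 0.5 * (1.0 - np.tanh((zc - h) / edge_width))
    return sigma_eff * (math.pi / 4) * np.repeat(
        prof[:, None], grids.orientation.n_bins, axis=1)


@dataclass
class RegimeResult:
    sigma_eff: float
    result: SCFResult
    profile: BrushProfile
    psi: float
    psi_err: float


def planar_regime_run(sigma_eff: float, seed: int, Nm: int = 50,
                      N: float = 30.0, m_per_iter: int = 100_000,
                      nz: int = 80, ntheta: int = 12, nphi: int = 12,
                      max_iter: int = 30, lam: Optional[float] = None,
                      streams: int = 4, n_avg: int = 8, stride: float = 1.0,
                      warm_start: Optional[str] = "auto") -> RegimeResult:
    """One planar-brush solve in the standard regime L/a = 30 at reduced scale.

    The default mixing parameter scales inversely with the coupling (the
    linearized field-density feedback gain grows with 2daσ, so stability
    demands lam ~ 1/(1 + 2daσ)); ``warm_start='auto'`` seeds dense brushes
    (2daσ >= 10) with the strong-stretching step-field ansatz and dilute
    ones with zero field.
    """
    params = ChainParams(N=N, Nm=Nm)
    brush = BrushConfig(sigma_eff=sigma_eff)
    # slab width = bond length where possible: the midpoints of a fully
    # stretched chain then fall one per slab, avoiding the binning comb a
    # non-commensurate dz imprints on near-rigid segments at the wall
    b = params.bond_length
    z_max = nz * b if nz * b >= 1.1 * N else 1.2 * N
    grids = FieldGrid.zeros(nz, z_max, build_orientation_grid(ntheta, nphi))
    warm = None
    if warm_start == "auto" and sigma_eff >= 10.0:
        warm = stretched_field_guess(grids, sigma_eff, N,
                                     params.contour_length)
    if lam is None:
        lam = min(0.3, 1.2 / (1.0 + sigma_eff))
    sched = dict(m_per_iter=m_per_iter, m_start=max(1, m_per_iter // 8),
                 lam=lam, tol=0.02, max_iter=max_iter, streams=streams,
                 burn_in=100, stride=stride, n_avg=n_avg)
    res = scf_iterate(params, brush, grids, sched, base_seed=seed,
                      warm_field=warm)
    prof = brush_profile(res.density, res.stats)
    psi, psi_err = tilt_order_from_stats(res.stats)
    return RegimeResult(sigma_eff, res, prof, psi, psi_err)


def profile_shape_flags(profile: BrushProfile, L: float) -> dict:
    """Shape diagnostics of a converged rho(z).

    * ``depletion``: the wall-adjacent density lies below the interior
      maximum (the narrow depletion zone of the coil regime);
    * ``interior_max_z``: location of the single density maximum;
    * ``tail_monotone_frac``: fraction of non-increasing steps beyond the
      maximum (1 = strictly monotone decay up to binning noise);
    * ``plateau`` / ``plateau_maxdev``: median density over z/L in
      [0.1, 0.8] and the maximum relative deviation from it;
    * ``tail_over_plateau``: rho at z/L = 1.1 relative to the plateau.
    """
    z = profile.z_centers / L
    rho = profile.rho_z
    kmax = int(np.argmax(rho))
    core = rho[(z >= 0.1) & (z <= 0.8)]
    plateau = float(np.median(core))
    k11 = int(np.argmin(np.abs(z - 1.1)))
    tail = rho[kmax:]
    # smooth over 3 bins before judging monotonicity of the decay
    sm = np.convolve(tail, np.ones(3) / 3, mode="valid")
    mono = float(np.mean(np.diff(sm) <= 1e-12)) if sm.size > 1 else 1.0
    return {
        "depletion": bool(rho[0] < rho[kmax]),
        "interior_max_z": float(z[kmax]),
        "tail_monotone_frac": mono,
        "plateau": plateau,
        "plateau_maxdev": float(np.max(np.abs(core - plateau) / plateau)),
        "tail_over_plateau": float(rho[k11] / plateau) if plateau > 0
        else np.nan,
    }


def opposing_brush_p2(D: float, seed: int, Nm: int = 20, N: float = 10.0,
                      sigma_eff: float = 2.0, m_per_iter: int = 20_000,
                      nz: int = 60, ntheta: int = 8, nphi: int = 8,
                      max_iter: int = 12, lam: float = 0.1,
                      streams: int = 4, n_avg: int = 4) -> dict:
    """End-overlap reactivity of two identical opposing planar brushes.

    One brush is solved self-consistently with the symmetric two-brush
    closure (the mirrored partner density enters the field; both walls
    act); by symmetry the partner's end distribution is the mirror of the
    own one, so P2 = sum_k e[k] e_mirrored[k] / dz on the common grid over
    the gap [0, D].
    """
    from .observables import end_distribution, p2_overlap

    params = ChainParams(N=N, Nm=Nm)
    brush = BrushConfig(sigma_eff=sigma_eff, opposing_D=D)
    grids = FieldGrid.zeros(nz, D, build_orientation_grid(ntheta, nphi))
    sched = dict(m_per_iter=m_per_iter, m_start=m_per_iter // 4, lam=lam,
                 tol=0.02, max_iter=max_iter, streams=streams,
                 burn_in=100, stride=1.0, n_avg=n_avg)
    res = scf_iterate(params, brush, grids, sched, base_seed=seed)
    end = end_distribution(res.stats)
    dz = D / nz
    return {"P2": p2_overlap(end, end, dz), "end_dist": end,
            "result": res}


def hysteresis_run(seed: int, Nm: int = 16, N: float = 1.5,
                   sigma_eff: float = 35.0, m_per_iter: int = 20_000,
                   nz: int = 24, ntheta: int = 12, nphi: int = 12,
                   n_H: int = 4, H_lo_frac: float = 0.45,
                   H_hi_frac: float = 0.85, max_iter: int = 18,
                   dwell_iter: int = 40, lam: float = 0.1,
                   streams: int = 4, n_avg: int = 5):
    """Compression/relaxation sweep of a semiflexible nematic brush.

    Stiff grafted rods (`L = 3 l_p`) at dense grafting order along the wall
    normal; compressing the layer below the rod length forces tilting, and
    the Onsager coupling makes the tilt direction a collective, spontaneously
    broken azimuth.  The transition is first order, so the tilted and
    untilted branches are separately metastable.

    The upper wall is lowered from ``H_hi_frac*L`` to ``H_lo_frac*L`` and
    raised back, each solve warm-started from its predecessor.  Spontaneous
    nucleation of the broken azimuth from sampling noise is slow (its
    growth rate is throttled by the mixing parameter), so at the turning
    point the tilt channel is seeded with a weak azimuthal field
    perturbation (``seed_amp * (1 - cos 2 phi)``) and the iteration dwells
    for ``dwell_iter`` updates: at strong compression the perturbation
    grows into the self-consistent tilted state, at weak compression it
    decays — the solver, not the seed, decides the branch.  On relaxation
    the tilted state persists into wall heights where the compression
    branch stayed untilted; that branch dependence is the hysteresis
    signature of the first-order tilting transition.

    Returns ``(forward_records, backward_records, indicator)`` with the
    indicator ``max_H |psi_forward - psi_backward|``.
    """
    from .observables import brush_profile, tilt_order_from_stats

    seed_frac = 0.15            # seed amplitude relative to the field scale
    params = ChainParams(N=N, Nm=Nm)
    L = params.contour_length
    b = params.bond_length
    z_max = nz * b if nz * b >= 1.05 * L else 1.05 * L
    ogrid = build_orientation_grid(ntheta, nphi)
    grids = FieldGrid.zeros(nz, z_max, ogrid)
    d = ogrid.directions
    h2 = d[:, 0] ** 2 + d[:, 1] ** 2
    cos2phi = np.where(h2 > 1e-12,
                       (d[:, 0] ** 2 - d[:, 1] ** 2) / np.maximum(h2, 1e-12),
                       0.0)
    tilt_shape = (1.0 - cos2phi)[None, :] * np.ones((nz, 1))

    down = list(np.linspace(H_hi_frac * L, H_lo_frac * L, n_H))
    schedule_H = down + [down[-1]] + down[::-1][1:]   # dwell at the turn
    sched = dict(m_per_iter=m_per_iter, m_start=m_per_iter // 4, lam=lam,
                 tol=1e-4, max_iter=max_iter, streams=streams,
                 burn_in=150, stride=1.0, n_avg=n_avg)
    recs = []
    warm_field = warm_chains = None
    for i, H in enumerate(schedule_H):
        brush = BrushConfig(sigma_eff=sigma_eff, compression_H=float(H))
        sch = dict(sched)
        if i == n_H:                     # turning point: seed + dwell
            sch["max_iter"] = dwell_iter
            warm_field = warm_field + \
                seed_frac * float(np.max(np.abs(warm_field))) * tilt_shape
        res = scf_iterate(params, brush, grids, sch,
                          base_seed=seed + 7919 * i,
                          warm_field=warm_field, warm_chains=warm_chains)
        warm_field, warm_chains = res.field.omega, res.chains
        psi, psi_err = tilt_order_from_stats(res.stats)
        prof = brush_profile(res.density, res.stats)
        recs.append({"H": H, "result": res, "psi": psi,
                     "psi_err": psi_err, "height": prof.height})
    fwd = recs[:n_H]
    bwd = recs[n_H:][::-1]               # same H values, relaxation branch
    diffs = [abs(f["psi"] - bb["psi"]) for f, bb in zip(fwd, bwd)]
    indicator = float(max(diffs)) if diffs else 0.0
    return fwd, bwd, indicator
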