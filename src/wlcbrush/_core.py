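"""Numba kernels for the Metropolis pivot sampler.

All randomness enters through pre-drawn uniform variates (one row of five per
trial move: pivot index, axis polar, axis azimuth, rotation angle, acceptance),
so the kernels are pure functions of their inputs and a pure-Python reference
step can consume identical variates for exact cross-checks.

Conventions shared with the Python layer:

* bonds are array-indexed ``0..Nm-1`` (bond i+1 of the 1-based formulas);
* a pivot at array index ``p`` rotates bonds ``p..Nm-1`` about the node
  ``r_p``, so only the joint between bonds ``p-1`` and ``p`` changes its angle;
* the auxiliary field is tabulated on ``Nz`` uniform z-slabs times ``Norient``
  orientation bins, evaluated at bond midpoints with linear interpolation in z
  and nearest-bin assignment in orientation;
* the hard wall (and optional compression wall at z = H) acts on the chain
  nodes ``r_1..r_Nm`` by rejection, which is equivalent to an infinite
  potential in the Metropolis rule.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True, inline="always")
def _obin(ux, uy, uz, cos_inner, nphi):
    """Orientation-bin index: searchsorted in cos(theta), floor in phi."""
    it = np.searchsorted(cos_inner, uz)
    phi = math.atan2(uy, ux)
    if phi < 0.0:
        phi += TWO_PI
    ip = int(phi * nphi / TWO_PI)
    if ip >= nphi:
        ip = nphi - 1
    return it * nphi + ip


@njit(cache=True, inline="always")
def _fval(omega, ob, z, dz, nz):
    """Field value at height z, orientation bin ob: linear interp between
    slab centers, clamped at the boundary slabs."""
    x = z / dz - 0.5
    if x <= 0.0:
        return omega[0, ob]
    if x >= nz - 1.0:
        return omega[nz - 1, ob]
    i0 = int(x)
    f = x - i0
    return omega[i0, ob] * (1.0 - f) + omega[i0 + 1, ob] * f


@njit(cache=True, fastmath=True)
def run_mc(u, pos, unew, b, eps, fscale, use_field, omega, dz, nz,
           cos_inner, nphi, use_wall, H, azo_idx, max_angle,
           rnd, stride, record,
           dens, endz, sz_sum, sz_cnt, acc, joint_series, joint_idx,
           end_series):
    """Run ``rnd.shape[0]`` pivot trial moves in place; optionally record.

    When ``record`` is true a sample is recorded every ``stride`` proposals:
    the (z-midpoint, orientation) density histogram ``dens``, the free-end z
    histogram ``endz``, per-slab nematic sums ``sz_sum``/``sz_cnt``, scalar
    accumulators ``acc`` = [sum uu, sum uu^2, sum R2, sum R2^2, sum cos2phi,
    sum sin2phi, n horizontal bonds, n samples, sum uu lag-2, sum uu lag-3],
    and (if ``joint_idx >= 0``) the cosine of one joint angle per sample
    into ``joint_series``.

    Returns the number of accepted moves.
    """
    Nm = u.shape[0]
    nprop = rnd.shape[0]
    nacc = 0
    nrec = 0
    # per-bond field values of the current conformation (cached so rejected
    # proposals never re-evaluate the old tail)
    ef = np.zeros(Nm)
    efnew = np.zeros(Nm)
    if use_field:
        for i in range(Nm):
            zm = pos[i, 2] + 0.5 * b * u[i, 2]
            ef[i] = _fval(omega,
                          _obin(u[i, 0], u[i, 1], u[i, 2], cos_inner, nphi),
                          zm, dz, nz)
    for t in range(nprop):
        p = int(rnd[t, 0] * Nm)
        if p >= Nm:
            p = Nm - 1
        # rotation axis: uniform on the sphere, except at a constrained
        # (azo) joint where the axis is the preceding bond so the kink
        # angle is preserved exactly
        if azo_idx >= 0 and p == azo_idx:
            ax = u[p - 1, 0]
            ay = u[p - 1, 1]
            az = u[p - 1, 2]
        else:
            cz = 2.0 * rnd[t, 1] - 1.0
            s2 = 1.0 - cz * cz
            s = math.sqrt(s2) if s2 > 0.0 else 0.0
            aphi = TWO_PI * rnd[t, 2]
            ax = s * math.cos(aphi)
            ay = s * math.sin(aphi)
            az = cz
        th = (2.0 * rnd[t, 3] - 1.0) * max_angle
        ct = math.cos(th)
        st = math.sin(th)
        omc = 1.0 - ct

        ok = True
        efn = 0.0
        efo = 0.0
        zprev = pos[p, 2]
        for i in range(p, Nm):
            rx = u[i, 0]
            ry = u[i, 1]
            rz = u[i, 2]
            dot = ax * rx + ay * ry + az * rz
            cx = ay * rz - az * ry
            cy = az * rx - ax * rz
            cz2 = ax * ry - ay * rx
            nx = rx * ct + ax * dot * omc + cx * st
            ny = ry * ct + ay * dot * omc + cy * st
            nzv = rz * ct + az * dot * omc + cz2 * st
            inv = 1.0 / math.sqrt(nx * nx + ny * ny + nzv * nzv)
            nx *= inv
            ny *= inv
            nzv *= inv
            unew[i, 0] = nx
            unew[i, 1] = ny
            unew[i, 2] = nzv
            znew = zprev + b * nzv
            if use_wall and (znew <= 0.0 or znew >= H):
                ok = False
                break
            if use_field:
                zmn = zprev + 0.5 * b * nzv
                v = _fval(omega, _obin(nx, ny, nzv, cos_inner, nphi),
                          zmn, dz, nz)
                efnew[i] = v
                efn += v
                efo += ef[i]
            zprev = znew
        if ok:
            dE = fscale * (efn - efo)
            if p > 0:
                dxo = u[p, 0] - u[p - 1, 0]
                dyo = u[p, 1] - u[p - 1, 1]
                dzo = u[p, 2] - u[p - 1, 2]
                dxn = unew[p, 0] - u[p - 1, 0]
                dyn = unew[p, 1] - u[p - 1, 1]
                dzn = unew[p, 2] - u[p - 1, 2]
                dE += eps * ((dxn * dxn + dyn * dyn + dzn * dzn)
                             - (dxo * dxo + dyo * dyo + dzo * dzo))
            if dE <= 0.0 or rnd[t, 4] < math.exp(-dE):
                nacc += 1
                for i in range(p, Nm):
                    u[i, 0] = unew[i, 0]
                    u[i, 1] = unew[i, 1]
                    u[i, 2] = unew[i, 2]
                    pos[i + 1, 0] = pos[i, 0] + b * u[i, 0]
                    pos[i + 1, 1] = pos[i, 1] + b * u[i, 1]
                    pos[i + 1, 2] = pos[i, 2] + b * u[i, 2]
                    if use_field:
                        ef[i] = efnew[i]

        if record and ((t + 1) % stride == 0):
            rx2 = pos[Nm, 0] - pos[0, 0]
            ry2 = pos[Nm, 1] - pos[0, 1]
            rz2 = pos[Nm, 2] - pos[0, 2]
            r2 = rx2 * rx2 + ry2 * ry2 + rz2 * rz2
            acc[2] += r2
            acc[3] += r2 * r2
            suu = 0.0
            for i in range(Nm - 1):
                suu += (u[i, 0] * u[i + 1, 0] + u[i, 1] * u[i + 1, 1]
                        + u[i, 2] * u[i + 1, 2])
            suu /= (Nm - 1)
            acc[0] += suu
            acc[1] += suu * suu
            if Nm > 3:
                s2 = 0.0
                for i in range(Nm - 2):
                    s2 += (u[i, 0] * u[i + 2, 0] + u[i, 1] * u[i + 2, 1]
                           + u[i, 2] * u[i + 2, 2])
                acc[8] += s2 / (Nm - 2)
                s3 = 0.0
                for i in range(Nm - 3):
                    s3 += (u[i, 0] * u[i + 3, 0] + u[i, 1] * u[i + 3, 1]
                           + u[i, 2] * u[i + 3, 2])
                acc[9] += s3 / (Nm - 3)
            ke = int(pos[Nm, 2] / dz)
            if ke < 0:
                ke = 0
            if ke >= nz:
                ke = nz - 1
            endz[ke] += 1.0
            for i in range(Nm):
                zm = pos[i, 2] + 0.5 * b * u[i, 2]
                kb = int(zm / dz)
                if kb < 0:
                    kb = 0
                if kb >= nz:
                    kb = nz - 1
                ob = _obin(u[i, 0], u[i, 1], u[i, 2], cos_inner, nphi)
                dens[kb, ob] += 1.0
                uz2 = u[i, 2] * u[i, 2]
                sz_sum[kb] += 1.5 * uz2 - 0.5
                sz_cnt[kb] += 1.0
                h2 = u[i, 0] * u[i, 0] + u[i, 1] * u[i, 1]
                if h2 > 1e-16:
                    acc[4] += (u[i, 0] * u[i, 0] - u[i, 1] * u[i, 1]) / h2
                    acc[5] += 2.0 * u[i, 0] * u[i, 1] / h2
                    acc[6] += 1.0
            if joint_idx >= 0:
                joint_series[nrec] = (
                    u[joint_idx, 0] * u[joint_idx + 1, 0]
                    + u[joint_idx, 1] * u[joint_idx + 1, 1]
                    + u[joint_idx, 2] * u[joint_idx + 1, 2])
            end_series[nrec] = pos[Nm, 2]
            nrec += 1
            acc[7] += 1.0
    return nacc


@njit(cache=True)
def _discrete_energy(idx, dirs, b, eps, fscale, use_field, omega, dz, nz,
                     use_wall, H):
    """Total energy of a discrete-orientation chain; inf on wall violation."""
    Nm = idx.shape[0]
    z = 0.0
    e = 0.0
    for i in range(Nm):
        j = idx[i]
        uz = dirs[j, 2]
        znew = z + b * uz
        if use_wall and (znew <= 0.0 or znew >= H):
            return np.inf
        if use_field:
            e += fscale * _fval(omega, j, z + 0.5 * b * uz, dz, nz)
        if i > 0:
            k = idx[i - 1]
            dx = dirs[j, 0] - dirs[k, 0]
            dy = dirs[j, 1] - dirs[k, 1]
            dzc = dirs[j, 2] - dirs[k, 2]
            e += eps * (dx * dx + dy * dy + dzc * dzc)
        z = znew
    return e


@njit(cache=True)
def run_discrete(idx, dirs, b, eps, fscale, use_field, omega, dz, nz,
                 use_wall, H, rnd, stride, hist):
    """Single-bond-redraw Metropolis over a finite direction set.

    ``rnd`` has one row of three uniforms per proposal (bond, new direction,
    acceptance).  Every ``stride`` proposals the flat state index
    ``sum_i idx[i] * nd**i`` is histogrammed into ``hist``.  Returns the
    number of accepted moves.
    """
    Nm = idx.shape[0]
    nd = dirs.shape[0]
    nacc = 0
    e_cur = _discrete_energy(idx, dirs, b, eps, fscale, use_field, omega,
                             dz, nz, use_wall, H)
    for t in range(rnd.shape[0]):
        i = int(rnd[t, 0] * Nm)
        if i >= Nm:
            i = Nm - 1
        jnew = int(rnd[t, 1] * nd)
        if jnew >= nd:
            jnew = nd - 1
        jold = idx[i]
        idx[i] = jnew
        e_new = _discrete_energy(idx, dirs, b, eps, fscale, use_field, omega,
                                 dz, nz, use_wall, H)
        dE = e_new - e_cur
        if dE <= 0.0 or (math.isfinite(dE) and rnd[t, 2] < math.exp(-dE)):
            e_cur = e_new
            nacc += 1
        else:
            idx[i] = jold
        if (t + 1) % stride == 0:
            flat = 0
            mult = 1
            for k in range(Nm):
                flat += idx[k] * mult
                mult *= nd
            hist[flat] += 1.0
    return nacc
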