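"""Numba kernels for energy evaluation and the Metropolis inner loop.

Everything here operates on raw ``(n, 3)`` float64 position arrays and
scalar parameters; the public API lives in :mod:`helibundle.model_core`
and :mod:`helibundle.mc_engine`.  Incremental deltas are exact local
recomputations of the affected terms, so they agree with a full energy
recomputation to accumulation tolerance by construction.

Dihedrals with three (numerically) collinear points contribute zero to
the torsion term — a measure-zero configuration during sampling.
"""

import math

import numpy as np
from numba import njit

_DEGEN2 = 1e-24  # squared cross-product norm below which a dihedral is degenerate


@njit(cache=True)
def _fene(r, r0, R):
    x = (r - r0) / R
    if x <= -1.0 or x >= 1.0:
        return np.inf
    return -math.log(1.0 - x * x)


@njit(cache=True)
def _lj_r2(r2, sigma, rc, vc):
    if r2 >= rc * rc:
        return 0.0
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    return 4.0 * (s6 * s6 - s6) - vc


@njit(cache=True)
def _dist2(pos, i, j):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def _vbend(ax, ay, az, bx, by, bz, cx, cy, cz, theta0):
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - bx, cy - by, cz - bz
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = math.acos(c)
    return 1.0 - math.cos(theta - theta0)


@njit(cache=True)
def _vtor(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz, tau0):
    b1x, b1y, b1z = bx - ax, by - ay, bz - az
    b2x, b2y, b2z = cx - bx, cy - by, cz - bz
    b3x, b3y, b3z = dx - cx, dy - cy, dz - cz
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    if (n1x * n1x + n1y * n1y + n1z * n1z) < _DEGEN2:
        return 0.0
    if (n2x * n2x + n2y * n2y + n2z * n2z) < _DEGEN2:
        return 0.0
    nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    cxx = n1y * n2z - n1z * n2y
    cxy = n1z * n2x - n1x * n2z
    cxz = n1x * n2y - n1y * n2x
    y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
    x = n1x * n2x + n1y * n2y + n1z * n2z
    tau = math.atan2(y, x)
    return 1.0 - math.cos(tau - tau0)


@njit(cache=True)
def _vbend_i(pos, a, b, c, theta0):
    return _vbend(pos[a, 0], pos[a, 1], pos[a, 2],
                  pos[b, 0], pos[b, 1], pos[b, 2],
                  pos[c, 0], pos[c, 1], pos[c, 2], theta0)


@njit(cache=True)
def _vtor_i(pos, a, b, c, d, tau0):
    return _vtor(pos[a, 0], pos[a, 1], pos[a, 2],
                 pos[b, 0], pos[b, 1], pos[b, 2],
                 pos[c, 0], pos[c, 1], pos[c, 2],
                 pos[d, 0], pos[d, 1], pos[d, 2], tau0)


@njit(cache=True)
def total_energy_terms(pos, r0, R, sigma, rc, vc, theta0, tau0):
    """Unscaled sums of the four terms: (fene, lj, bend, torsion)."""
    n = pos.shape[0]
    e_f = 0.0
    for i in range(n - 1):
        e_f += _fene(math.sqrt(_dist2(pos, i, i + 1)), r0, R)
    e_l = 0.0
    for i in range(n - 2):
        for j in range(i + 2, n):
            e_l += _lj_r2(_dist2(pos, i, j), sigma, rc, vc)
    e_b = 0.0
    for k in range(1, n - 1):
        e_b += _vbend_i(pos, k - 1, k, k + 1, theta0)
    e_t = 0.0
    for l in range(n - 3):
        e_t += _vtor_i(pos, l, l + 1, l + 2, l + 3, tau0)
    return e_f, e_l, e_b, e_t


@njit(cache=True)
def lj_split(pos, sigma, rc, vc, cut):
    """Non-bonded LJ energy split by bond separation: (|i-j| <= cut, > cut)."""
    n = pos.shape[0]
    short = 0.0
    long_ = 0.0
    for i in range(n - 2):
        for j in range(i + 2, n):
            v = _lj_r2(_dist2(pos, i, j), sigma, rc, vc)
            if j - i <= cut:
                short += v
            else:
                long_ += v
    return short, long_


@njit(cache=True)
def displacement_delta(pos, i, new, r0, R, sigma, rc, vc, theta0, tau0,
                       s_fene, s_lj, s_theta, s_tau):
    """Scaled energy change for moving monomer i to ``new`` (3-vector).

    Returns +inf when a FENE stretching limit would be violated.
    """
    n = pos.shape[0]
    nx, ny, nz = new[0], new[1], new[2]
    # bonds touching i
    d_f = 0.0
    for j in (i - 1, i + 1):
        if 0 <= j < n:
            dxo = pos[i, 0] - pos[j, 0]
            dyo = pos[i, 1] - pos[j, 1]
            dzo = pos[i, 2] - pos[j, 2]
            dxn = nx - pos[j, 0]
            dyn = ny - pos[j, 1]
            dzn = nz - pos[j, 2]
            fn = _fene(math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn), r0, R)
            if fn == np.inf:
                return np.inf
            d_f += fn - _fene(math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo), r0, R)
    # non-bonded pairs touching i
    d_l = 0.0
    for j in range(n):
        if j < i - 1 or j > i + 1:
            dxn = nx - pos[j, 0]
            dyn = ny - pos[j, 1]
            dzn = nz - pos[j, 2]
            d_l += _lj_r2(dxn * dxn + dyn * dyn + dzn * dzn, sigma, rc, vc)
            d_l -= _lj_r2(_dist2(pos, i, j), sigma, rc, vc)
    # bending angles centred at i-1, i, i+1
    d_b = 0.0
    for k in range(max(1, i - 1), min(n - 1, i + 2)):
        vo = _vbend_i(pos, k - 1, k, k + 1, theta0)
        if k - 1 == i:
            vn = _vbend(nx, ny, nz,
                        pos[k, 0], pos[k, 1], pos[k, 2],
                        pos[k + 1, 0], pos[k + 1, 1], pos[k + 1, 2], theta0)
        elif k == i:
            vn = _vbend(pos[k - 1, 0], pos[k - 1, 1], pos[k - 1, 2],
                        nx, ny, nz,
                        pos[k + 1, 0], pos[k + 1, 1], pos[k + 1, 2], theta0)
        else:
            vn = _vbend(pos[k - 1, 0], pos[k - 1, 1], pos[k - 1, 2],
                        pos[k, 0], pos[k, 1], pos[k, 2],
                        nx, ny, nz, theta0)
        d_b += vn - vo
    # dihedrals containing i
    d_t = 0.0
    for l in range(max(0, i - 3), min(n - 3, i + 1)):
        vo = _vtor_i(pos, l, l + 1, l + 2, l + 3, tau0)
        px = np.empty(12)
        for m in range(4):
            idx = l + m
            if idx == i:
                px[3 * m], px[3 * m + 1], px[3 * m + 2] = nx, ny, nz
            else:
                px[3 * m] = pos[idx, 0]
                px[3 * m + 1] = pos[idx, 1]
                px[3 * m + 2] = pos[idx, 2]
        vn = _vtor(px[0], px[1], px[2], px[3], px[4], px[5],
                   px[6], px[7], px[8], px[9], px[10], px[11], tau0)
        d_t += vn - vo
    return s_fene * d_f + s_lj * d_l + s_theta * d_b + s_tau * d_t


@njit(cache=True)
def _rotate_side(pos, out, k, phi, suffix):
    """Rotate one side of bond (k, k+1) by phi about the bond axis.

    Writes rotated coordinates into ``out`` rows [lo, hi); returns (lo, hi).
    Monomers k and k+1 lie on the axis and never move.
    """
    n = pos.shape[0]
    ux = pos[k + 1, 0] - pos[k, 0]
    uy = pos[k + 1, 1] - pos[k, 1]
    uz = pos[k + 1, 2] - pos[k, 2]
    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= norm
    uy /= norm
    uz /= norm
    c = math.cos(phi)
    s = math.sin(phi)
    C = 1.0 - c
    r00 = c + ux * ux * C
    r01 = ux * uy * C - uz * s
    r02 = ux * uz * C + uy * s
    r10 = uy * ux * C + uz * s
    r11 = c + uy * uy * C
    r12 = uy * uz * C - ux * s
    r20 = uz * ux * C - uy * s
    r21 = uz * uy * C + ux * s
    r22 = c + uz * uz * C
    if suffix:
        lo, hi = k + 2, n
    else:
        lo, hi = 0, k
    px, py, pz = pos[k, 0], pos[k, 1], pos[k, 2]
    for m in range(lo, hi):
        dx = pos[m, 0] - px
        dy = pos[m, 1] - py
        dz = pos[m, 2] - pz
        out[m, 0] = px + r00 * dx + r01 * dy + r02 * dz
        out[m, 1] = py + r10 * dx + r11 * dy + r12 * dz
        out[m, 2] = pz + r20 * dx + r21 * dy + r22 * dz
    return lo, hi


@njit(cache=True)
def _pivot_dE(pos, new, lo, hi, k, sigma, rc, vc, tau0, s_lj, s_tau):
    """Energy change of a pivot about bond (k, k+1) with side rows in new[lo:hi].

    Only the cross LJ pairs between the two sides and the single dihedral
    with central bond (k, k+1) change; bonds, bends and within-side pairs
    are preserved by the rigid rotation (the axis passes through both
    monomers k and k+1, so their distances to the moving side are also
    preserved).
    """
    n = pos.shape[0]
    d_l = 0.0
    for i in range(0, k):
        for j in range(k + 2, n):
            # exactly one of i, j is in the moving range [lo, hi)
            if lo <= i < hi:
                ax_, ay_, az_ = new[i, 0], new[i, 1], new[i, 2]
                bx_, by_, bz_ = pos[j, 0], pos[j, 1], pos[j, 2]
            else:
                ax_, ay_, az_ = pos[i, 0], pos[i, 1], pos[i, 2]
                bx_, by_, bz_ = new[j, 0], new[j, 1], new[j, 2]
            dx = ax_ - bx_
            dy = ay_ - by_
            dz = az_ - bz_
            d_l += _lj_r2(dx * dx + dy * dy + dz * dz, sigma, rc, vc)
            d_l -= _lj_r2(_dist2(pos, i, j), sigma, rc, vc)
    d_t = 0.0
    if 1 <= k <= n - 3:
        vo = _vtor_i(pos, k - 1, k, k + 1, k + 2, tau0)
        if lo <= k - 1 < hi:  # prefix rotation: monomer k-1 moved
            vn = _vtor(new[k - 1, 0], new[k - 1, 1], new[k - 1, 2],
                       pos[k, 0], pos[k, 1], pos[k, 2],
                       pos[k + 1, 0], pos[k + 1, 1], pos[k + 1, 2],
                       pos[k + 2, 0], pos[k + 2, 1], pos[k + 2, 2], tau0)
        else:  # suffix rotation: monomer k+2 moved
            vn = _vtor(pos[k - 1, 0], pos[k - 1, 1], pos[k - 1, 2],
                       pos[k, 0], pos[k, 1], pos[k, 2],
                       pos[k + 1, 0], pos[k + 1, 1], pos[k + 1, 2],
                       new[k + 2, 0], new[k + 2, 1], new[k + 2, 2], tau0)
        d_t += vn - vo
    return s_lj * d_l + s_tau * d_t


@njit(cache=True)
def pivot_apply(pos, k, phi, suffix, r0, R, sigma, rc, vc, theta0, tau0,
                s_fene, s_lj, s_theta, s_tau):
    """Apply a torsion pivot in place; return the scaled energy change."""
    scratch = np.empty_like(pos)
    lo, hi = _rotate_side(pos, scratch, k, phi, suffix)
    de = _pivot_dE(pos, scratch, lo, hi, k, sigma, rc, vc, tau0, s_lj, s_tau)
    for m in range(lo, hi):
        pos[m, 0] = scratch[m, 0]
        pos[m, 1] = scratch[m, 1]
        pos[m, 2] = scratch[m, 2]
    return de


@njit
def mc_block(pos, e_tot, n_updates, T, rd, p_disp, rng,
             r0, R, sigma, rc, vc, theta0, tau0,
             s_fene, s_lj, s_theta, s_tau):
    """Run ``n_updates`` Metropolis updates in place.

    The RNG stream is consumed in exactly the same order as the pure
    Python reference path in :mod:`helibundle.mc_engine`:
    move-type draw; then (monomer, 3 offsets) or (bond, side, angle);
    then one acceptance draw only when 0 < dE < inf.

    Returns (e_tot, acc_disp, prop_disp, acc_tor, prop_tor).
    """
    n = pos.shape[0]
    scratch = np.empty_like(pos)
    acc_d = 0
    prop_d = 0
    acc_t = 0
    prop_t = 0
    new = np.empty(3)
    for _ in range(n_updates):
        if rng.random() < p_disp:
            prop_d += 1
            i = int(rng.integers(0, n))
            new[0] = pos[i, 0] + rd * (rng.random() - 0.5)
            new[1] = pos[i, 1] + rd * (rng.random() - 0.5)
            new[2] = pos[i, 2] + rd * (rng.random() - 0.5)
            de = displacement_delta(pos, i, new, r0, R, sigma, rc, vc,
                                    theta0, tau0, s_fene, s_lj, s_theta, s_tau)
            if de <= 0.0:
                accept = True
            elif de == np.inf:
                accept = False
            else:
                accept = rng.random() < math.exp(-de / T)
            if accept:
                pos[i, 0] = new[0]
                pos[i, 1] = new[1]
                pos[i, 2] = new[2]
                e_tot += de
                acc_d += 1
        else:
            prop_t += 1
            k = int(rng.integers(0, n - 1))
            suffix = rng.random() < 0.5
            phi = (2.0 * rng.random() - 1.0) * math.pi
            lo, hi = _rotate_side(pos, scratch, k, phi, suffix)
            de = _pivot_dE(pos, scratch, lo, hi, k, sigma, rc, vc, tau0,
                           s_lj, s_tau)
            if de <= 0.0:
                accept = True
            else:
                accept = rng.random() < math.exp(-de / T)
            if accept:
                for m in range(lo, hi):
                    pos[m, 0] = scratch[m, 0]
                    pos[m, 1] = scratch[m, 1]
                    pos[m, 2] = scratch[m, 2]
                e_tot += de
                acc_t += 1
    return e_tot, acc_d, prop_d, acc_t, prop_t


@njit(cache=True)
def dihedral_array(pos):
    """Signed dihedrals for all n-3 quadruples; NaN where degenerate."""
    n = pos.shape[0]
    out = np.empty(n - 3)
    for l in range(n - 3):
        b1x = pos[l + 1, 0] - pos[l, 0]
        b1y = pos[l + 1, 1] - pos[l, 1]
        b1z = pos[l + 1, 2] - pos[l, 2]
        b2x = pos[l + 2, 0] - pos[l + 1, 0]
        b2y = pos[l + 2, 1] - pos[l + 1, 1]
        b2z = pos[l + 2, 2] - pos[l + 1, 2]
        b3x = pos[l + 3, 0] - pos[l + 2, 0]
        b3y = pos[l + 3, 1] - pos[l + 2, 1]
        b3z = pos[l + 3, 2] - pos[l + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        if (n1x * n1x + n1y * n1y + n1z * n1z) < _DEGEN2 or \
           (n2x * n2x + n2y * n2y + n2z * n2z) < _DEGEN2:
            out[l] = np.nan
            continue
        nb2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        out[l] = math.atan2((cxx * b2x + cxy * b2y + cxz * b2z) / nb2,
                            n1x * n2x + n1y * n2y + n1z * n2z)
    return out
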