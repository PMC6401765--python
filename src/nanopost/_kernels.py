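"""Numba-compiled hot loops: pair search, forces, leap-frog integration.

All kernels work on a single linear chain (consecutive bonds 0..N-2).
Units: epsilon = sigma = m_o = 1.  The WCA cutoff is 2^(1/6) sigma.

Error codes returned by the kernels:
    0  ok
    1  bond overstretched (l >= R_o)
    2  bead at or inside a bare post surface
    3  coincident beads (r = 0 within a pair)
    4  pair-list buffer overflow (caller must grow buffers and retry)
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: WCA cutoff (squared): r_c = 2^(1/6) sigma.
RCUT = 2.0 ** (1.0 / 6.0)
RCUT2 = 2.0 ** (1.0 / 3.0)

#: Verlet-list skin.
SKIN = 0.45

ERR_NONE = 0
ERR_OVERSTRETCH = 1
ERR_POST_OVERLAP = 2
ERR_PAIR_OVERLAP = 3
ERR_NLIST_OVERFLOW = 4


@njit(cache=True, inline="always")
def _pair_wca(r2):
    """Shifted WCA at squared distance r2 < RCUT2.

    Returns (energy, g) with force_on_i = g * (r_i - r_j).
    """
    inv = 1.0 / r2
    s6 = inv * inv * inv
    s12 = s6 * s6
    e = 4.0 * (s12 - s6) + 1.0
    g = 24.0 * (2.0 * s12 - s6) * inv
    return e, g


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _build_pairs(pos, rlist2, pi, pj):
    """Non-adjacent pair scan into a Verlet list (bonded pairs are handled in
    the bond loop).  Returns pair count or -1 on overflow."""
    n = pos.shape[0]
    cap = pi.shape[0]
    m = 0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 2, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2:
                if m >= cap:
                    return -1
                pi[m] = i
                pj[m] = j
                m += 1
    return m


@njit(cache=True)
def _max_disp2(pos, ref):
    n = pos.shape[0]
    worst = 0.0
    for i in range(n):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > worst:
            worst = d2
    return worst


@njit(cache=True)
def _compute_forces(pos, f, angle_b, kT, kappa, ro2, use_nb, npairs, pi, pj,
                    has_posts, sp, dp_bare):
    """Total potential energy and forces (f is overwritten).

    Terms: WCA over all bead pairs within the cutoff (non-adjacent pairs
    via the pair list, bonded pairs inside the bond loop; use_nb = 0 none,
    1 all pairs, 2 bonded pairs only), FENE on consecutive bonds, bending
    b*kT*(1+cos theta) per angle, shifted WCA from the four nearest post
    images.

    Returns (pe, err).
    """
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    pe = 0.0

    # --- WCA between non-adjacent beads ---
    if use_nb == 1:
        for m in range(npairs):
            i = pi[m]
            j = pj[m]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < RCUT2:
                if r2 <= 0.0:
                    return 0.0, ERR_PAIR_OVERLAP
                e, g = _pair_wca(r2)
                pe += e
                f[i, 0] += g * dx
                f[i, 1] += g * dy
                f[i, 2] += g * dz
                f[j, 0] -= g * dx
                f[j, 1] -= g * dy
                f[j, 2] -= g * dz

    # --- bonds: FENE plus the WCA of the bonded pair ---
    for i in range(n - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        l2 = dx * dx + dy * dy + dz * dz
        if l2 >= ro2:
            return 0.0, ERR_OVERSTRETCH
        arg = 1.0 - l2 / ro2
        pe += -0.5 * kappa * ro2 * np.log(arg)
        h = -kappa / arg
        if use_nb != 0 and l2 < RCUT2:
            if l2 <= 0.0:
                return 0.0, ERR_PAIR_OVERLAP
            e, g = _pair_wca(l2)
            pe += e
            h += g
        f[i, 0] += h * dx
        f[i, 1] += h * dy
        f[i, 2] += h * dz
        f[i + 1, 0] -= h * dx
        f[i + 1, 1] -= h * dy
        f[i + 1, 2] -= h * dz

    # --- bending ---
    for k in range(n - 2):
        c0 = angle_b[k] * kT
        if c0 == 0.0:
            continue
        ux = pos[k, 0] - pos[k + 1, 0]
        uy = pos[k, 1] - pos[k + 1, 1]
        uz = pos[k, 2] - pos[k + 1, 2]
        vx = pos[k + 2, 0] - pos[k + 1, 0]
        vy = pos[k + 2, 1] - pos[k + 1, 1]
        vz = pos[k + 2, 2] - pos[k + 1, 2]
        u2 = ux * ux + uy * uy + uz * uz
        v2 = vx * vx + vy * vy + vz * vz
        ulen = np.sqrt(u2)
        vlen = np.sqrt(v2)
        dot = ux * vx + uy * vy + uz * vz
        ct = dot / (ulen * vlen)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        pe += c0 * (1.0 + ct)
        inv_uv = 1.0 / (ulen * vlen)
        # d(cos)/du and d(cos)/dv
        gux = vx * inv_uv - ct * ux / u2
        guy = vy * inv_uv - ct * uy / u2
        guz = vz * inv_uv - ct * uz / u2
        gvx = ux * inv_uv - ct * vx / v2
        gvy = uy * inv_uv - ct * vy / v2
        gvz = uz * inv_uv - ct * vz / v2
        f[k, 0] -= c0 * gux
        f[k, 1] -= c0 * guy
        f[k, 2] -= c0 * guz
        f[k + 2, 0] -= c0 * gvx
        f[k + 2, 1] -= c0 * gvy
        f[k + 2, 2] -= c0 * gvz
        f[k + 1, 0] += c0 * (gux + gvx)
        f[k + 1, 1] += c0 * (guy + gvy)
        f[k + 1, 2] += c0 * (guz + gvz)

    # --- posts: shifted WCA from the four nearest lattice images ---
    if has_posts:
        half_d = 0.5 * dp_bare
        for i in range(n):
            u = pos[i, 1] - sp * np.floor(pos[i, 1] / sp)
            v = pos[i, 2] - sp * np.floor(pos[i, 2] / sp)
            for a in range(2):
                for b in range(2):
                    dy = u - a * sp
                    dz = v - b * sp
                    r2 = dy * dy + dz * dz
                    r = np.sqrt(r2)
                    s = r - half_d
                    if s <= 0.0:
                        return 0.0, ERR_POST_OVERLAP
                    if s * s < RCUT2:
                        if r == 0.0:
                            return 0.0, ERR_PAIR_OVERLAP
                        e, g = _pair_wca(s * s)
                        pe += e
                        # radial force magnitude g*s along (dy, dz)/r
                        scale = g * s / r
                        f[i, 1] += scale * dy
                        f[i, 2] += scale * dz
    return pe, ERR_NONE


@njit(cache=True)
def _advance(pos, vel, fbuf, angle_b, kT, kappa, ro2, use_nb,
             has_posts, sp, dp_bare, dt, thermo, gamma, tau_nh, chi,
             n_steps, pi, pj, ref_pos, nstate):
    """Advance n_steps of leap-frog dynamics in place.

    vel holds half-step velocities (t - dt/2 relative to pos at t).
    thermo: 0 = none (NVE), 1 = Langevin, 2 = Nose-Hoover.
    nstate[0] caches the pair count (-1 = needs rebuild).

    Returns (err, steps_completed).
    """
    n = pos.shape[0]
    rlist = RCUT + SKIN
    rlist2 = rlist * rlist
    half_skin2 = (0.5 * SKIN) * (0.5 * SKIN)
    c_fric = np.exp(-gamma * dt)
    noise = np.sqrt((1.0 - c_fric * c_fric) * kT)

    for step in range(n_steps):
        if use_nb == 1:
            if nstate[0] < 0 or _max_disp2(pos, ref_pos) > half_skin2:
                m = _build_pairs(pos, rlist2, pi, pj)
                if m < 0:
                    return ERR_NLIST_OVERFLOW, step
                nstate[0] = m
                for i in range(n):
                    ref_pos[i, 0] = pos[i, 0]
                    ref_pos[i, 1] = pos[i, 1]
                    ref_pos[i, 2] = pos[i, 2]
        pe, err = _compute_forces(pos, fbuf, angle_b, kT, kappa, ro2, use_nb,
                                  nstate[0], pi, pj, has_posts, sp, dp_bare)
        if err != ERR_NONE:
            return err, step

        if thermo == 1:  # Langevin: exact OU friction + full kick
            for i in range(n):
                for d in range(3):
                    vel[i, d] = (c_fric * vel[i, d] + dt * fbuf[i, d]
                                 + noise * np.random.standard_normal())
        elif thermo == 2:  # Nose-Hoover (leap-frog variant)
            ke2 = 0.0
            for i in range(n):
                ke2 += (vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
                        + vel[i, 2] * vel[i, 2])
            chi[0] += dt * (ke2 / (3.0 * n * kT) - 1.0) / (tau_nh * tau_nh)
            for i in range(n):
                for d in range(3):
                    vel[i, d] += dt * (fbuf[i, d] - chi[0] * vel[i, d])
        else:  # NVE
            for i in range(n):
                for d in range(3):
                    vel[i, d] += dt * fbuf[i, d]

        for i in range(n):
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
    return ERR_NONE, n_steps


@njit(cache=True)
def _measure(pos, vel, fbuf, angle_b, kT, kappa, ro2, use_nb,
             has_posts, sp, dp_bare, dt, pi, pj):
    """Potential energy and on-step kinetic energy at the current position.

    Rebuilds an exact (skinless) pair list; interpolates on-step velocities
    as v(t) = v(t - dt/2) + (dt/2) a(t).  Returns (pe, ke, err).
    """
    m = _build_pairs(pos, RCUT2, pi, pj)
    if m < 0:
        return 0.0, 0.0, ERR_NLIST_OVERFLOW
    pe, err = _compute_forces(pos, fbuf, angle_b, kT, kappa, ro2, use_nb,
                              m, pi, pj, has_posts, sp, dp_bare)
    if err != ERR_NONE:
        return 0.0, 0.0, err
    n = pos.shape[0]
    ke = 0.0
    for i in range(n):
        for d in range(3):
            v = vel[i, d] + 0.5 * dt * fbuf[i, d]
            ke += 0.5 * v * v
    return pe, ke, ERR_NONE


@njit(cache=True)
def _sq_direct(frames, q, nsub):
    """Single-chain structure factor by the direct double sum.

    frames: (n_frames, nsub, 3) positions of the analyzed subset.
    Returns S(q) averaged over frames, with the i = j diagonal included.
    """
    nf = frames.shape[0]
    nq = q.shape[0]
    acc = np.zeros(nq)
    for fidx in range(nf):
        for i in range(nsub - 1):
            for j in range(i + 1, nsub):
                dx = frames[fidx, i, 0] - frames[fidx, j, 0]
                dy = frames[fidx, i, 1] - frames[fidx, j, 1]
                dz = frames[fidx, i, 2] - frames[fidx, j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                for m in range(nq):
                    x = q[m] * r
                    if x != 0.0:
                        acc[m] += np.sin(x) / x
                    else:
                        acc[m] += 1.0
    out = np.empty(nq)
    for m in range(nq):
        out[m] = (nsub + 2.0 * acc[m] / nf) / (nsub * nsub)
    return out
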