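"""Numba-compiled inner loops for production dynamics.

The Python-level reference path (``energetics.total_forces`` +
``dynamics.step_overdamped``) defines the model; these kernels are a
faster equivalent used by ``run_simulation``.  Equality between the two
routes is enforced by the test suite.

Pair interactions use a Verlet neighbour list (skin set by
``dynamics.VERLET_SKIN``), rebuilt whenever the maximal displacement
since the last build exceeds half the skin.  Status codes returned by :func:`integrate_chunk`:

* 0 — chunk completed,
* 1 — non-finite position (bead reported),
* 2 — membrane bond stretched beyond 3x its rest length (bead reported),
* 3 — bead pair collapsed to zero distance (bead reported).
"""
from __future__ import annotations

import numpy as np
from numba import njit

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def _code_in(codes: np.ndarray, code: np.int64) -> bool:
    lo, hi = 0, codes.size
    while lo < hi:
        mid = (lo + hi) // 2
        if codes[mid] < code:
            lo = mid + 1
        else:
            hi = mid
    return lo < codes.size and codes[lo] == code


@njit(cache=True, fastmath=True)
def _build_pairs(pos, roles, excl_codes, r_list, heads_only):
    """O(n^2) Verlet-list build.  Returns (pair_i, pair_j, pair_attr)."""
    n = pos.shape[0]
    r2 = r_list * r_list
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            if dx * dx + dy * dy < r2 and not _code_in(excl_codes, np.int64(i) * n + j):
                count += 1
    pi = np.empty(count, dtype=np.int32)
    pj = np.empty(count, dtype=np.int32)
    pa = np.empty(count, dtype=np.bool_)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            if dx * dx + dy * dy < r2 and not _code_in(excl_codes, np.int64(i) * n + j):
                pi[k] = i
                pj[k] = j
                ri = roles[i]
                rj = roles[j]
                if heads_only:
                    ai = ri == 3
                    aj = rj == 3
                else:
                    ai = ri == 2 or ri == 3
                    aj = rj == 2 or rj == 3
                pa[k] = (ri == 0 and aj) or (rj == 0 and ai)
                k += 1
    return pi, pj, pa


@njit(cache=True, fastmath=True)
def _accumulate_forces(pos, F,
                       bonds_i, bonds_j, bond_rest, bond_k, bond_maxext,
                       ang_i, ang_j, ang_k, ang_cos0, ang_sin0, ang_kk,
                       pair_i, pair_j, pair_attr,
                       sigma, sigma_attr, eps_rep, U3, rc_attr):
    """Fill ``F`` with the total force; returns the index of a collapsed
    bead pair, or -1 if the geometry is sound.

    Trig-free formulation: with cross = a x b and dot = a . b at an angle
    vertex, sin(theta - theta0) = (cross*cos(theta0) - dot*sin(theta0))
    / (|a||b|), so only one sqrt per angle is needed; the pair loop works
    entirely in squared distances.
    """
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
    # springs (harmonic) and membrane tethers (FENE, finite max ext)
    for b in range(bonds_i.size):
        i = bonds_i[b]
        j = bonds_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = np.sqrt(dx * dx + dy * dy)
        if r < 1e-10:
            return i
        # FENE tether force; harmonic bonds carry a huge L (~1e30) for
        # which x*L == stretch and 1 - x^2 == 1, i.e. exact Hooke's law
        # (fastmath forbids an isfinite() branch here)
        stretch = r - bond_rest[b]
        L = bond_maxext[b]
        x = stretch / L
        if x > 0.99:
            x = 0.99
        elif x < -0.99:
            x = -0.99
        fm = -bond_k[b] * (x * L) / ((1.0 - x * x) * r)
        F[i, 0] += fm * dx
        F[i, 1] += fm * dy
        F[j, 0] -= fm * dx
        F[j, 1] -= fm * dy
    # bending
    for a in range(ang_i.size):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        la2 = ax * ax + ay * ay
        lb2 = bx * bx + by * by
        if la2 < 1e-20 or lb2 < 1e-20:
            return j
        cross = ax * by - ay * bx
        dot = ax * bx + ay * by
        inv_ab = 1.0 / np.sqrt(la2 * lb2)
        dE = ang_kk[a] * (cross * ang_cos0[a] - dot * ang_sin0[a]) * inv_ab
        fix = -dE * ay / la2
        fiy = dE * ax / la2
        fkx = dE * by / lb2
        fky = -dE * bx / lb2
        F[i, 0] += fix
        F[i, 1] += fiy
        F[k, 0] += fkx
        F[k, 1] += fky
        F[j, 0] -= fix + fkx
        F[j, 1] -= fiy + fky
    # non-bonded pairs (energy shifts at the cutoffs carry no force);
    # membrane-actin pairs interact through the narrow adhesion range
    # sigma_attr, all other pairs through the full WCA core
    rc_wca2 = (_WCA_CUT * sigma) ** 2
    rc_attr2 = (rc_attr * sigma) ** 2
    s2 = sigma * sigma
    s2a = sigma_attr * sigma_attr
    for p in range(pair_i.size):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r2 = dx * dx + dy * dy
        if r2 < 1e-16:
            return i
        fm = 0.0
        if pair_attr[p]:
            # pure truncated-shifted LJ of depth U3 (no separate core:
            # grip and stickiness both scale with cortical tension)
            if r2 >= rc_attr2:
                continue
            sr2 = s2a / r2
            sr6 = sr2 * sr2 * sr2
            fm = U3 * 24.0 * (2.0 * sr6 * sr6 - sr6) / r2
        else:
            if r2 >= rc_wca2:
                continue
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            fm = eps_rep * 24.0 * (2.0 * sr6 * sr6 - sr6) / r2
        F[i, 0] += fm * dx
        F[i, 1] += fm * dy
        F[j, 0] -= fm * dx
        F[j, 1] -= fm * dy
    return -1


@njit(cache=True, fastmath=True)
def integrate_chunk(pos, noise, growth_u,
                    roles,
                    bonds_i, bonds_j, bond_rest, bond_k, bond_maxext,
                    mem_bond_idx,
                    ang_i, ang_j, ang_k, ang_t0, ang_kk,
                    excl_codes,
                    term_bond_idx, fil_rest_total,
                    mobile,
                    dt, gamma, kT, sigma, sigma_attr, eps_rep, U3, rc_attr,
                    heads_only,
                    growth_rate, growth_inc, stall_deficit, max_fil_len,
                    skin, max_step):
    """Advance ``noise.shape[0]`` overdamped steps in place.

    ``pos``, ``bond_rest`` and ``fil_rest_total`` are mutated.  Returns
    ``(status, step_local, bead)``.
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    amp = np.sqrt(2.0 * kT * dt / gamma)
    inv_gamma = dt / gamma
    ang_cos0 = np.cos(ang_t0)
    ang_sin0 = np.sin(ang_t0)

    r_list = max(rc_attr, _WCA_CUT * sigma) + skin
    pair_i, pair_j, pair_attr = _build_pairs(pos, roles, excl_codes, r_list, heads_only)
    ref = pos.copy()
    F = np.empty((n, 2))
    half_skin2 = (0.5 * skin) ** 2

    for s in range(n_steps):
        # rebuild neighbour list when any bead moved more than skin/2
        rebuild = False
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            if dx * dx + dy * dy > half_skin2:
                rebuild = True
                break
        if rebuild:
            pair_i, pair_j, pair_attr = _build_pairs(pos, roles, excl_codes,
                                                     r_list, heads_only)
            for i in range(n):
                ref[i, 0] = pos[i, 0]
                ref[i, 1] = pos[i, 1]

        bad = _accumulate_forces(pos, F,
                                 bonds_i, bonds_j, bond_rest, bond_k, bond_maxext,
                                 ang_i, ang_j, ang_k, ang_cos0, ang_sin0, ang_kk,
                                 pair_i, pair_j, pair_attr,
                                 sigma, sigma_attr, eps_rep, U3, rc_attr)
        if bad >= 0:
            return 3, s, bad

        for i in range(n):
            if mobile[i]:
                ddx = F[i, 0] * inv_gamma + amp * noise[s, i, 0]
                ddy = F[i, 1] * inv_gamma + amp * noise[s, i, 1]
                # displacement limiter: a bead driven deep into a
                # repulsive core would otherwise be launched (k*dt >> 1);
                # the cap is far above any thermal or elastic step size
                d2 = ddx * ddx + ddy * ddy
                if d2 > max_step * max_step:
                    scale = max_step / np.sqrt(d2)
                    ddx *= scale
                    ddy *= scale
                pos[i, 0] += ddx
                pos[i, 1] += ddy
                if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                    return 1, s, i

        # membrane rupture guard
        for b in range(mem_bond_idx.size):
            bb = mem_bond_idx[b]
            i = bonds_i[bb]
            j = bonds_j[bb]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            lim = 3.0 * bond_rest[bb]
            if dx * dx + dy * dy > lim * lim:
                return 2, s, i

        # stochastic filament tip growth; stalls while the terminal bond
        # is compressed beyond the stall deficit (finite stall force)
        for f in range(term_bond_idx.size):
            if growth_u[s, f] < growth_rate and \
                    fil_rest_total[f] + growth_inc <= max_fil_len + 1e-12:
                bb = term_bond_idx[f]
                i = bonds_i[bb]
                j = bonds_j[bb]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                if bond_rest[bb] - np.sqrt(dx * dx + dy * dy) < stall_deficit:
                    bond_rest[bb] += growth_inc
                    fil_rest_total[f] += growth_inc

    return 0, n_steps, -1


def kernel_forces(pos, roles, bonds_i, bonds_j, bond_rest, bond_k,
                  bond_maxext,
                  ang_i, ang_j, ang_k, ang_t0, ang_kk, excl_codes,
                  sigma, sigma_attr, eps_rep, U3, rc_attr, heads_only,
                  skin=0.3):
    """Compute forces through the kernel machinery (testing hook)."""
    r_list = max(rc_attr, _WCA_CUT * sigma) + skin
    pair_i, pair_j, pair_attr = _build_pairs(pos, roles, excl_codes, r_list,
                                             heads_only)
    F = np.zeros((pos.shape[0], 2))
    bad = _accumulate_forces(pos, F, bonds_i, bonds_j, bond_rest, bond_k,
                             bond_maxext,
                             ang_i, ang_j, ang_k,
                             np.cos(ang_t0), np.sin(ang_t0), ang_kk,
                             pair_i, pair_j, pair_attr,
                             sigma, sigma_attr, eps_rep, U3, rc_attr)
    if bad >= 0:
        raise FloatingPointError(f"collapsed pair at bead {bad}")
    return F
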