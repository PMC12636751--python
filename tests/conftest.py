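import numpy as np
import pytest

from neuritesim import (
    SimulationParameters,
    build_cell,
    generate_fixture_cell,
    perturb_positions,
)


@pytest.fixture(scope="session")
def small_params() -> SimulationParameters:
    return generate_fixture_cell("small")


@pytest.fixture()
def small_cell(small_params):
    return build_cell(small_params)


@pytest.fixture()
def jiggled_cell(small_params):
    """Small cell with positions perturbed so no term sits exactly at rest."""
    return perturb_positions(build_cell(small_params), 0.05, seed=42)


@pytest.fixture(scope="session")
def quick_run_params(small_params) -> SimulationParameters:
    """Sub-second dynamics schedule on the small fixture."""
    return small_params.replace(n_steps=500, record_every=100)


def brute_force_energy_forces(state, params):
    """Independent O(n^2) oracle: sums every term pairwise with no neighbor
    list, using only closed-form expressions written out locally."""
    n = state.n_beads
    pos = state.positions
    E = {"spring": 0.0, "bending": 0.0, "attraction": 0.0, "excluded_volume": 0.0}
    F = np.zeros((n, 2))

    for b in range(state.n_bonds):
        i, j = map(int, state.bonds_ij[b])
        d = pos[i] - pos[j]
        r = np.hypot(*d)
        k, r0 = state.bond_stiffness[b], state.bond_rest[b]
        L = state.bond_max_ext[b]
        if np.isfinite(L):
            x = np.clip((r - r0) / L, -0.99, 0.99)
            E["spring"] += -0.5 * k * L**2 * np.log1p(-x * x)
            f = -k * (x * L) / (1 - x * x) * d / r
        else:
            E["spring"] += 0.5 * k * (r - r0) ** 2
            f = -k * (r - r0) * d / r
        F[i] += f
        F[j] -= f

    for a in range(state.n_angles):
        i, j, k = map(int, state.angles_ijk[a])
        va = pos[i] - pos[j]
        vb = pos[k] - pos[j]
        theta = np.arctan2(va[0] * vb[1] - va[1] * vb[0], va @ vb)
        kk, t0 = state.angle_stiffness[a], state.angle_theta0[a]
        E["bending"] += kk * (1.0 - np.cos(theta - t0))
        dE = kk * np.sin(theta - t0)
        gi = np.array([va[1], -va[0]]) / (va @ va)
        gk = np.array([-vb[1], vb[0]]) / (vb @ vb)
        F[i] += -dE * gi
        F[k] += -dE * gk
        F[j] -= -dE * gi - dE * gk
    bonded = {frozenset(map(int, b)) for b in state.bonds_ij}
    rc_wca = 2 ** (1 / 6) * params.sigma
    s_attr = params.sigma_attr * params.sigma
    rc_attr = params.r_cut_attr * params.sigma
    membrane, shaft, head = 0, 2, 3

    def lj(r, eps, s):
        sr6 = (s / r) ** 6
        return 4 * eps * (sr6**2 - sr6)

    def ljf(r, eps, s):
        sr6 = (s / r) ** 6
        return 24 * eps * (2 * sr6**2 - sr6) / r

    for i in range(n - 1):
        for j in range(i + 1, n):
            if frozenset((i, j)) in bonded:
                continue
            d = pos[i] - pos[j]
            r = np.hypot(*d)
            ri, rj = int(state.roles[i]), int(state.roles[j])
            actin = (head,) if params.attract_heads_only else (shaft, head)
            attr = (ri == membrane and rj in actin) or (rj == membrane and ri in actin)
            e = f = 0.0
            if attr:
                if r < rc_attr:
                    e += lj(r, params.U3, s_attr) - lj(rc_attr, params.U3, s_attr)
                    f += ljf(r, params.U3, s_attr)
            elif r < rc_wca:
                e += lj(r, params.epsilon_repulsion, params.sigma) + params.epsilon_repulsion
                f += ljf(r, params.epsilon_repulsion, params.sigma)
            E["attraction" if attr else "excluded_volume"] += e
            fv = f * d / r
            F[i] += fv
            F[j] -= fv
    E["total"] = sum(E.values())
    return E, F
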