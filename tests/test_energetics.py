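"""Per-term potentials, force/gradient consistency, and oracle equivalence."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuritesim import (
    EnergyBreakdown,
    GeometryError,
    attraction_energy_force,
    bending_energy_force,
    build_cell,
    excluded_volume_energy_force,
    perturb_positions,
    spring_energy_force,
    total_energy,
    total_forces,
)
from neuritesim.model import AngleTriple
from neuritesim import _kernels, energetics

from conftest import brute_force_energy_forces

WCA_CUT = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------- springs
def test_spring_at_rest_length_is_zero():
    e, fi, fj = spring_energy_force([0, 0], [1.5, 0], stiffness=3.0, rest_length=1.5)
    assert e == 0.0
    np.testing.assert_allclose(fi, 0.0)
    np.testing.assert_allclose(fj, 0.0)


def test_spring_hooke_closed_form():
    """k=1, r0=1, d=2: E=1/2, |F|=1, attractive, equal and opposite."""
    e, fi, fj = spring_energy_force([0, 0], [2, 0], stiffness=1.0, rest_length=1.0)
    assert e == pytest.approx(0.5)
    np.testing.assert_allclose(fi, [1.0, 0.0])   # pulls i toward j
    np.testing.assert_allclose(fj, [-1.0, 0.0])
    np.testing.assert_allclose(fi + fj, 0.0)


def test_spring_coincident_beads_raise():
    with pytest.raises(GeometryError):
        spring_energy_force([0, 0], [0, 0], 1.0, 1.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 10_000))
def test_spring_force_matches_numerical_gradient(seed):
    rng = np.random.default_rng(seed)
    pi, pj = rng.normal(size=2), rng.normal(size=2) + np.array([2.0, 0.0])
    k, r0 = rng.uniform(0.5, 5.0), rng.uniform(0.5, 2.0)
    _, fi, _ = spring_energy_force(pi, pj, k, r0)
    eps = 1e-6
    grad = np.zeros(2)
    for d in range(2):
        dp = np.zeros(2)
        dp[d] = eps
        ep = spring_energy_force(pi + dp, pj, k, r0)[0]
        em = spring_energy_force(pi - dp, pj, k, r0)[0]
        grad[d] = (ep - em) / (2 * eps)
    np.testing.assert_allclose(fi, -grad, atol=1e-6)


# ---------------------------------------------------------------- bending
def _triple(theta0=np.pi, k=1.0):
    return AngleTriple(i=0, j=1, k=2, preferred_angle=theta0, stiffness=k)


def test_bending_zero_at_preferred_angle():
    pos = np.array([[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0]])  # straight: theta=pi
    e, forces = bending_energy_force(_triple(np.pi), pos, kappa00=4.0)
    assert e == pytest.approx(0.0, abs=1e-12)
    for f in forces:
        np.testing.assert_allclose(f, 0.0, atol=1e-12)


@pytest.mark.parametrize("n", [6, 24, 240])
def test_regular_ngon_ring_bending_closed_form(n):
    """Ring with theta0=pi: total E = N * k * (1 - cos(2*pi/N))."""
    k = 2.5
    ang = 2 * np.pi * np.arange(n) / n
    pos = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    total = 0.0
    for a in range(n):
        t = AngleTriple(i=a, j=(a + 1) % n, k=(a + 2) % n,
                        preferred_angle=np.pi, stiffness=k)
        total += bending_energy_force(t, pos, kappa00=k)[0]
    expected = n * k * (1 - np.cos(2 * np.pi / n))
    assert total == pytest.approx(expected, abs=1e-9)


def test_bending_energy_bounded_and_net_force_torque_vanish():
    rng = np.random.default_rng(3)
    for _ in range(20):
        pos = rng.normal(scale=2.0, size=(3, 2))
        if min(np.linalg.norm(pos[0] - pos[1]), np.linalg.norm(pos[2] - pos[1])) < 0.1:
            continue
        k = 3.0
        t = _triple(theta0=rng.uniform(0.1, 2 * np.pi - 0.1), k=k)
        e, (fi, fj, fk) = bending_energy_force(t, pos, kappa00=k)
        assert 0.0 <= e <= 2 * k + 1e-12
        np.testing.assert_allclose(fi + fj + fk, 0.0, atol=1e-10)
        torque = sum(p[0] * f[1] - p[1] * f[0]
                     for p, f in zip(pos, (fi, fj, fk)))
        assert abs(torque) < 1e-10


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 10_000))
def test_bending_force_matches_numerical_gradient(seed):
    rng = np.random.default_rng(seed)
    pos = rng.normal(scale=2.0, size=(3, 2))
    if min(np.linalg.norm(pos[0] - pos[1]), np.linalg.norm(pos[2] - pos[1])) < 0.2:
        pos[0] += 1.0
        pos[2] -= 1.0
    t = _triple(theta0=rng.uniform(0.1, 2 * np.pi - 0.1), k=2.0)
    _, forces = bending_energy_force(t, pos, kappa00=2.0)
    eps = 1e-6
    for b in range(3):
        for d in range(2):
            pp, pm = pos.copy(), pos.copy()
            pp[b, d] += eps
            pm[b, d] -= eps
            grad = (bending_energy_force(t, pp, 2.0)[0]
                    - bending_energy_force(t, pm, 2.0)[0]) / (2 * eps)
            assert forces[b][d] == pytest.approx(-grad, abs=1e-6)


# ------------------------------------------------------------- attraction
def test_attraction_zero_beyond_cutoff():
    for r in (2.5, 3.0, 10.0):
        e, f = attraction_energy_force(r, U3=5.0)
        assert e == 0.0 and f == 0.0


def test_attraction_minimum_depth_and_location():
    """Well minimum -U3*(1 - shift) at 2^(1/6) sigma, continuous at cutoff."""
    u3 = 7.0
    rmin = WCA_CUT
    e_min, f_min = attraction_energy_force(rmin, U3=u3)
    shift = 4 * ((1 / 2.5) ** 12 - (1 / 2.5) ** 6)  # LJ(r_cut)/U3
    assert e_min == pytest.approx(-u3 * (1 + shift), rel=1e-12)
    assert abs(f_min) < 1e-9  # stationary point
    # continuity at the cutoff
    e_in, _ = attraction_energy_force(2.5 - 1e-9, U3=u3)
    assert abs(e_in) < 1e-6


def test_attraction_zero_depth_means_zero_coupling():
    """U3=0: the membrane-actin coupling vanishes entirely — both the
    repulsive branch and the well scale with the depth (the clutch is
    fully disengaged at zero cortical tension)."""
    for r in (0.8, 1.0, 1.2, 2.0, 3.0):
        e, f = attraction_energy_force(r, U3=0.0)
        assert e == 0.0 and f == 0.0
    # the repulsive branch at finite depth is confined below 2^(1/6) sigma
    e_in, f_in = attraction_energy_force(0.9, U3=2.0)
    assert e_in > 0 and f_in > 0
    e_out, _ = attraction_energy_force(1.2, U3=2.0)
    assert e_out < 0  # attractive tail beyond the minimum


def test_attraction_force_matches_numerical_derivative():
    u3 = 4.0
    grid = np.linspace(0.95, 2.6, 200)
    eps = 1e-7
    for r in grid:
        _, f = attraction_energy_force(r, U3=u3)
        ep, _ = attraction_energy_force(r + eps, U3=u3)
        em, _ = attraction_energy_force(r - eps, U3=u3)
        assert f == pytest.approx(-(ep - em) / (2 * eps), abs=1e-5)


# ---------------------------------------------------------- excluded volume
def test_wca_zero_at_and_beyond_cutoff():
    e, f = excluded_volume_energy_force(WCA_CUT)
    assert e == pytest.approx(0.0, abs=1e-12) and f == pytest.approx(0.0, abs=1e-9)


def test_wca_monotone_repulsion():
    a, b = 0.9, 1.05
    ea, fa = excluded_volume_energy_force(a)
    eb, fb = excluded_volume_energy_force(b)
    assert ea > eb > 0
    assert fa > fb > 0


def test_wca_force_matches_numerical_derivative():
    eps = 1e-8
    for r in np.linspace(0.85, 1.115, 100):
        _, f = excluded_volume_energy_force(r)
        ep, _ = excluded_volume_energy_force(r + eps)
        em, _ = excluded_volume_energy_force(r - eps)
        assert f == pytest.approx(-(ep - em) / (2 * eps), rel=1e-5, abs=1e-5)


# ------------------------------------------------------------- whole state
def test_two_bonded_beads_at_rest_have_zero_energy():
    from neuritesim.model import CellState
    state = CellState(
        positions=np.array([[0.0, 0.0], [3.0, 0.0]]),
        roles=np.array([2, 2], dtype=np.int8),
        filament_ids=np.array([-1, -1], dtype=np.int32),
        bonds_ij=np.array([[0, 1]], dtype=np.int32),
        bond_rest=np.array([3.0]), bond_stiffness=np.array([1.0]),
        bond_kind=np.array([2], dtype=np.int8),
        angles_ijk=np.empty((0, 3), dtype=np.int32),
        angle_theta0=np.empty(0), angle_stiffness=np.empty(0),
    )
    from neuritesim import SimulationParameters
    e = total_energy(state, SimulationParameters())
    assert e.total == pytest.approx(0.0, abs=1e-12)


def test_breakdown_total_is_sum_of_parts(jiggled_cell, small_params):
    e = total_energy(jiggled_cell, small_params)
    parts = e.spring + e.bending + e.attraction + e.excluded_volume
    assert e.total == pytest.approx(parts, rel=1e-12)
    with pytest.raises(ValueError):
        EnergyBreakdown(spring=1.0, bending=0.0, attraction=0.0,
                        excluded_volume=0.0, total=2.0)


def test_translation_invariance(jiggled_cell, small_params):
    e0 = total_energy(jiggled_cell, small_params).total
    shifted = jiggled_cell.copy()
    shifted.positions = shifted.positions + np.array([13.7, -4.2])
    e1 = total_energy(shifted, small_params).total
    assert e1 == pytest.approx(e0, abs=1e-9 * max(1, abs(e0)))


def test_total_energy_matches_brute_force_oracle(jiggled_cell, small_params):
    e = total_energy(jiggled_cell, small_params)
    E, _ = brute_force_energy_forces(jiggled_cell, small_params)
    assert e.spring == pytest.approx(E["spring"], abs=1e-10)
    assert e.bending == pytest.approx(E["bending"], abs=1e-10)
    assert e.attraction == pytest.approx(E["attraction"], abs=1e-10)
    assert e.excluded_volume == pytest.approx(E["excluded_volume"], abs=1e-10)


def test_total_forces_match_brute_force_oracle(jiggled_cell, small_params):
    F = total_forces(jiggled_cell, small_params)
    _, F_oracle = brute_force_energy_forces(jiggled_cell, small_params)
    np.testing.assert_allclose(F, F_oracle, atol=1e-10)


def test_net_force_vanishes(jiggled_cell, small_params):
    F = total_forces(jiggled_cell, small_params)
    np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-8)


def test_total_forces_match_energy_gradient(jiggled_cell, small_params):
    F = total_forces(jiggled_cell, small_params)
    eps = 1e-6
    rng = np.random.default_rng(0)
    beads = rng.choice(jiggled_cell.n_beads, size=12, replace=False)
    for b in beads:
        for d in range(2):
            sp = jiggled_cell.copy()
            sp.positions[b, d] += eps
            sm = jiggled_cell.copy()
            sm.positions[b, d] -= eps
            grad = (total_energy(sp, small_params).total
                    - total_energy(sm, small_params).total) / (2 * eps)
            assert F[b, d] == pytest.approx(-grad, abs=1e-5)


def test_kernel_forces_equal_reference_path(jiggled_cell, small_params):
    """Compiled Verlet-list kernel against the NumPy/KD-tree route, and
    against the O(n^2) brute-force oracle, to 1e-10."""
    s, p = jiggled_cell, small_params
    F_ref = total_forces(s, p)
    F_kernel = _kernels.kernel_forces(
        np.ascontiguousarray(s.positions), s.roles,
        np.ascontiguousarray(s.bonds_ij[:, 0], dtype=np.int32),
        np.ascontiguousarray(s.bonds_ij[:, 1], dtype=np.int32),
        s.bond_rest, s.bond_stiffness,
        np.minimum(s.bond_max_ext, 1e30),
        np.ascontiguousarray(s.angles_ijk[:, 0], dtype=np.int32),
        np.ascontiguousarray(s.angles_ijk[:, 1], dtype=np.int32),
        np.ascontiguousarray(s.angles_ijk[:, 2], dtype=np.int32),
        s.angle_theta0, s.angle_stiffness,
        energetics.bonded_pair_codes(s),
        p.sigma, p.sigma_attr_effective, p.epsilon_repulsion, p.U3,
        p.r_cut_attr, p.attract_heads_only)
    np.testing.assert_allclose(F_kernel, F_ref, atol=1e-10)
    _, F_oracle = brute_force_energy_forces(s, p)
    np.testing.assert_allclose(F_kernel, F_oracle, atol=1e-10)
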