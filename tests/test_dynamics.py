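"""Integrator oracles (harmonic relaxation, Einstein relation), growth
statistics, determinism, and trajectory integrity."""
import numpy as np
import pytest

from neuritesim import (
    NumericalInstabilityError,
    SimulationParameters,
    Trajectory,
    build_cell,
    grow_filaments,
    run_simulation,
    step_overdamped,
    suggest_timestep,
    total_energy,
)
from neuritesim.dynamics import filament_growth_arrays
from neuritesim.model import BondKind, CellState, Role


def _free_beads_state(n, spacing=50.0):
    """n mutually non-interacting beads on a sparse grid."""
    side = int(np.ceil(np.sqrt(n)))
    pos = np.array([[spacing * (k % side), spacing * (k // side)]
                    for k in range(n)], dtype=float)
    return CellState(
        positions=pos,
        roles=np.full(n, int(Role.ACTIN_SHAFT), dtype=np.int8),
        filament_ids=np.full(n, -1, dtype=np.int32),
        bonds_ij=np.empty((0, 2), dtype=np.int32),
        bond_rest=np.empty(0), bond_stiffness=np.empty(0),
        bond_kind=np.empty(0, dtype=np.int8),
        angles_ijk=np.empty((0, 3), dtype=np.int32),
        angle_theta0=np.empty(0), angle_stiffness=np.empty(0),
    )


def _trap_state(x0=1.0, k=1.0):
    """A mobile bead bonded to a pinned bead: harmonic trap."""
    state = CellState(
        positions=np.array([[0.0, 0.0], [x0, 0.0]]),
        roles=np.array([int(Role.NUCLEAR), int(Role.ACTIN_SHAFT)], dtype=np.int8),
        filament_ids=np.array([-1, -1], dtype=np.int32),
        bonds_ij=np.array([[0, 1]], dtype=np.int32),
        bond_rest=np.array([1e-12]),  # ~zero rest length: pure linear trap
        bond_stiffness=np.array([k]),
        bond_kind=np.array([int(BondKind.ANCHOR)], dtype=np.int8),
        angles_ijk=np.empty((0, 3), dtype=np.int32),
        angle_theta0=np.empty(0), angle_stiffness=np.empty(0),
        pinned=np.array([True, False]),
    )
    return state


def test_zero_force_zero_temperature_is_static():
    state = _free_beads_state(4)
    params = SimulationParameters(kT=0.0)
    rng = np.random.default_rng(0)
    out = step_overdamped(state, params, rng)
    np.testing.assert_array_equal(out.positions, state.positions)
    assert out.time == pytest.approx(params.dt)


def test_overdamped_harmonic_relaxation_closed_form():
    """x(t) = x0 exp(-k t / gamma) within 1% for dt <= 1e-3 / k."""
    k, gamma, x0, t_end = 2.0, 1.0, 1.0, 1.0
    params = SimulationParameters(kT=0.0, gamma=gamma, dt=5e-4)
    state = _trap_state(x0=x0, k=k)
    rng = np.random.default_rng(0)
    n_steps = int(round(t_end / params.dt))
    for _ in range(n_steps):
        state = step_overdamped(state, params, rng)
    expected = x0 * np.exp(-k * t_end / gamma)
    assert state.positions[1, 0] == pytest.approx(expected, rel=0.01)
    assert state.positions[0, 0] == 0.0  # pinned bead did not move


def test_free_bead_msd_matches_einstein_relation():
    """MSD = 4 D t with D = kT/gamma, within 3 standard errors over 10^3
    replicate beads."""
    n_rep, n_steps = 1000, 40
    params = SimulationParameters(kT=1.0, gamma=1.0, dt=1e-3)
    state = _free_beads_state(n_rep)
    x0 = state.positions.copy()
    rng = np.random.default_rng(123)
    for _ in range(n_steps):
        state = step_overdamped(state, params, rng)
    t = n_steps * params.dt
    sq = np.sum((state.positions - x0) ** 2, axis=1)
    msd = sq.mean()
    expected = 4.0 * params.kT / params.gamma * t
    se = sq.std(ddof=1) / np.sqrt(n_rep)
    assert abs(msd - expected) < 3 * se


# ------------------------------------------------------------------ growth
def _relax_tips(state):
    """Move each head to its terminal bond's rest distance (unloaded tip),
    so growth statistics can be observed without running dynamics."""
    term, _ = filament_growth_arrays(state)
    for b in term:
        i, j = state.bonds_ij[b]
        # head is one of i, j
        head, base = (i, j) if state.roles[i] == int(Role.ACTIN_HEAD) else (j, i)
        d = state.positions[head] - state.positions[base]
        d /= np.linalg.norm(d)
        state.positions[head] = state.positions[base] + d * state.bond_rest[b]
    return state


def test_growth_rate_zero_changes_nothing(small_cell, small_params):
    rng = np.random.default_rng(0)
    out = grow_filaments(small_cell, small_params.replace(growth_rate=0.0), rng)
    np.testing.assert_array_equal(out.bond_rest, small_cell.bond_rest)


def test_growth_rate_one_deterministic_limit(small_cell, small_params):
    """rate 1, 10 calls, increment 0.05: every uncapped terminal bond
    grows by exactly 0.5."""
    params = small_params.replace(growth_rate=1.0, growth_increment=0.05,
                                  max_filament_length=100.0)
    rng = np.random.default_rng(0)
    state = small_cell
    term, _ = filament_growth_arrays(state)
    before = state.bond_rest[term].copy()
    for _ in range(10):
        state = grow_filaments(_relax_tips(state), params, rng)
    np.testing.assert_allclose(state.bond_rest[term], before + 0.5, rtol=1e-12)


def test_growth_respects_length_cap(small_cell, small_params):
    _, total = filament_growth_arrays(small_cell)
    cap = total[0] + 0.1
    params = small_params.replace(growth_rate=1.0, growth_increment=0.05,
                                  max_filament_length=float(cap))
    state = small_cell
    rng = np.random.default_rng(0)
    for _ in range(10):
        state = grow_filaments(state, params, rng)
    _, total_after = filament_growth_arrays(state)
    assert np.all(total_after <= cap + 1e-9)
    assert total_after[0] == pytest.approx(cap)


def test_growth_event_count_is_binomial(small_cell, small_params):
    """rate 0.2 over 10^3 calls x 4 filaments: total events within 3 sigma
    of the Binomial(4000, 0.2) mean."""
    rate, n_calls = 0.2, 1000
    params = small_params.replace(growth_rate=rate, growth_increment=0.05,
                                  max_filament_length=1e6)
    rng = np.random.default_rng(7)
    state = small_cell
    term, _ = filament_growth_arrays(state)
    before = state.bond_rest[term].sum()
    for _ in range(n_calls):
        state = grow_filaments(_relax_tips(state), params, rng)
    events = (state.bond_rest[term].sum() - before) / params.growth_increment
    n_trials = n_calls * len(term)
    mean, sd = n_trials * rate, np.sqrt(n_trials * rate * (1 - rate))
    assert abs(events - mean) < 3 * sd


# ------------------------------------------------------------------- runs
def test_run_is_bitwise_deterministic(quick_run_params):
    a = run_simulation(quick_run_params)
    b = run_simulation(quick_run_params)
    assert len(a) == len(b)
    for sa, sb in zip(a.snapshots, b.snapshots):
        np.testing.assert_array_equal(sa.positions, sb.positions)
        np.testing.assert_array_equal(sa.bond_rest, sb.bond_rest)


def test_different_seeds_differ(quick_run_params):
    a = run_simulation(quick_run_params)
    b = run_simulation(quick_run_params.replace(seed=1))
    assert not np.array_equal(a.snapshots[-1].positions, b.snapshots[-1].positions)


def test_bead_count_conserved_every_frame(quick_run_params):
    traj = run_simulation(quick_run_params)
    assert all(s.n_beads == quick_run_params.n_total for s in traj.snapshots)


def test_snapshot_times_strictly_increasing(quick_run_params):
    traj = run_simulation(quick_run_params)
    times = traj.times
    assert np.all(np.diff(times) > 0)
    assert len(traj) == quick_run_params.n_steps // quick_run_params.record_every + 1


def test_zero_temperature_energy_descent(small_params):
    """kT=0, no growth: overdamped dynamics is gradient descent, so the
    recorded total energy never increases (within per-step tolerance)."""
    params = small_params.replace(kT=0.0, growth_rate=0.0, init_noise=0.08,
                                  n_steps=2000, record_every=100)
    traj = run_simulation(params)
    energies = [total_energy(s, params).total for s in traj.snapshots]
    for e0, e1 in zip(energies, energies[1:]):
        assert e1 <= e0 + 1e-8 * max(1.0, abs(e0))


def test_membrane_bonds_stay_below_rupture_guard(quick_run_params):
    traj = run_simulation(quick_run_params)
    for s in traj.snapshots:
        mem = s.bond_kind == int(BondKind.MEMBRANE)
        d = np.linalg.norm(s.positions[s.bonds_ij[mem, 0]]
                           - s.positions[s.bonds_ij[mem, 1]], axis=1)
        assert np.all(d <= 3.0 * s.bond_rest[mem])


def test_instability_error_reports_step_and_bead(small_params, small_cell):
    """A membrane bond beyond 3x its rest length (here: one bead displaced
    outward by hand) must abort the run with the rupture error, naming the
    step at which the guard fired."""
    torn = small_cell.copy()
    bead = int(torn.membrane_indices[0])
    torn.positions[bead] *= 1.9  # both adjacent membrane bonds now > 3x rest
    params = small_params.replace(n_steps=1_000, record_every=100, kT=0.0)
    with pytest.raises(NumericalInstabilityError) as exc_info:
        run_simulation(params, initial_state=torn)
    assert exc_info.value.step >= 0


def test_resume_from_snapshot_continues_exactly(small_params):
    """A run split in two at a snapshot equals the unsplit run bitwise."""
    params = small_params.replace(n_steps=400, record_every=200)
    full = run_simulation(params)
    first = run_simulation(params.replace(n_steps=200))
    second = run_simulation(params.replace(n_steps=200),
                            initial_state=first.snapshots[-1])
    np.testing.assert_array_equal(second.snapshots[-1].positions,
                                  full.snapshots[-1].positions)
    assert second.snapshots[-1].time == pytest.approx(full.snapshots[-1].time)


def test_timestep_halving_changes_little(small_params):
    """Integration-error control: halving dt changes the final projection
    length of a zero-temperature fixture run by < 5%."""
    from neuritesim import projection_length
    base = small_params.replace(kT=0.0, init_noise=0.1, growth_rate=0.0,
                                n_steps=4000, record_every=4000)
    half = base.replace(dt=base.dt / 2, n_steps=8000, record_every=8000)
    p1 = projection_length(run_simulation(base).snapshots[-1])
    p2 = projection_length(run_simulation(half).snapshots[-1])
    assert p2 == pytest.approx(p1, rel=0.05, abs=0.02)


def test_suggest_timestep_respects_stiffest_mode():
    p = SimulationParameters()
    dt = suggest_timestep(p)
    assert dt <= p.dt
    stiff = p.replace(U3=30.0)
    assert suggest_timestep(stiff) < dt
    # adhesion-well curvature dominates: ~57 U3 / sigma_attr^2
    assert suggest_timestep(stiff) == pytest.approx(
        0.1 / (57.1464 * 30.0 / p.sigma_attr_effective**2), rel=1e-6)


def test_trajectory_metadata(quick_run_params):
    traj = run_simulation(quick_run_params)
    assert traj.wall_metadata["seed"] == quick_run_params.seed
    assert traj.record_every == quick_run_params.record_every
    assert traj.params == quick_run_params
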