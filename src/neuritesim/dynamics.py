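"""Overdamped Langevin time integration and stochastic filament growth.

The cell is inertia-free at its scale, so positions follow the
first-order Euler–Maruyama update

    x <- x + (F / gamma) dt + sqrt(2 kT dt / gamma) xi,

with ``xi`` a standard normal per coordinate.  Filament tips lengthen by
stochastically incrementing the rest length of the terminal (head) bond,
which keeps the bead count constant throughout a run.

Two equivalent integration routes exist: :func:`step_overdamped` (pure
NumPy, the reference definition) and the compiled chunked loop used by
:func:`run_simulation`.  The run loop draws all randomness from a single
seeded generator in a fixed order (per chunk: a block of normals, then a
block of growth uniforms), so a run is a pure function of its parameters
and seed, and is resumable from any snapshot's serialized RNG state.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from . import _kernels, energetics
from .errors import NumericalInstabilityError
from .model import BondKind, CellState, Role, build_cell, perturb_positions
from .params import SimulationParameters, WCA_CUT_FACTOR

logger = logging.getLogger(__name__)

#: Verlet-list skin in units of sigma (rebuild at half-skin displacement).
VERLET_SKIN = 1.0
#: maximum steps integrated per compiled-kernel call (bounds noise memory).
CHUNK_STEPS = 512

#: curvature of the LJ potential at its minimum, per unit well depth.
_LJ_CURVATURE = 57.1464
#: per-step displacement cap in units of sigma (see step_overdamped).
MAX_STEP_FACTOR = 0.1


def _step_cap(params: SimulationParameters) -> float:
    """Per-step displacement cap: never below six standard deviations of
    the thermal step, so the limiter cannot bias free diffusion."""
    amp = np.sqrt(2.0 * params.kT * params.dt / params.gamma)
    return max(MAX_STEP_FACTOR * params.sigma, 6.0 * amp)


@dataclass
class Trajectory:
    """Ordered snapshots of a run plus the parameters that produced it."""

    snapshots: list[CellState]
    record_every: int
    params: SimulationParameters
    wall_metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])


def suggest_timestep(params: SimulationParameters, safety: float = 0.1) -> float:
    """Largest timestep compatible with the stiffest mode of the model.

    Considers bond springs (including the membrane tension kappa00), the
    transverse stiffness of the stiffest bending term (about
    ``4 k_bend / l^2`` for bond length ``l``), and the curvature of the
    adhesion well (``~57 U3 / sigma_attr^2``).  Returns
    ``min(params.dt, safety * gamma / k_max)``.
    """
    bend = max(params.kappa_bend_membrane, params.kappa_nuclear_effective,
               params.kappa_anchor,
               params.kappa_filament * (params.mt_stiffness_factor
                                        if params.mt_fraction > 0 else 1.0))
    k_max = max(
        params.kappa,
        2.0 * params.kappa00,  # FENE tether stiffens beyond its linear range
        4.0 * bend / params.sigma**2,
        _LJ_CURVATURE * params.epsilon_repulsion / params.sigma**2,
        _LJ_CURVATURE * params.U3 / params.sigma_attr_effective**2,
    )
    return min(params.dt, safety * params.gamma / k_max)


# ---------------------------------------------------------------------
# growth bookkeeping
# ---------------------------------------------------------------------

def filament_growth_arrays(state: CellState):
    """Per-filament terminal-bond index and total rest length.

    Returns ``(term_bond_idx, fil_rest_total)``, both indexed by filament
    id.  The terminal bond is the filament bond incident to the head bead.
    """
    heads = state.indices_of(Role.ACTIN_HEAD)
    n_fil = len(heads)
    term = np.full(n_fil, -1, dtype=np.int64)
    total = np.zeros(n_fil)
    fid = state.filament_ids
    for b in range(state.n_bonds):
        kind = int(state.bond_kind[b])
        if kind not in (int(BondKind.FILAMENT), int(BondKind.ANCHOR)):
            continue
        i, j = int(state.bonds_ij[b, 0]), int(state.bonds_ij[b, 1])
        f = max(int(fid[i]), int(fid[j]))
        if f < 0:
            continue
        total[f] += state.bond_rest[b]
        if kind == int(BondKind.FILAMENT) and (
                int(state.roles[i]) == int(Role.ACTIN_HEAD)
                or int(state.roles[j]) == int(Role.ACTIN_HEAD)):
            term[f] = b
    if n_fil and np.any(term < 0):
        raise ValueError("could not locate a terminal bond for every filament")
    return term, total


def grow_filaments(state: CellState, params: SimulationParameters,
                   rng: np.random.Generator) -> CellState:
    """One growth update: each filament's terminal bond rest length grows
    by ``growth_increment`` with probability ``growth_rate``, capped at
    ``max_filament_length`` total rest length and stalled while the
    terminal bond is compressed beyond ``growth_stall_deficit`` (the
    finite stall force of a polymerizing tip).  Bead count is unchanged."""
    term, total = filament_growth_arrays(state)
    new = state.copy()
    if term.size == 0:
        return new
    u = rng.random(term.size)
    for f in range(term.size):
        if u[f] < params.growth_rate and \
                total[f] + params.growth_increment <= params.max_filament_length + 1e-12:
            b = term[f]
            i, j = state.bonds_ij[b]
            length = float(np.linalg.norm(state.positions[i] - state.positions[j]))
            if state.bond_rest[b] - length < params.growth_stall_deficit:
                new.bond_rest[b] += params.growth_increment
    return new


# ---------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------

def step_overdamped(state: CellState, params: SimulationParameters,
                    rng: np.random.Generator) -> CellState:
    """One Euler–Maruyama step through the reference (NumPy) force path.

    Per-step displacements are capped at
    ``max(MAX_STEP_FACTOR * sigma, 6 * noise amplitude)`` — at least six
    standard deviations of the thermal step, at any timestep, so free
    diffusion is unbiased: the cap never binds during regular dynamics and only
    arrests the runaway launch of a bead transiently driven deep into a
    repulsive core, where the local stiffness exceeds the stable-timestep
    bound.
    """
    F = energetics.total_forces(state, params)
    n = state.n_beads
    noise = rng.standard_normal((n, 2))
    amp = np.sqrt(2.0 * params.kT * params.dt / params.gamma)
    new = state.copy()
    step_disp = F * (params.dt / params.gamma) + amp * noise
    cap = _step_cap(params)
    norms = np.linalg.norm(step_disp, axis=1)
    over = norms > cap
    if np.any(over):
        step_disp[over] *= (cap / norms[over])[:, None]
    if state.pinned is not None:
        step_disp[state.pinned] = 0.0
    new.positions = state.positions + step_disp
    if not np.all(np.isfinite(new.positions)):
        bead = int(np.flatnonzero(~np.isfinite(new.positions).all(axis=1))[0])
        raise NumericalInstabilityError(
            f"non-finite position at bead {bead} (t={state.time:.6g})", bead=bead)
    new.time = state.time + params.dt
    return new


_STATUS_MSG = {
    1: "non-finite position",
    2: "membrane bond stretched beyond 3x rest length",
    3: "bead pair collapsed to zero distance",
}


def run_simulation(params: SimulationParameters,
                   initial_state: CellState | None = None) -> Trajectory:
    """Build, perturb, and integrate a cell; record every ``record_every``
    steps (the initial perturbed state is frame 0).

    Deterministic: identical parameters (including seed) give bitwise
    identical trajectories.  Raises :class:`NumericalInstabilityError`
    with the offending step and bead on blow-up or membrane rupture.

    ``initial_state`` continues from an existing snapshot instead of
    building a fresh cell; if the snapshot carries a serialized RNG state
    the noise stream resumes exactly where the producing run left off.
    """
    params.validate()
    if initial_state is None:
        state = build_cell(params)
        rng = np.random.default_rng(params.seed)
        state = perturb_positions(state, params.init_noise, rng=rng)
    else:
        state = initial_state.copy()
        rng = np.random.default_rng(params.seed)
        if state.rng_state is not None:
            rng.bit_generator.state = state.rng_state

    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    bond_rest = state.bond_rest.copy()
    bonds_i = np.ascontiguousarray(state.bonds_ij[:, 0], dtype=np.int32)
    bonds_j = np.ascontiguousarray(state.bonds_ij[:, 1], dtype=np.int32)
    mem_bond_idx = np.flatnonzero(
        state.bond_kind == int(BondKind.MEMBRANE)).astype(np.int64)
    ang_i = np.ascontiguousarray(state.angles_ijk[:, 0], dtype=np.int32)
    ang_j = np.ascontiguousarray(state.angles_ijk[:, 1], dtype=np.int32)
    ang_k = np.ascontiguousarray(state.angles_ijk[:, 2], dtype=np.int32)
    excl = energetics.bonded_pair_codes(state)
    term_idx, fil_total = filament_growth_arrays(state)
    mobile = np.ones(state.n_beads, dtype=np.bool_)
    if state.pinned is not None:
        mobile = ~state.pinned

    n_fil = term_idx.size

    def snapshot(t: float) -> CellState:
        snap = state.copy()
        snap.positions = pos.copy()
        snap.bond_rest = bond_rest.copy()
        snap.time = t
        snap.rng_state = rng.bit_generator.state
        return snap

    t0 = state.time
    snapshots = [snapshot(t0)]
    done = 0
    while done < params.n_steps:
        next_record = min(params.n_steps,
                          (done // params.record_every + 1) * params.record_every)
        chunk = min(CHUNK_STEPS, next_record - done)
        noise = rng.standard_normal((chunk, state.n_beads, 2))
        growth_u = rng.random((chunk, n_fil))
        status, step_local, bead = _kernels.integrate_chunk(
            pos, noise, growth_u,
            state.roles,
            bonds_i, bonds_j, bond_rest, state.bond_stiffness,
            np.minimum(state.bond_max_ext, 1e30),
            mem_bond_idx,
            ang_i, ang_j, ang_k, state.angle_theta0, state.angle_stiffness,
            excl,
            term_idx, fil_total,
            mobile,
            params.dt, params.gamma, params.kT, params.sigma,
            params.sigma_attr_effective,
            params.epsilon_repulsion, params.U3, params.r_cut_attr,
            params.attract_heads_only,
            params.growth_rate if n_fil else 0.0,
            params.growth_increment, params.growth_stall_deficit,
            params.max_filament_length,
            VERLET_SKIN * params.sigma,
            _step_cap(params),
        )
        if status != 0:
            step = done + step_local
            raise NumericalInstabilityError(
                f"{_STATUS_MSG[status]} at step {step}, bead {bead} "
                f"(t={t0 + step * params.dt:.6g})", step=step, bead=bead)
        done += chunk
        if done % params.record_every == 0 or done == params.n_steps:
            snapshots.append(snapshot(t0 + done * params.dt))

    meta = {
        "seed": params.seed,
        "package_version": _pkg_version,
        "n_steps": params.n_steps,
        "dt": params.dt,
    }
    logger.info("run finished: %d steps, %d frames", params.n_steps, len(snapshots))
    return Trajectory(snapshots=snapshots, record_every=params.record_every,
                      params=params, wall_metadata=meta)
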