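"""Potential-energy terms and forces.

Four terms compose the Hamiltonian:

* harmonic springs of stiffness ``kappa`` along all bonds,
  ``E = 1/2 k (r - r0)^2``;
* discrete bending ``E = k_bend (1 - cos(theta - theta0))`` on angle
  triples — the membrane ring carries ``kappa00`` here, which is the
  model's membrane tension / elasticity;
* membrane–actin adhesion: a truncated-and-shifted Lennard-Jones well
  of depth ``U3`` cut at ``r_cut_attr`` — the model's cortical tension.
  Core and tail both scale with ``U3``, so the coupling disappears
  entirely as cortical tension goes to zero (clutch disengagement);
* WCA excluded volume between all remaining non-bonded pairs.

Every term exposes energy *and* analytic forces; consistency with the
numerical gradient is enforced by the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError
from .model import AngleTriple, CellState, Role
from .params import SimulationParameters, WCA_CUT_FACTOR

_MIN_DIST = 1e-12


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term decomposition of the total potential energy."""

    spring: float
    bending: float
    attraction: float
    excluded_volume: float
    total: float

    def __post_init__(self):
        parts = self.spring + self.bending + self.attraction + self.excluded_volume
        scale = max(1.0, abs(self.total))
        if abs(parts - self.total) > 1e-9 * scale:
            raise ValueError("EnergyBreakdown total does not equal the sum of parts")


# ---------------------------------------------------------------------
# per-term operations
# ---------------------------------------------------------------------

def spring_energy_force(pos_i, pos_j, stiffness: float, rest_length: float):
    """Harmonic bond: returns ``(energy, force_on_i, force_on_j)``."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    d = pos_i - pos_j
    r = float(np.linalg.norm(d))
    if r < _MIN_DIST:
        raise GeometryError("coincident beads in spring_energy_force")
    stretch = r - rest_length
    energy = 0.5 * stiffness * stretch * stretch
    f_i = -stiffness * stretch * d / r
    return energy, f_i, -f_i


def bending_energy_force(triple: AngleTriple, positions: np.ndarray, kappa00: float):
    """Discrete bending at the middle bead of an angle triple.

    Energy ``kappa00 * (1 - cos(theta - theta0))`` with ``theta`` the
    signed angle at bead ``j`` from ``(i - j)`` to ``(k - j)``; bounded in
    ``[0, 2*kappa00]``.  Returns ``(energy, (f_i, f_j, f_k))``.
    """
    ri, rj, rk = (np.asarray(positions[x], dtype=float) for x in (triple.i, triple.j, triple.k))
    a = ri - rj
    b = rk - rj
    la2 = float(a @ a)
    lb2 = float(b @ b)
    if la2 < _MIN_DIST**2 or lb2 < _MIN_DIST**2:
        raise GeometryError("coincident beads in bending_energy_force")
    theta = float(np.arctan2(a[0] * b[1] - a[1] * b[0], a @ b))
    delta = theta - triple.preferred_angle
    energy = kappa00 * (1.0 - np.cos(delta))
    dE = kappa00 * np.sin(delta)
    # dtheta/dri = (a_y, -a_x)/|a|^2 ; dtheta/drk = (-b_y, b_x)/|b|^2
    g_i = np.array([a[1], -a[0]]) / la2
    g_k = np.array([-b[1], b[0]]) / lb2
    f_i = -dE * g_i
    f_k = -dE * g_k
    f_j = -(f_i + f_k)
    return float(energy), (f_i, f_j, f_k)


def _lj(r, eps, sigma):
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


def _lj_force(r, eps, sigma):
    """Radial force -dE/dr of the (unshifted) LJ potential."""
    sr6 = (sigma / r) ** 6
    return 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r


def excluded_volume_energy_force(distance: float, sigma: float = 1.0,
                                 epsilon: float = 1.0):
    """WCA repulsion: LJ shifted up by ``epsilon`` and cut at 2^(1/6) sigma.

    Returns ``(energy, radial_force)`` with the force positive = repulsive
    (acting to increase the distance).
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance <= 0):
        raise GeometryError("non-positive distance in excluded_volume_energy_force")
    rc = WCA_CUT_FACTOR * sigma
    inside = distance < rc
    energy = np.where(inside, _lj(np.where(inside, distance, rc), epsilon, sigma) + epsilon, 0.0)
    force = np.where(inside, _lj_force(np.where(inside, distance, rc), epsilon, sigma), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def attraction_energy_force(distance: float, U3: float, sigma: float = 1.0,
                            r_cut_attr: float = 2.5):
    """Membrane–actin adhesion: truncated-and-shifted LJ well of depth U3.

    ``sigma`` is the contact range of this term (for membrane–actin pairs
    the narrow ``sigma_attr_effective``); ``r_cut_attr`` is the absolute
    cutoff distance.  The well attains its minimum
    ``-U3 * (1 - |LJ(r_cut)|/U3)`` at ``2^(1/6) sigma`` and vanishes
    continuously at ``r_cut_attr``.  Both the attractive tail and the
    repulsive core scale with U3 — the whole membrane-cytoskeleton
    coupling, stickiness *and* grip, is cortical tension: with U3 = 0 the
    membrane does not feel the filament tips at all, and a weakly coupled
    tip under load can slip through the membrane ring (the clutch
    disengages).  Returns ``(energy, radial_force)``.
    """
    distance = np.asarray(distance, dtype=float)
    if np.any(distance <= 0):
        raise GeometryError("non-positive distance in attraction_energy_force")
    rc = r_cut_attr
    inside = distance < rc
    shift = _lj(rc, U3, sigma)
    safe = np.where(inside, distance, rc)
    energy = np.where(inside, _lj(safe, U3, sigma) - shift, 0.0)
    force = np.where(inside, _lj_force(safe, U3, sigma), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


# ---------------------------------------------------------------------
# whole-state sums
# ---------------------------------------------------------------------

#: FENE tethers are evaluated no closer than this to their extension
#: limit (the force there is ~50x the linear one; the rupture guard and
#: displacement limiter own anything beyond).
_FENE_CLAMP = 0.99


def tether_energy_force(pos_i, pos_j, stiffness: float, rest_length: float,
                        max_extension: float):
    """Finitely extensible (FENE-style) tether about its rest length.

    ``E = -(k L^2 / 2) ln(1 - (dr/L)^2)`` with ``dr = r - rest`` and ``L``
    the maximum extension: harmonic with stiffness ``k`` at small strain,
    diverging as ``|dr| -> L``.  Used for membrane bonds, whose stiffness
    is the membrane tension kappa00.  Returns
    ``(energy, force_on_i, force_on_j)``.
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    d = pos_i - pos_j
    r = float(np.linalg.norm(d))
    if r < _MIN_DIST:
        raise GeometryError("coincident beads in tether_energy_force")
    x = np.clip((r - rest_length) / max_extension, -_FENE_CLAMP, _FENE_CLAMP)
    energy = -0.5 * stiffness * max_extension**2 * np.log1p(-x * x)
    f_i = -stiffness * (x * max_extension) / (1.0 - x * x) * d / r
    return float(energy), f_i, -f_i


def _bond_terms(state: CellState):
    ij = state.bonds_ij
    d = state.positions[ij[:, 0]] - state.positions[ij[:, 1]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < _MIN_DIST):
        raise GeometryError("coincident bonded beads")
    stretch = r - state.bond_rest
    fene = np.isfinite(state.bond_max_ext)
    energy = np.empty_like(r)
    fmag = np.empty_like(r)
    k = state.bond_stiffness
    energy[~fene] = 0.5 * k[~fene] * stretch[~fene] ** 2
    fmag[~fene] = -k[~fene] * stretch[~fene] / r[~fene]
    if np.any(fene):
        L = state.bond_max_ext[fene]
        x = np.clip(stretch[fene] / L, -_FENE_CLAMP, _FENE_CLAMP)
        energy[fene] = -0.5 * k[fene] * L**2 * np.log1p(-x * x)
        fmag[fene] = -k[fene] * (x * L) / (1.0 - x * x) / r[fene]
    return energy, fmag[:, None] * d


def _angle_terms(state: CellState):
    ijk = state.angles_ijk
    pos = state.positions
    a = pos[ijk[:, 0]] - pos[ijk[:, 1]]
    b = pos[ijk[:, 2]] - pos[ijk[:, 1]]
    la2 = np.einsum("ij,ij->i", a, a)
    lb2 = np.einsum("ij,ij->i", b, b)
    if np.any(la2 < _MIN_DIST**2) or np.any(lb2 < _MIN_DIST**2):
        raise GeometryError("coincident beads in an angle triple")
    theta = np.arctan2(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0],
                       np.einsum("ij,ij->i", a, b))
    delta = theta - state.angle_theta0
    energy = state.angle_stiffness * (1.0 - np.cos(delta))
    dE = state.angle_stiffness * np.sin(delta)
    f_i = -dE[:, None] * np.stack([a[:, 1], -a[:, 0]], axis=1) / la2[:, None]
    f_k = -dE[:, None] * np.stack([-b[:, 1], b[:, 0]], axis=1) / lb2[:, None]
    return energy, f_i, f_k


def bonded_pair_codes(state: CellState) -> np.ndarray:
    """Sorted codes ``min*n + max`` of all bonded pairs (pair exclusions)."""
    n = state.n_beads
    lo = np.minimum(state.bonds_ij[:, 0], state.bonds_ij[:, 1]).astype(np.int64)
    hi = np.maximum(state.bonds_ij[:, 0], state.bonds_ij[:, 1]).astype(np.int64)
    return np.sort(lo * n + hi)


def nonbonded_pairs(state: CellState, params: SimulationParameters):
    """Candidate non-bonded pairs within the largest cutoff.

    Returns ``(i, j, is_attractive)`` index arrays; attractive pairs are
    membrane × actin (heads only if ``attract_heads_only``).
    """
    rc_max = max(params.r_cut_attr, WCA_CUT_FACTOR) * params.sigma
    tree = cKDTree(state.positions)
    pairs = tree.query_pairs(rc_max, output_type="ndarray")
    if pairs.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, np.empty(0, dtype=bool)
    n = state.n_beads
    codes = pairs[:, 0].astype(np.int64) * n + pairs[:, 1]
    excl = bonded_pair_codes(state)
    keep = ~np.isin(codes, excl)
    i, j = pairs[keep, 0], pairs[keep, 1]
    roles = state.roles
    mem_i = roles[i] == int(Role.MEMBRANE)
    mem_j = roles[j] == int(Role.MEMBRANE)
    if params.attract_heads_only:
        act_i = roles[i] == int(Role.ACTIN_HEAD)
        act_j = roles[j] == int(Role.ACTIN_HEAD)
    else:
        act_i = (roles[i] == int(Role.ACTIN_SHAFT)) | (roles[i] == int(Role.ACTIN_HEAD))
        act_j = (roles[j] == int(Role.ACTIN_SHAFT)) | (roles[j] == int(Role.ACTIN_HEAD))
    attractive = (mem_i & act_j) | (mem_j & act_i)
    return i, j, attractive


def _pair_terms(state: CellState, params: SimulationParameters):
    i, j, attractive = nonbonded_pairs(state, params)
    pos = state.positions
    d = pos[i] - pos[j]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < _MIN_DIST):
        raise GeometryError("coincident non-bonded beads")
    e = np.zeros_like(r)
    f = np.zeros_like(r)
    if np.any(attractive):
        e[attractive], f[attractive] = attraction_energy_force(
            r[attractive], params.U3, params.sigma_attr_effective,
            params.r_cut_attr * params.sigma)
    rep = ~attractive
    if np.any(rep):
        e[rep], f[rep] = excluded_volume_energy_force(
            r[rep], params.sigma, params.epsilon_repulsion)
    # radial force f > 0 pushes i and j apart
    fvec = (f / r)[:, None] * d
    return i, j, attractive, e, fvec


def total_energy(state: CellState, params: SimulationParameters) -> EnergyBreakdown:
    """Full potential-energy decomposition of a state."""
    e_bond, _ = _bond_terms(state)
    e_ang, _, _ = _angle_terms(state)
    _, _, attractive, e_pair, _ = _pair_terms(state, params)
    spring = float(np.sum(e_bond))
    bending = float(np.sum(e_ang))
    attraction = float(np.sum(e_pair[attractive]))
    excluded = float(np.sum(e_pair[~attractive]))
    return EnergyBreakdown(
        spring=spring, bending=bending, attraction=attraction,
        excluded_volume=excluded,
        total=spring + bending + attraction + excluded,
    )


def total_forces(state: CellState, params: SimulationParameters) -> np.ndarray:
    """Analytic force on every bead, shape ``(n, 2)``.

    Internal terms only, so the forces sum to zero (Newton's third law).
    """
    n = state.n_beads
    F = np.zeros((n, 2))
    if state.n_bonds:
        _, f_bond = _bond_terms(state)
        np.add.at(F, state.bonds_ij[:, 0], f_bond)
        np.add.at(F, state.bonds_ij[:, 1], -f_bond)
    if state.n_angles:
        _, f_i, f_k = _angle_terms(state)
        np.add.at(F, state.angles_ijk[:, 0], f_i)
        np.add.at(F, state.angles_ijk[:, 2], f_k)
        np.add.at(F, state.angles_ijk[:, 1], -(f_i + f_k))
    i, j, _, _, fvec = _pair_terms(state, params)
    if len(i):
        np.add.at(F, i, fvec)
        np.add.at(F, j, -fvec)
    return F
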