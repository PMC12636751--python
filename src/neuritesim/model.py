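"""Cell geometry: bead roles, topology, construction and validation.

The model cell is two-dimensional: a closed membrane ring, a concentric
nuclear ring, and radial actin filaments whose anchor sits on the nuclear
envelope and whose tip carries a distinct "head" bead.  The head starts
inside the membrane-actin attraction range, so the nuclear envelope is
mechanically connected to the cell membrane through the filaments.

Positions are stored as a dense ``(n, 2)`` float array; topology as index
arrays.  Object views (:class:`Bead`, :class:`Bond`, :class:`AngleTriple`)
are generated on demand for inspection and validation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

from .errors import ConfigurationError, GeometryError
from .params import SimulationParameters

#: extra radial clearance (units of sigma) added to the adhesion-well
#: minimum when placing filament heads below the membrane at construction,
#: so every head starts engaged in (but not at the bottom of) its well.
HEAD_CLEARANCE = 0.15


def head_gap(params: SimulationParameters) -> float:
    """Radial distance between a filament head and the membrane ring at
    construction: just outside the adhesion-well minimum."""
    from .params import WCA_CUT_FACTOR
    return WCA_CUT_FACTOR * params.sigma_attr_effective + HEAD_CLEARANCE * params.sigma


class Role(IntEnum):
    MEMBRANE = 0
    NUCLEAR = 1
    ACTIN_SHAFT = 2
    ACTIN_HEAD = 3


class BondKind(IntEnum):
    MEMBRANE = 0
    NUCLEAR = 1
    FILAMENT = 2
    ANCHOR = 3


@dataclass(frozen=True)
class Bead:
    id: int
    role: Role
    position: np.ndarray
    filament_id: Optional[int]


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    rest_length: float
    stiffness: float
    kind: BondKind


@dataclass(frozen=True)
class AngleTriple:
    i: int
    j: int
    k: int
    preferred_angle: float
    stiffness: float


@dataclass
class CellState:
    """One time point of the cell: positions plus full interaction topology.

    ``positions`` is (n, 2); ``bonds_ij`` (nb, 2); ``angles_ijk`` (na, 3).
    ``filament_ids`` is -1 for beads not on a filament.  ``pinned`` is an
    optional boolean mask of immobilized beads (boundary conditions for
    validation experiments); ``None`` means all beads are mobile.
    """

    positions: np.ndarray
    roles: np.ndarray
    filament_ids: np.ndarray
    bonds_ij: np.ndarray
    bond_rest: np.ndarray
    bond_stiffness: np.ndarray
    bond_kind: np.ndarray
    angles_ijk: np.ndarray
    angle_theta0: np.ndarray
    angle_stiffness: np.ndarray
    time: float = 0.0
    rng_state: Optional[dict] = None
    pinned: Optional[np.ndarray] = None
    #: per-bond maximum extension beyond rest (FENE tether limit);
    #: ``inf`` marks a plain harmonic bond.  ``None`` means all harmonic.
    bond_max_ext: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.bond_max_ext is None:
            self.bond_max_ext = np.full(self.n_bonds, np.inf)

    # -- sizes --------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds_ij.shape[0]

    @property
    def n_angles(self) -> int:
        return self.angles_ijk.shape[0]

    # -- convenient index sets ----------------------------------------
    def indices_of(self, role: Role) -> np.ndarray:
        return np.flatnonzero(self.roles == int(role))

    @property
    def membrane_indices(self) -> np.ndarray:
        return self.indices_of(Role.MEMBRANE)

    @property
    def nuclear_indices(self) -> np.ndarray:
        return self.indices_of(Role.NUCLEAR)

    @property
    def actin_indices(self) -> np.ndarray:
        return np.flatnonzero(
            (self.roles == int(Role.ACTIN_SHAFT)) | (self.roles == int(Role.ACTIN_HEAD))
        )

    # -- object views -------------------------------------------------
    @property
    def beads(self) -> list[Bead]:
        return [
            Bead(
                id=i,
                role=Role(int(self.roles[i])),
                position=self.positions[i].copy(),
                filament_id=None if self.filament_ids[i] < 0 else int(self.filament_ids[i]),
            )
            for i in range(self.n_beads)
        ]

    @property
    def bonds(self) -> list[Bond]:
        return [
            Bond(
                i=int(self.bonds_ij[b, 0]),
                j=int(self.bonds_ij[b, 1]),
                rest_length=float(self.bond_rest[b]),
                stiffness=float(self.bond_stiffness[b]),
                kind=BondKind(int(self.bond_kind[b])),
            )
            for b in range(self.n_bonds)
        ]

    @property
    def angles(self) -> list[AngleTriple]:
        return [
            AngleTriple(
                i=int(self.angles_ijk[a, 0]),
                j=int(self.angles_ijk[a, 1]),
                k=int(self.angles_ijk[a, 2]),
                preferred_angle=float(self.angle_theta0[a]),
                stiffness=float(self.angle_stiffness[a]),
            )
            for a in range(self.n_angles)
        ]

    def copy(self) -> "CellState":
        """Deep copy of mutable arrays; topology index arrays are shared
        (they never change during a run)."""
        return CellState(
            positions=self.positions.copy(),
            roles=self.roles,
            filament_ids=self.filament_ids,
            bonds_ij=self.bonds_ij,
            bond_rest=self.bond_rest.copy(),
            bond_stiffness=self.bond_stiffness,
            bond_kind=self.bond_kind,
            bond_max_ext=self.bond_max_ext,
            angles_ijk=self.angles_ijk,
            angle_theta0=self.angle_theta0,
            angle_stiffness=self.angle_stiffness,
            time=self.time,
            rng_state=self.rng_state,
            pinned=None if self.pinned is None else self.pinned.copy(),
        )


def signed_angle(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Signed angle from vector ``a`` to vector ``b`` in (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cross = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    dot = a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]
    return np.arctan2(cross, dot)


def _ring_positions(n: int, radius: float) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def build_cell(params: SimulationParameters) -> CellState:
    """Construct the initial cell at mechanical rest.

    Geometry: nuclear ring with unit-chord spacing (circumradius
    ``R_nuc = sigma / (2 sin(pi/n_nuclear))``); filaments radial with bead
    spacing ``sigma``; membrane ring at
    ``R_mem = R_nuc + beads_per_filament*sigma + head_gap(params)`` so
    every head bead starts engaged in the adhesion well of the membrane.
    All bond rest lengths and preferred angles are taken from the as-built
    geometry, so the fresh cell is stress free.
    """
    params.validate()
    s = params.sigma
    n_mem, n_nuc, n_fil, bpf = (
        params.n_membrane, params.n_nuclear, params.n_filaments, params.beads_per_filament,
    )

    gap = head_gap(params)
    r_nuc = s / (2.0 * math.sin(math.pi / n_nuc))
    r_mem = r_nuc + bpf * s + gap
    if r_nuc >= r_mem:
        raise ConfigurationError("nuclear radius >= membrane radius")

    n = params.n_total
    positions = np.zeros((n, 2))
    roles = np.full(n, -1, dtype=np.int8)
    filament_ids = np.full(n, -1, dtype=np.int32)

    mem_ids = np.arange(0, n_mem)
    nuc_ids = np.arange(n_mem, n_mem + n_nuc)
    positions[mem_ids] = _ring_positions(n_mem, r_mem)
    positions[nuc_ids] = _ring_positions(n_nuc, r_nuc)
    roles[mem_ids] = int(Role.MEMBRANE)
    roles[nuc_ids] = int(Role.NUCLEAR)

    bonds: list[tuple[int, int, float, float, int]] = []
    angles: list[tuple[int, int, int, float, float]] = []

    def _ring_topology(ids: np.ndarray, radius: float, n_ring: int, kind: BondKind,
                       spring_k: float, bend_k: float) -> None:
        chord = 2.0 * radius * math.sin(math.pi / n_ring)
        for a in range(n_ring):
            i, j = int(ids[a]), int(ids[(a + 1) % n_ring])
            bonds.append((i, j, chord, spring_k, int(kind)))
            k = int(ids[(a + 2) % n_ring])
            # preferred angle = as-built angle (stress-free circle); the
            # magnitude is the polygon interior angle pi - 2*pi/n_ring
            t0 = float(signed_angle(positions[i] - positions[j],
                                    positions[k] - positions[j]))
            if t0 <= 0.0:  # map into (0, 2*pi); cos(theta - t0) unchanged
                t0 += 2.0 * math.pi
            angles.append((i, j, k, t0, bend_k))

    _ring_topology(mem_ids, r_mem, n_mem, BondKind.MEMBRANE,
                   params.kappa00, params.kappa_bend_membrane)
    _ring_topology(nuc_ids, r_nuc, n_nuc, BondKind.NUCLEAR,
                   params.kappa, params.kappa_nuclear_effective)

    # Filaments: radial chains anchored to the nearest nuclear bead.
    n_mt = int(round(params.mt_fraction * n_fil))
    next_id = n_mem + n_nuc
    for f in range(n_fil):
        phi = 2.0 * math.pi * f / n_fil
        # nearest nuclear bead by angle
        anchor = int(nuc_ids[int(round(phi / (2.0 * math.pi / n_nuc))) % n_nuc])
        chain = [anchor]
        u = np.array([math.cos(phi), math.sin(phi)])
        # Radial head placement: head_gap(params) below the membrane
        # radius by default, pulled outward if the nearest membrane bead
        # (which can be angularly offset on sparse rings) would fall
        # outside the attraction range.
        r_head = r_nuc + bpf * s
        mem_pos = positions[mem_ids]
        d_near = np.min(np.linalg.norm(mem_pos - r_head * u, axis=1))
        rc = 0.98 * params.r_cut_attr * s
        if d_near >= rc:
            m = mem_pos[np.argmin(np.linalg.norm(mem_pos - r_head * u, axis=1))]
            um = float(u @ m)
            disc = um * um - float(m @ m) + rc * rc
            if disc <= 0:
                raise ConfigurationError(
                    "membrane ring too sparse: no head placement reaches the "
                    "attraction range; increase n_membrane or r_cut_attr")
            r_head = um - math.sqrt(disc)
            if r_head <= r_nuc + (bpf - 0.5) * s:
                raise ConfigurationError(
                    "membrane ring too sparse: head cannot reach the "
                    "attraction range without collapsing the filament")
        for b in range(bpf):
            bead = next_id
            next_id += 1
            radius = r_head if b == bpf - 1 else r_nuc + (b + 1) * s
            positions[bead] = radius * u
            roles[bead] = int(Role.ACTIN_HEAD) if b == bpf - 1 else int(Role.ACTIN_SHAFT)
            filament_ids[bead] = f
            chain.append(bead)
        bend_k = params.kappa_filament * (params.mt_stiffness_factor if f < n_mt else 1.0)
        for a in range(len(chain) - 1):
            i, j = chain[a], chain[a + 1]
            rest = float(np.linalg.norm(positions[j] - positions[i]))
            kind = BondKind.ANCHOR if a == 0 else BondKind.FILAMENT
            bonds.append((i, j, rest, params.kappa, int(kind)))
        for a in range(len(chain) - 2):
            i, j, k = chain[a], chain[a + 1], chain[a + 2]
            t0 = float(signed_angle(positions[i] - positions[j],
                                    positions[k] - positions[j]))
            if t0 <= 0.0:  # keep preferred angles in (0, 2*pi)
                t0 += 2.0 * math.pi
            # the base joint (anchor bead at the hinge) stays soft so the
            # filament can pivot; the shaft itself is rod-like
            stiff = params.kappa_anchor if a == 0 else bend_k
            angles.append((i, j, k, t0, stiff))

    assert next_id == n

    bond_arr = np.array([(b[0], b[1]) for b in bonds], dtype=np.int32).reshape(-1, 2)
    kinds = np.array([b[4] for b in bonds], dtype=np.int8)
    # membrane bonds are finitely extensible tethers; all others harmonic
    max_ext = np.where(kinds == int(BondKind.MEMBRANE),
                       params.membrane_max_extension * params.sigma, np.inf)
    state = CellState(
        positions=positions,
        roles=roles,
        filament_ids=filament_ids,
        bonds_ij=bond_arr,
        bond_rest=np.array([b[2] for b in bonds], dtype=float),
        bond_stiffness=np.array([b[3] for b in bonds], dtype=float),
        bond_kind=kinds,
        bond_max_ext=max_ext,
        angles_ijk=np.array([(a[0], a[1], a[2]) for a in angles],
                            dtype=np.int32).reshape(-1, 3),
        angle_theta0=np.array([a[3] for a in angles], dtype=float),
        angle_stiffness=np.array([a[4] for a in angles], dtype=float),
        time=0.0,
    )
    violations = validate_state(state, params)
    if violations:
        raise GeometryError("built cell violates invariants: " + "; ".join(violations))
    return state


def _ring_violations(state: CellState, role: Role, kind: BondKind, label: str) -> list[str]:
    """Check that beads of ``role`` form exactly one closed cycle of bonds
    of ``kind`` by brute-force walking."""
    out: list[str] = []
    members = set(state.indices_of(role).tolist())
    ring_bonds = [
        (int(i), int(j))
        for (i, j), k in zip(state.bonds_ij, state.bond_kind)
        if int(k) == int(kind)
    ]
    adj: dict[int, list[int]] = {m: [] for m in members}
    for i, j in ring_bonds:
        if i not in members or j not in members:
            out.append(f"{label}: bond ({i},{j}) touches a bead of the wrong role")
            return out
        adj[i].append(j)
        adj[j].append(i)
    bad_degree = [m for m, nb in adj.items() if len(nb) != 2]
    if bad_degree:
        out.append(f"{label}: ring not closed; beads with degree != 2: {sorted(bad_degree)[:5]}")
        return out
    if not members:
        return out
    start = min(members)
    seen = {start}
    prev, cur = None, start
    for _ in range(len(members)):
        nxt = [b for b in adj[cur] if b != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        seen.add(cur)
    if seen != members:
        out.append(f"{label}: membrane bonds form more than one cycle "
                   f"({len(seen)} of {len(members)} beads reachable)")
    return out


def validate_state(state: CellState, params: SimulationParameters | None = None) -> list[str]:
    """Diagnostic invariant check; returns a list of violation messages.

    Never mutates the state.  An empty list means the state is valid.
    When ``params`` is given, role counts are checked against the budget,
    and for a fresh state (time == 0) the initial membrane-actin
    connectivity (every head within the attraction range of the membrane)
    is verified.
    """
    v: list[str] = []
    pos = state.positions
    if pos.ndim != 2 or pos.shape[1] != 2:
        return [f"positions must be (n, 2); got {pos.shape}"]
    if not np.all(np.isfinite(pos)):
        v.append("non-finite positions")

    if state.bond_rest.size and np.any(state.bond_rest <= 0):
        v.append("non-positive bond rest length")
    if state.bond_stiffness.size and np.any(state.bond_stiffness <= 0):
        v.append("non-positive bond stiffness")
    if state.bonds_ij.size and np.any(state.bonds_ij[:, 0] == state.bonds_ij[:, 1]):
        v.append("self-bond (i == j)")
    if state.angles_ijk.size:
        a = state.angles_ijk
        if np.any((a[:, 0] == a[:, 1]) | (a[:, 1] == a[:, 2]) | (a[:, 0] == a[:, 2])):
            v.append("angle triple with repeated bead")
        if np.any((state.angle_theta0 <= 0) | (state.angle_theta0 >= 2 * np.pi)):
            v.append("preferred angle outside (0, 2*pi)")

    v += _ring_violations(state, Role.MEMBRANE, BondKind.MEMBRANE, "membrane")
    v += _ring_violations(state, Role.NUCLEAR, BondKind.NUCLEAR, "nuclear")

    # filament chains: per filament, shaft+head beads form a simple path
    # whose first bead is bonded to a nuclear bead by an anchor bond.
    fil_ids = np.unique(state.filament_ids[state.filament_ids >= 0])
    heads = state.indices_of(Role.ACTIN_HEAD)
    if len(heads) != len(fil_ids):
        v.append(f"{len(heads)} head beads for {len(fil_ids)} filaments")
    anchor_mask = state.bond_kind == int(BondKind.ANCHOR)
    fil_mask = state.bond_kind == int(BondKind.FILAMENT)
    for f in fil_ids:
        members = np.flatnonzero(state.filament_ids == f)
        mset = set(members.tolist())
        chain_bonds = [
            (int(i), int(j)) for (i, j), m in zip(state.bonds_ij, fil_mask)
            if m and (int(i) in mset and int(j) in mset)
        ]
        if len(chain_bonds) != len(members) - 1:
            v.append(f"filament {f}: {len(chain_bonds)} internal bonds for "
                     f"{len(members)} beads (not a simple chain)")
        anchors = [
            (int(i), int(j)) for (i, j), m in zip(state.bonds_ij, anchor_mask)
            if m and (int(i) in mset or int(j) in mset)
        ]
        if len(anchors) != 1:
            v.append(f"filament {f}: expected exactly 1 anchor bond, found {len(anchors)}")
        else:
            i, j = anchors[0]
            outside = i if i not in mset else j
            if int(state.roles[outside]) != int(Role.NUCLEAR):
                v.append(f"filament {f}: anchor bond not attached to a nuclear bead")
        n_heads_f = sum(1 for b in members if int(state.roles[b]) == int(Role.ACTIN_HEAD))
        if n_heads_f != 1:
            v.append(f"filament {f}: {n_heads_f} head beads")

    if params is not None:
        params.validate()
        counts = {
            "n_membrane": (Role.MEMBRANE, params.n_membrane),
            "n_nuclear": (Role.NUCLEAR, params.n_nuclear),
        }
        for name, (role, expected) in counts.items():
            got = len(state.indices_of(role))
            if got != expected:
                v.append(f"{name}: expected {expected}, found {got}")
        if state.n_beads != params.n_total:
            v.append(f"n_total: expected {params.n_total}, found {state.n_beads}")
        if len(heads) != params.n_filaments:
            v.append(f"expected {params.n_filaments} head beads, found {len(heads)}")
        if state.time == 0.0 and len(heads) and params.n_membrane:
            mem = state.positions[state.membrane_indices]
            for h in heads:
                d = np.min(np.linalg.norm(mem - state.positions[h], axis=1))
                if d >= params.r_cut_attr * params.sigma:
                    v.append(f"head bead {int(h)} outside attraction range of membrane "
                             f"(min distance {d:.3f})")
    return v


def perturb_positions(
    state: CellState,
    magnitude: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CellState:
    """Displace every bead by isotropic Gaussian noise of SD ``magnitude``.

    Topology is untouched; the returned state is a new object.  Given the
    same seed the perturbation is reproducible.
    """
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    new = state.copy()
    if magnitude > 0:
        new.positions = new.positions + rng.normal(0.0, magnitude, size=new.positions.shape)
    return new
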