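"""Simulation parameters and configuration-file handling.

All quantities are in reduced units: the bead diameter ``sigma`` sets the
length scale, the thermal energy ``kT`` the energy scale, and the friction
coefficient ``gamma`` the time scale (so one time unit is the time a free
bead needs to diffuse about one bead diameter).  In these units the
adhesion depth ``U3`` and bending stiffness ``kappa00`` are dimensionless
and the literature values (e.g. 3.0 / 30.0 and 10 / 500) can be used
verbatim.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Lennard-Jones minimum position in units of sigma; also the WCA cutoff.
WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class SimulationParameters:
    """Complete, immutable description of one simulation.

    Bead budget
    -----------
    n_total = n_membrane + n_nuclear + n_filaments * beads_per_filament,
    where ``beads_per_filament`` counts shaft beads plus the single head
    bead at the filament tip.  The defaults (240 + 120 + 20*17) give the
    canonical 700-bead cell.

    Energetics
    ----------
    U3 : depth of the membrane-actin adhesion well (cortical tension).
    kappa00 : elastic (spring) constant of the membrane ring bonds — the
        model's membrane tension: it sets how strongly the membrane
        resists changes of its perimeter.  A stiff ring (kappa00 ~ 500)
        is areally inextensible; a soft ring (kappa00 ~ 10) can feed
        protrusions by stretching, and can also be parted locally by a
        filament tip.
    kappa : harmonic bond stiffness of all non-membrane springs (nuclear
        ring, filaments, anchors).
    kappa_bend_membrane : discrete bending stiffness of the membrane
        ring; fixed across the canonical experiments (shape smoothness,
        not tension).
    membrane_max_extension : membrane bonds are finitely extensible
        tethers (FENE-style): harmonic with stiffness kappa00 at small
        strain, diverging as the extension approaches this limit.  Keeps
        even a soft membrane from stretching without bound.
    kappa_filament : bending stiffness along actin filaments; filaments
        flagged "microtubule-like" get kappa_filament * mt_stiffness_factor.
    kappa_anchor : bending stiffness of the joint between the nuclear
        anchor and the filament base — kept soft so filaments can pivot
        about their anchor instead of transmitting torque to the nucleus.
    kappa_nuclear : bending stiffness of the nuclear ring; ``None`` means
        "same as kappa00".  The default is stiff — the nuclear lamina is
        far more rigid than the plasma membrane, and it must bear the
        reaction forces of pushing filaments.
    epsilon_repulsion : WCA excluded-volume energy scale.
    sigma_attr : membrane–actin contact range in units of sigma.  Smaller
        than the bead diameter: an adhesion well much narrower than the
        membrane bead spacing acts as a molecular clutch — a deeply bound
        tip (large U3) stays engaged in the notch between two membrane
        beads and transmits force, while a weakly bound tip under load can
        slip through the ring and stops deforming it.

    Dynamics
    --------
    Overdamped Langevin (Brownian) dynamics with timestep ``dt``; filament
    tips lengthen stochastically: each step, each filament's terminal bond
    rest length grows by ``growth_increment`` with probability
    ``growth_rate``, until the filament's total rest length reaches
    ``max_filament_length``.  Growth stalls under load: while the
    terminal bond is compressed by more than ``growth_stall_deficit``
    (i.e. polymerization pushes against a resisting membrane with more
    than ``kappa * growth_stall_deficit`` of force), no further rest
    length is added — the finite stall force of polymerizing actin.
    """

    # bead budget
    n_total: int = 700
    n_membrane: int = 240
    n_nuclear: int = 120
    n_filaments: int = 20
    beads_per_filament: int = 17

    # energetics
    U3: float = 10.0
    kappa00: float = 10.0
    kappa: float = 500.0
    kappa_bend_membrane: float = 50.0
    membrane_max_extension: float = 1.0
    kappa_filament: float = 100.0
    kappa_anchor: float = 2.0
    kappa_nuclear: float | None = 200.0
    epsilon_repulsion: float = 1.0
    sigma: float = 1.0
    sigma_attr: float = 0.55
    r_cut_attr: float = 2.5
    attract_heads_only: bool = True

    # dynamics
    kT: float = 1.0
    gamma: float = 1.0
    dt: float = 1.5e-4
    n_steps: int = 400_000
    record_every: int = 4_000
    init_noise: float = 0.05

    # filament growth
    growth_rate: float = 2e-3
    growth_increment: float = 0.05
    growth_stall_deficit: float = 0.2
    max_filament_length: float = 40.0
    mt_fraction: float = 0.0
    mt_stiffness_factor: float = 20.0

    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` if any invariant is violated."""
        p = self
        budget = p.n_membrane + p.n_nuclear + p.n_filaments * p.beads_per_filament
        if budget != p.n_total:
            raise ConfigurationError(
                f"bead budget violated: {p.n_membrane} + {p.n_nuclear} + "
                f"{p.n_filaments}*{p.beads_per_filament} = {budget} != n_total={p.n_total}"
            )
        if p.n_membrane < 3 or p.n_nuclear < 3:
            raise ConfigurationError("membrane and nuclear rings need >= 3 beads each")
        if p.n_filaments < 0 or (p.n_filaments > 0 and p.beads_per_filament < 2):
            raise ConfigurationError("filaments need >= 2 beads (one shaft + head)")
        for name in ("U3", "kappa_bend_membrane",
                     "kappa_filament", "kappa_anchor",
                     "epsilon_repulsion", "kT", "mt_fraction", "growth_rate",
                     "growth_stall_deficit", "init_noise"):
            if getattr(p, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if p.kappa_nuclear is not None and p.kappa_nuclear < 0:
            raise ConfigurationError("kappa_nuclear must be >= 0")
        if p.kappa00 <= 0:
            raise ConfigurationError("kappa00 must be > 0 (membrane bond stiffness)")
        for name in ("kappa", "sigma", "gamma", "dt", "growth_increment",
                     "membrane_max_extension",
                     "max_filament_length", "mt_stiffness_factor"):
            if getattr(p, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.0 < p.sigma_attr <= 1.0):
            raise ConfigurationError("sigma_attr must lie in (0, 1]")
        if p.r_cut_attr * p.sigma <= WCA_CUT_FACTOR * p.sigma_attr_effective:
            raise ConfigurationError(
                f"r_cut_attr must exceed the attraction minimum "
                f"2^(1/6)*sigma_attr*sigma = "
                f"{WCA_CUT_FACTOR * p.sigma_attr_effective:.6f}"
            )
        if p.n_steps < 0 or p.record_every <= 0:
            raise ConfigurationError("n_steps >= 0 and record_every > 0 required")
        if not (0.0 <= p.growth_rate <= 1.0):
            raise ConfigurationError("growth_rate must lie in [0, 1]")
        if not (0.0 <= p.mt_fraction <= 1.0):
            raise ConfigurationError("mt_fraction must lie in [0, 1]")

    # -- derived quantities -------------------------------------------
    @property
    def sigma_attr_effective(self) -> float:
        """Membrane–actin contact range in absolute length units."""
        return self.sigma_attr * self.sigma

    @property
    def kappa_nuclear_effective(self) -> float:
        return self.kappa if self.kappa_nuclear is None else self.kappa_nuclear

    @property
    def total_time(self) -> float:
        return self.n_steps * self.dt

    def replace(self, **changes) -> "SimulationParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        """Canonical JSON serialization (sorted keys; used for digests)."""
        return json.dumps(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationParameters":
        """Load parameters from a flat YAML (or JSON) mapping.

        Keys mirror the field names exactly; unknown keys are rejected.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of parameter names")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
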