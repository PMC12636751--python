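"""Trajectory persistence and interchange.

Native format: one HDF5 container per run — header attributes
(format version, bead-budget counts, a SHA-256 digest of the canonical
parameter JSON, frame count), the static topology arrays, and per-frame
positions / bond rest lengths / times / serialized RNG states.  The
round trip is lossless at full double precision, and two writes of the
same trajectory produce byte-identical files.

Extended-XYZ export is a lossy text dump for visualization tools: for
each frame a bead-count line, a comment line with the frame time, then
one ``label x y 0`` record per bead (z padded to 0 for the 2-D model).
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .errors import CorruptTrajectoryError, UnsupportedFormatError
from .model import CellState, Role
from .params import SimulationParameters

FORMAT_VERSION = "1"

#: single-letter labels used in extended-XYZ exports, by role.
XYZ_LABELS = {Role.MEMBRANE: "M", Role.NUCLEAR: "N",
              Role.ACTIN_SHAFT: "A", Role.ACTIN_HEAD: "H"}


def _dset(group, name, data):
    # track_times=False keeps files byte-reproducible
    group.create_dataset(name, data=data, track_times=False)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory to an HDF5 file (see module docstring)."""
    params = trajectory.params
    first = trajectory.snapshots[0]
    n_frames = len(trajectory)
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_total"] = first.n_beads
        f.attrs["n_membrane"] = len(first.membrane_indices)
        f.attrs["n_nuclear"] = len(first.nuclear_indices)
        f.attrs["n_filaments"] = len(first.indices_of(Role.ACTIN_HEAD))
        f.attrs["frame_count"] = n_frames
        f.attrs["record_every"] = trajectory.record_every
        f.attrs["params_json"] = params.to_json()
        f.attrs["params_digest"] = params.digest()
        f.attrs["wall_metadata"] = json.dumps(trajectory.wall_metadata, sort_keys=True)

        topo = f.create_group("topology")
        _dset(topo, "roles", first.roles)
        _dset(topo, "filament_ids", first.filament_ids)
        _dset(topo, "bonds_ij", first.bonds_ij)
        _dset(topo, "bond_stiffness", first.bond_stiffness)
        _dset(topo, "bond_max_ext", first.bond_max_ext)
        _dset(topo, "bond_kind", first.bond_kind)
        _dset(topo, "angles_ijk", first.angles_ijk)
        _dset(topo, "angle_theta0", first.angle_theta0)
        _dset(topo, "angle_stiffness", first.angle_stiffness)

        frames = f.create_group("frames")
        _dset(frames, "positions",
              np.stack([s.positions for s in trajectory.snapshots]))
        _dset(frames, "bond_rest",
              np.stack([s.bond_rest for s in trajectory.snapshots]))
        _dset(frames, "times", np.array([s.time for s in trajectory.snapshots]))
        rng_states = [json.dumps(s.rng_state, sort_keys=True, default=int)
                      for s in trajectory.snapshots]
        _dset(frames, "rng_states", np.array(rng_states, dtype=h5py.string_dtype()))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Raises :class:`UnsupportedFormatError` on a version mismatch and
    :class:`CorruptTrajectoryError` (with the frame index) when the
    per-frame data do not match the header.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise UnsupportedFormatError(
                f"{path}: format version {version!r}, expected {FORMAT_VERSION!r}")
        params = SimulationParameters.from_dict(json.loads(f.attrs["params_json"]))
        if params.digest() != f.attrs["params_digest"]:
            raise CorruptTrajectoryError(f"{path}: parameter digest mismatch")
        n_total = int(f.attrs["n_total"])
        n_frames = int(f.attrs["frame_count"])
        topo = f["topology"]
        roles = topo["roles"][()]
        filament_ids = topo["filament_ids"][()]
        bonds_ij = topo["bonds_ij"][()]
        bond_stiffness = topo["bond_stiffness"][()]
        bond_max_ext = topo["bond_max_ext"][()]
        bond_kind = topo["bond_kind"][()]
        angles_ijk = topo["angles_ijk"][()]
        angle_theta0 = topo["angle_theta0"][()]
        angle_stiffness = topo["angle_stiffness"][()]
        frames = f["frames"]
        positions = frames["positions"][()]
        bond_rest = frames["bond_rest"][()]
        times = frames["times"][()]
        rng_states = [json.loads(s) for s in frames["rng_states"].asstr()[()]]
        meta = json.loads(f.attrs["wall_metadata"])

    for name, arr, expected in (
        ("positions", positions, (n_frames, n_total, 2)),
        ("bond_rest", bond_rest, (n_frames, bonds_ij.shape[0])),
        ("times", times, (n_frames,)),
    ):
        if arr.shape != expected:
            frame = arr.shape[0] if arr.shape[0] != n_frames else -1
            raise CorruptTrajectoryError(
                f"{path}: {name} shape {arr.shape} != {expected}", frame=frame)
    if roles.shape != (n_total,):
        raise CorruptTrajectoryError(f"{path}: roles shape {roles.shape}")

    snapshots = []
    for k in range(n_frames):
        if positions[k].shape != (n_total, 2):
            raise CorruptTrajectoryError(f"{path}: bad frame {k}", frame=k)
        snapshots.append(CellState(
            positions=positions[k].copy(),
            roles=roles, filament_ids=filament_ids,
            bonds_ij=bonds_ij, bond_rest=bond_rest[k].copy(),
            bond_stiffness=bond_stiffness, bond_kind=bond_kind,
            bond_max_ext=bond_max_ext,
            angles_ijk=angles_ijk, angle_theta0=angle_theta0,
            angle_stiffness=angle_stiffness,
            time=float(times[k]), rng_state=rng_states[k],
        ))
    return Trajectory(snapshots=snapshots,
                      record_every=int(meta.get("record_every", 0)) or
                      int(params.record_every),
                      params=params, wall_metadata=meta)


def export_xyz(trajectory: Trajectory, path: str | Path) -> None:
    """Write the trajectory as extended XYZ text (z padded to 0)."""
    with open(path, "w") as fh:
        for s in trajectory.snapshots:
            fh.write(f"{s.n_beads}\n")
            fh.write(f"time={s.time:.9g}\n")
            for i in range(s.n_beads):
                label = XYZ_LABELS[Role(int(s.roles[i]))]
                x, y = s.positions[i]
                fh.write(f"{label} {x:.10g} {y:.10g} 0\n")


def write_morphometrics(result, path: str | Path) -> None:
    """One row per frame, as CSV."""
    pd.DataFrame(result.to_records()).to_csv(path, index=False)


def write_sweep_tables(result, out_dir: str | Path) -> tuple[Path, Path]:
    """Tidy per-replicate table plus per-condition summary, as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep_path = out_dir / "replicates.csv"
    sum_path = out_dir / "summary.csv"
    result.replicate_frame().to_csv(rep_path, index=False)
    result.summary().to_csv(sum_path, index=False)
    return rep_path, sum_path
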