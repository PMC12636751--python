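"""Persist a trajectory, re-load it, re-analyze, and render a snapshot.

The native format is a single HDF5 container (lossless, byte-stable);
extended XYZ is exported for molecular viewers (z padded to 0).
"""
from pathlib import Path

import neuritesim as ns

out = Path("scratch_example_out")
out.mkdir(exist_ok=True)

params = ns.generate_fixture_cell("small").replace(n_steps=2_000,
                                                   record_every=200, seed=4)
trajectory = ns.run_simulation(params)

ns.write_trajectory(trajectory, out / "trajectory.h5")
ns.export_xyz(trajectory, out / "trajectory.xyz")

reloaded = ns.read_trajectory(out / "trajectory.h5")
assert len(reloaded) == len(trajectory)
result = ns.analyze(reloaded, threshold=1.0)
print(f"reloaded {len(reloaded)} frames; "
      f"max projection {result.max_projection_length:.3f} sigma")

ns.render_snapshot(reloaded.snapshots[-1], out / "final_frame.png")
print(f"wrote {out / 'trajectory.h5'}, {out / 'trajectory.xyz'}, "
      f"{out / 'final_frame.png'}")
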