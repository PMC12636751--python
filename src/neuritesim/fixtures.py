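"""Miniature parameter sets for tests and examples."""
from __future__ import annotations

from .params import SimulationParameters


def generate_fixture_cell(scale: str = "small") -> SimulationParameters:
    """Parameters for a test-sized cell.

    ``"small"``: 60 beads (24 membrane, 12 nuclear, 4 filaments of 5
    shaft beads + head) with a short schedule — sub-second runs.
    ``"default"``: the canonical 700-bead configuration.
    """
    if scale == "small":
        return SimulationParameters(
            n_total=60, n_membrane=24, n_nuclear=12,
            n_filaments=4, beads_per_filament=6,
            n_steps=2_000, record_every=200,
        )
    if scale == "default":
        return SimulationParameters()
    raise ValueError(f"unknown fixture scale: {scale!r}")
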