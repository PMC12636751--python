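"""Protrusion morphometrics of the membrane outline.

The membrane ring is treated as a closed polygon.  The *radial excess* of
a membrane bead is its distance from the membrane centroid minus the
baseline radius ``R_base``, defined as the **median** radial distance so
that a single long protrusion does not inflate its own baseline.

* ``projection_length`` — the maximal radial excess (floored at zero):
  the simulated analogue of a neurite projection length.
* ``count_protrusions`` — number of maximal contiguous membrane arcs
  whose radial excess exceeds a threshold, with circular wrap-around.
* ``circularity`` — isoperimetric ratio 4*pi*A/P^2 of the outline.
* ``protrusion_stability`` — fraction of late frames that still carry a
  protrusion above threshold.

All quantities are invariant under rigid motions and under relabeling of
the membrane beads (the ring order is recovered from the bond topology).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .dynamics import Trajectory
from .errors import GeometryError
from .model import BondKind, CellState, Role

#: default protrusion threshold as a fraction of the baseline radius
DEFAULT_THRESHOLD_FRACTION = 0.5
#: default stability window as a fraction of the trajectory length
DEFAULT_WINDOW_FRACTION = 0.25


@dataclass(frozen=True)
class MorphometricsResult:
    """Per-frame outline measurements plus trajectory-level summaries."""

    per_frame: list[tuple[float, float, int, float]]  # (time, projection, count, circularity)
    max_projection_length: float
    stability: float
    threshold: float
    window: int

    def to_records(self) -> list[dict]:
        return [
            {"time": t, "projection_length": p, "protrusion_count": c, "circularity": q}
            for (t, p, c, q) in self.per_frame
        ]


def membrane_ring_order(state: CellState) -> np.ndarray:
    """Membrane bead indices in ring order, recovered from membrane bonds.

    Deterministic: starts at the lowest membrane bead id and walks toward
    its lower-id neighbour; all outline metrics are independent of the
    start and direction.
    """
    members = state.membrane_indices
    if len(members) < 3:
        raise GeometryError("membrane ring needs at least 3 beads")
    adj: dict[int, list[int]] = {int(m): [] for m in members}
    for (i, j), kind in zip(state.bonds_ij, state.bond_kind):
        if int(kind) == int(BondKind.MEMBRANE):
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
    start = int(members.min())
    if len(adj[start]) != 2:
        raise GeometryError("membrane ring is not closed at bead %d" % start)
    order = [start]
    prev, cur = None, start
    nxt = min(adj[start])
    while nxt != start:
        order.append(nxt)
        prev, cur = cur, nxt
        cands = [b for b in adj[cur] if b != prev]
        if len(cands) != 1:
            raise GeometryError("membrane ring is not a simple cycle")
        nxt = cands[0]
    if len(order) != len(members):
        raise GeometryError("membrane bonds do not form a single closed ring")
    return np.array(order, dtype=np.int64)


def _radial_excess(state: CellState) -> tuple[np.ndarray, float]:
    """Radial excess per membrane bead (ring order) and the baseline radius."""
    order = membrane_ring_order(state)
    pts = state.positions[order]
    centroid = pts.mean(axis=0)
    r = np.linalg.norm(pts - centroid, axis=1)
    r_base = float(np.median(r))
    return r - r_base, r_base


def baseline_radius(state: CellState) -> float:
    """Median distance of membrane beads from their centroid (R_base)."""
    return _radial_excess(state)[1]


def projection_length(state: CellState) -> float:
    """Maximal radial excess of the membrane outline, floored at zero."""
    excess, _ = _radial_excess(state)
    return max(0.0, float(excess.max()))


def count_protrusions(state: CellState, threshold: float) -> int:
    """Number of contiguous membrane arcs with radial excess > threshold.

    Wrap-around is handled: an arc spanning the index seam counts once.
    """
    if threshold <= 0:
        raise ValueError("protrusion threshold must be > 0")
    excess, _ = _radial_excess(state)
    above = excess > threshold
    if not above.any():
        return 0
    if above.all():
        return 1
    # count rising edges on the circular sequence
    rising = above & ~np.roll(above, 1)
    return int(rising.sum())


def circularity(state: CellState) -> float:
    """Isoperimetric ratio 4*pi*A/P^2 of the membrane polygon.

    1 in the large-N circular limit; decreases as protrusions form.  A
    self-intersecting outline triggers a warning and the value is still
    computed from the magnitude of the shoelace area.
    """
    order = membrane_ring_order(state)
    pts = state.positions[order]
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    perim = float(np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).sum())
    if perim <= 0:
        raise GeometryError("membrane polygon has zero perimeter")
    ring = LineString(np.vstack([pts, pts[:1]]))
    if not ring.is_simple:
        warnings.warn("membrane outline is self-intersecting; "
                      "circularity computed from |shoelace area|",
                      RuntimeWarning, stacklevel=2)
    return 4.0 * np.pi * area / (perim * perim)


def protrusion_stability(trajectory: Trajectory, threshold: float,
                         window: int) -> float:
    """Fraction of the final ``window`` frames with >= 1 protrusion and a
    projection length above ``threshold``."""
    n = len(trajectory)
    if n == 0:
        raise ValueError("empty trajectory")
    if not (1 <= window <= n):
        raise ValueError(f"window must be in [1, {n}]")
    tail = trajectory.snapshots[-window:]
    hits = sum(
        1 for s in tail
        if count_protrusions(s, threshold) >= 1 and projection_length(s) >= threshold
    )
    return hits / window


def analyze(trajectory: Trajectory, threshold: float | None = None,
            window: int | None = None) -> MorphometricsResult:
    """Full morphometric readout of a trajectory.

    ``threshold`` defaults to ``0.5 * R_base`` of the first frame;
    ``window`` defaults to the final 25% of frames (at least one).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if threshold is None:
        threshold = DEFAULT_THRESHOLD_FRACTION * baseline_radius(trajectory.snapshots[0])
    if window is None:
        window = max(1, round(DEFAULT_WINDOW_FRACTION * len(trajectory)))
    per_frame = [
        (s.time, projection_length(s), count_protrusions(s, threshold), circularity(s))
        for s in trajectory.snapshots
    ]
    return MorphometricsResult(
        per_frame=per_frame,
        max_projection_length=max(p for (_, p, _, _) in per_frame),
        stability=protrusion_stability(trajectory, threshold, window),
        threshold=float(threshold),
        window=int(window),
    )
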