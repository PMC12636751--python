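"""Parameter-sweep experiments: adhesion (U3) sweeps and (U3, kappa00)
phase diagrams with independent seeded replicates.

A sweep is a pure function of the base parameters, the grids, the number
of replicates, and a master seed.  Replicate seeds are derived as
``seed0 + condition_index * 10_000 + replicate_index`` (collision-free
for fewer than 10,000 replicates per condition).

Conditions differ in stiffness, so each condition is integrated with its
own stability-limited timestep while the *physical* schedule is held
fixed: total simulated time, recorded frame count, and filament
elongation speed (growth probability per unit time) are identical across
conditions in a sweep.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import run_simulation, suggest_timestep
from .errors import NumericalInstabilityError
from .morphometrics import analyze
from .params import SimulationParameters

logger = logging.getLogger(__name__)

#: printed adhesion depths of the two-condition comparison (low vs high
#: cortical tension) and its fixed membrane stiffness.
U3_LOW = 3.0
U3_HIGH = 30.0
KAPPA00_STIFF = 500.0
#: fixed membrane stiffness of the five-point U3 sweep.
KAPPA00_SOFT = 10.0
#: five-point geometric U3 grid spanning the printed low..high range.
U3_GRID = tuple(float(x) for x in np.geomspace(U3_LOW, U3_HIGH, 5))

#: absolute protrusion threshold (in sigma) used by the preset experiments.
PROTRUSION_THRESHOLD = 2.0


@dataclass(frozen=True)
class ReplicateRecord:
    seed: int
    max_projection_length: float
    stability: float
    final_protrusion_count: int
    failed: bool = False
    error: str | None = None


@dataclass
class SweepResult:
    """Per-(condition, replicate) morphometrics of a parameter sweep."""

    conditions: list[tuple[float, float]]  # (U3, kappa00)
    per_condition: list[list[ReplicateRecord]]
    base: SimulationParameters
    n_replicates: int
    seed0: int
    threshold: float | None = None
    window: int | None = None

    def replicate_frame(self) -> pd.DataFrame:
        """Tidy table: one row per replicate."""
        rows = []
        for (u3, k00), reps in zip(self.conditions, self.per_condition):
            for r in reps:
                rows.append({
                    "U3": u3, "kappa00": k00, "seed": r.seed,
                    "max_projection_length": r.max_projection_length,
                    "stability": r.stability,
                    "final_protrusion_count": r.final_protrusion_count,
                    "failed": r.failed,
                })
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return summarize(self)

    def mean_max_projection(self, u3: float, kappa00: float) -> float:
        ci = self.conditions.index((u3, kappa00))
        ok = [r.max_projection_length for r in self.per_condition[ci] if not r.failed]
        return float(np.mean(ok))

    def mean_stability(self, u3: float, kappa00: float) -> float:
        ci = self.conditions.index((u3, kappa00))
        ok = [r.stability for r in self.per_condition[ci] if not r.failed]
        return float(np.mean(ok))


def replicate_seed(seed0: int, condition_index: int, replicate_index: int) -> int:
    return seed0 + condition_index * 10_000 + replicate_index


def prepare_condition(base: SimulationParameters, u3: float,
                      kappa00: float, seed: int) -> SimulationParameters:
    """Parameters for one condition with a stability-limited timestep.

    The total simulated time, the number of recorded frames, and the
    filament elongation speed of ``base`` are preserved; only the
    discretization changes with the condition's stiffness.
    """
    cond = base.replace(U3=u3, kappa00=kappa00, seed=seed)
    dt = suggest_timestep(cond)
    if dt >= base.dt:
        return cond
    n_frames = max(1, base.n_steps // base.record_every)
    n_steps = math.ceil(base.total_time / dt)
    record_every = max(1, round(n_steps / n_frames))
    n_steps = record_every * n_frames
    growth_rate = min(1.0, base.growth_rate * dt / base.dt)
    return cond.replace(dt=dt, n_steps=n_steps, record_every=record_every,
                        growth_rate=growth_rate)


def _run_replicate(params: SimulationParameters, threshold, window) -> ReplicateRecord:
    try:
        traj = run_simulation(params)
    except NumericalInstabilityError as exc:
        logger.warning("replicate seed=%d failed: %s", params.seed, exc)
        return ReplicateRecord(seed=params.seed, max_projection_length=np.nan,
                               stability=np.nan, final_protrusion_count=-1,
                               failed=True, error=str(exc))
    res = analyze(traj, threshold=threshold, window=window)
    return ReplicateRecord(
        seed=params.seed,
        max_projection_length=res.max_projection_length,
        stability=res.stability,
        final_protrusion_count=res.per_frame[-1][2],
    )


def _sweep(base, conditions, n_replicates, seed0, threshold, window,
           n_jobs: int = 1) -> SweepResult:
    jobs = [
        prepare_condition(base, u3, k00, replicate_seed(seed0, ci, ri))
        for ci, (u3, k00) in enumerate(conditions)
        for ri in range(n_replicates)
    ]
    if n_jobs > 1:
        # replicates share no state (independent seeds), so process-level
        # parallelism is exact: results equal the serial ones
        from concurrent.futures import ProcessPoolExecutor
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            flat = list(pool.map(_run_replicate, jobs,
                                 [threshold] * len(jobs), [window] * len(jobs)))
    else:
        flat = [_run_replicate(p, threshold, window) for p in jobs]

    per_condition: list[list[ReplicateRecord]] = []
    for ci, (u3, k00) in enumerate(conditions):
        reps = flat[ci * n_replicates:(ci + 1) * n_replicates]
        if all(r.failed for r in reps):
            raise RuntimeError(
                f"all {n_replicates} replicates failed at U3={u3}, kappa00={k00}")
        n_failed = sum(r.failed for r in reps)
        if n_failed:
            logger.warning("condition U3=%g kappa00=%g: %d/%d replicates failed",
                           u3, k00, n_failed, n_replicates)
        per_condition.append(reps)
    return SweepResult(conditions=list(conditions), per_condition=per_condition,
                       base=base, n_replicates=n_replicates, seed0=seed0,
                       threshold=threshold, window=window)


def sweep_u3(base: SimulationParameters, u3_values, kappa00_fixed: float,
             n_replicates: int, seed0: int,
             threshold: float | None = None,
             window: int | None = None,
             n_jobs: int = 1) -> SweepResult:
    """Sweep the adhesion depth U3 at fixed membrane stiffness."""
    u3_values = list(u3_values)
    if not u3_values:
        raise ValueError("u3_values must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    conditions = [(float(u3), float(kappa00_fixed)) for u3 in u3_values]
    return _sweep(base, conditions, n_replicates, seed0, threshold, window, n_jobs)


def phase_diagram(base: SimulationParameters, u3_grid, kappa00_grid,
                  n_replicates: int, seed0: int,
                  threshold: float | None = None,
                  window: int | None = None,
                  n_jobs: int = 1) -> SweepResult:
    """Full factorial (U3, kappa00) sweep (kappa00-major condition order)."""
    u3_grid = list(u3_grid)
    kappa00_grid = list(kappa00_grid)
    if not u3_grid or not kappa00_grid:
        raise ValueError("both grids must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    conditions = [(float(u3), float(k00)) for k00 in kappa00_grid for u3 in u3_grid]
    return _sweep(base, conditions, n_replicates, seed0, threshold, window, n_jobs)


def summarize(result: SweepResult) -> pd.DataFrame:
    """Per-condition mean, SD, SEM (= SD/sqrt(n)) and n of the maximal
    projection length, plus mean stability; failed replicates excluded."""
    rows = []
    for (u3, k00), reps in zip(result.conditions, result.per_condition):
        ok = [r for r in reps if not r.failed]
        if not ok:
            raise RuntimeError(f"no successful replicates at U3={u3}, kappa00={k00}")
        proj = np.array([r.max_projection_length for r in ok])
        stab = np.array([r.stability for r in ok])
        sd = float(proj.std(ddof=1)) if len(ok) > 1 else 0.0
        rows.append({
            "U3": u3, "kappa00": k00, "n": len(ok),
            "mean_max_projection": float(proj.mean()),
            "sd_max_projection": sd,
            "sem_max_projection": sd / math.sqrt(len(ok)),
            "mean_stability": float(stab.mean()),
            "n_failed": len(reps) - len(ok),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# calibrated presets for the two canonical experiments
# ---------------------------------------------------------------------

def protrusion_preset(scale: str = "default") -> SimulationParameters:
    """Base parameters calibrated for the protrusion experiments.

    ``"default"`` is the full 700-bead cell simulated for 40 time units;
    ``"reduced"`` is a geometrically similar 192-bead cell (96 membrane +
    48 nuclear + 8 filaments x 6) for 30 time units — same stiffnesses,
    same elongation speed, growth cap scaled to the shorter filaments.
    The reduced cell reproduces the same qualitative phenomenology at
    roughly a tenth of the cost and is what the acceptance checks run.
    """
    if scale == "default":
        return SimulationParameters(n_steps=270_000, record_every=13_500)
    if scale == "reduced":
        return SimulationParameters(
            n_total=192, n_membrane=96, n_nuclear=48, n_filaments=8,
            beads_per_filament=6, max_filament_length=16.0,
            n_steps=200_000, record_every=10_000)
    raise ValueError(f"unknown scale: {scale!r}")


def low_vs_high_adhesion_experiment(seed0: int, n_replicates: int = 10,
                                    scale: str = "default") -> SweepResult:
    """Low vs high cortical tension (U3 = 3.0 vs 30.0) at kappa00 = 500."""
    base = protrusion_preset(scale)
    return sweep_u3(base, [U3_LOW, U3_HIGH], KAPPA00_STIFF, n_replicates, seed0,
                    threshold=PROTRUSION_THRESHOLD)


def adhesion_sweep_experiment(seed0: int, n_replicates: int = 10,
                              scale: str = "default") -> SweepResult:
    """Five-point U3 sweep at kappa00 = 10 (non-monotonic projection length)."""
    base = protrusion_preset(scale)
    return sweep_u3(base, list(U3_GRID), KAPPA00_SOFT, n_replicates, seed0,
                    threshold=PROTRUSION_THRESHOLD)
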