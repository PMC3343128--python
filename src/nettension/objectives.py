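"""Task objective functions for the three E2F dynamics.

Each network "task" is a quantitative criterion on a simulated
protocol:

* **hysteresis** — the up- and down-going serum dose responses of E2F
  mRNA separate; scored as the area between the branches over
  log10(serum) (the path difference Delta-P, uM x log10-units).
* **temporal adaptation** — after a serum step E2F protein peaks and
  returns toward baseline; scored as the peak-relative return ratio
  Delta-F / Delta-I over 25 h.
* **biphasic response** — E2F mRNA rises then falls along a MYC dose
  axis; scored as the dose-axis analogue of the adaptation ratio.

A minimal rise Delta-I is enforced for the ratio-based tasks to filter
out trivial flat responses.  For search guidance the ratio is softly
scaled by min(1, Delta-I / Delta-I_min); the *solution* criterion always
applies the hard gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import (ACTIVATED_SERUM, ContractError, DoseResponse, InputSignal,
                    ModelSpec, QUIESCENT_SERUM, SimulationError, Trajectory,
                    default_myc_grid, default_serum_grid, myc_sweep,
                    quiescent_state, serum_bidirectional_sweep, simulate)

__all__ = [
    "TaskSpec", "ObjectiveResult",
    "hysteresis_score", "adaptation_score", "biphasic_score",
    "dual_score", "evaluate_task", "default_task_spec", "TASKS",
]

TASKS = ("hysteresis", "adaptation", "biphasic")

#: Solution thresholds: path difference for hysteresis (uM x log10-serum
#: units), return ratio for adaptation and biphasic.
DEFAULT_THRESHOLDS = {"hysteresis": 0.5, "adaptation": 0.80, "biphasic": 0.80}
DEFAULT_DELTA_I_MIN = 0.2   # uM; minimal rise for the ratio-based tasks


@dataclass(frozen=True)
class TaskSpec:
    """Protocol and scoring settings for one task."""

    task: str
    threshold: float
    delta_i_min: float = DEFAULT_DELTA_I_MIN
    n_doses: int = 21
    adaptation_horizon: float = 25.0
    sweep_horizon: float = 24.0
    biphasic_horizon: float = 36.0

    def __post_init__(self):
        if self.task not in TASKS:
            raise ContractError(f"unknown task {self.task!r}")
        if self.threshold <= 0 or self.delta_i_min < 0:
            raise ContractError("threshold must be > 0 and gate >= 0")


def default_task_spec(task: str, **overrides) -> TaskSpec:
    return TaskSpec(task=task, threshold=DEFAULT_THRESHOLDS[task], **overrides)


@dataclass(frozen=True)
class ObjectiveResult:
    """A task score with its components and the solution verdict."""

    task: str
    score: float
    components: Mapping[str, float]
    is_solution: bool
    threshold: float

    def __post_init__(self):
        if self.score < 0:
            raise ContractError("scores are nonnegative by construction")


def hysteresis_score(up: DoseResponse, down: DoseResponse,
                     spec: TaskSpec | None = None) -> ObjectiveResult:
    """Path difference between down- and up-going serum branches.

    Delta-P is the trapezoidal integral of max(down - up, 0) over
    log10(dose), which makes the score independent of grid resolution;
    the positive-part guard absorbs numerically crossing branches.
    """
    spec = spec or default_task_spec("hysteresis")
    if len(up.doses) != len(down.doses) or not np.allclose(up.doses, down.doses):
        raise ContractError("up and down branches must share one dose grid")
    gap = np.clip(down.values - up.values, 0.0, None)
    if len(up.doses) < 2:
        delta_p = 0.0
    else:
        delta_p = float(np.trapezoid(gap, np.log10(up.doses)))
    return ObjectiveResult(
        task="hysteresis", score=delta_p, components={"delta_P": delta_p},
        is_solution=bool(delta_p >= spec.threshold), threshold=spec.threshold)


def _peak_return_score(values: np.ndarray, spec: TaskSpec, task: str) -> ObjectiveResult:
    """Shared Delta-F/Delta-I scoring for adaptation and biphasic tasks.

    Besides the minimal-rise gate Delta-I >= Delta-I_min, a solution
    must rise from a silenced baseline: Delta-I >= v[0].  Without the
    baseline condition, parameter sets whose readout starts high (E2F
    already ON before the stimulus) and slowly drifts down would count
    as adaptive even though nothing is induced — the biology of both
    tasks is an E2F response ignited from the RB-repressed OFF state.
    The search score applies both gates softly to avoid flat landscapes.
    """
    v = np.asarray(values, dtype=float)
    baseline = float(v[0])
    peak = float(np.max(v))
    delta_i = peak - baseline
    delta_f = peak - float(v[-1])
    if delta_i <= 0:
        ratio = 0.0
    else:
        ratio = max(delta_f, 0.0) / delta_i
    score = ratio
    if spec.delta_i_min > 0:
        score *= min(1.0, delta_i / spec.delta_i_min)
    if delta_i > 0 and baseline > delta_i:
        score *= 2.0 * delta_i / (delta_i + baseline)
    is_solution = (delta_i >= spec.delta_i_min) and (ratio >= spec.threshold) \
        and (delta_i >= baseline)
    return ObjectiveResult(
        task=task, score=float(score),
        components={"delta_I": max(delta_i, 0.0), "delta_F": max(delta_f, 0.0),
                    "ratio": float(ratio), "baseline": baseline},
        is_solution=bool(is_solution), threshold=spec.threshold)


def adaptation_score(traj: Trajectory, spec: TaskSpec | None = None) -> ObjectiveResult:
    """Peak-relative return of E2F protein within 25 h of a serum step."""
    spec = spec or default_task_spec("adaptation")
    if traj.t[-1] < spec.adaptation_horizon - 1e-9:
        raise ContractError(
            f"trajectory must cover {spec.adaptation_horizon} h after the step")
    mask = traj.t <= spec.adaptation_horizon + 1e-9
    return _peak_return_score(traj.e2f_protein[mask], spec, "adaptation")


def biphasic_score(curve: DoseResponse, spec: TaskSpec | None = None) -> ObjectiveResult:
    """Peak-relative suppression of E2F mRNA along the MYC dose axis."""
    spec = spec or default_task_spec("biphasic")
    return _peak_return_score(curve.values, spec, "biphasic")


def dual_score(results: Sequence[ObjectiveResult], mode: str = "product") -> ObjectiveResult:
    """Composite objective over several tasks.

    Per-task scores are normalised by their thresholds and combined by
    product or sum; the combination only guides the search.  The
    solution criterion is always conjunctive: every task must be a
    solution on its own.
    """
    if not results:
        raise ContractError("dual_score needs at least one task result")
    if mode not in ("product", "sum"):
        raise ContractError(f"unknown combination mode {mode!r}")
    normalised = [r.score / r.threshold for r in results]
    combined = float(np.prod(normalised) if mode == "product" else np.sum(normalised))
    return ObjectiveResult(
        task="+".join(r.task for r in results), score=combined,
        components={f"s_{r.task}": s for r, s in zip(results, normalised)},
        is_solution=all(r.is_solution for r in results),
        threshold=1.0 if mode == "product" else float(len(results)))


def _failed(task, spec):
    return ObjectiveResult(task=task, score=0.0, components={},
                           is_solution=False, threshold=spec.threshold)


def evaluate_task(model: ModelSpec, params: Mapping[str, float],
                  spec: TaskSpec) -> ObjectiveResult:
    """Runs the task's protocol and scores it; solver failure scores 0."""
    try:
        if spec.task == "hysteresis":
            up, down = serum_bidirectional_sweep(
                model, params, grid=default_serum_grid(spec.n_doses),
                horizon=spec.sweep_horizon)
            return hysteresis_score(up, down, spec)
        if spec.task == "adaptation":
            q = quiescent_state(model, params)
            traj = simulate(
                model, params, InputSignal(S=ACTIVATED_SERUM), q,
                duration=spec.adaptation_horizon,
                report_times=np.linspace(0.0, spec.adaptation_horizon, 101))
            return adaptation_score(traj, spec)
        # biphasic
        curve = myc_sweep(model, params,
                          grid=default_myc_grid(model, spec.n_doses),
                          horizon=spec.biphasic_horizon)
        return biphasic_score(curve, spec)
    except SimulationError:
        return _failed(spec.task, spec)


def evaluate_tasks(model: ModelSpec, params: Mapping[str, float],
                   specs: Sequence[TaskSpec], mode: str = "product") -> ObjectiveResult:
    """Evaluates several tasks and combines them with :func:`dual_score`."""
    results = [evaluate_task(model, params, s) for s in specs]
    if len(results) == 1:
        return results[0]
    return dual_score(results, mode=mode)
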