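"""Adaptive-walk search of the viable parameter space.

Each iteration starts from a log-uniform random parameter set and
performs a greedy stochastic walk: one parameter is mutated by a random
factor of up to 10x, the move is kept only if the objective score
strictly improves, and the iteration ends the first time the solution
criterion is met or after a fixed number of consecutive
non-improvements (the stall limit, 100 by default).  Iterations are
independent and individually seeded from the master seed, so serial and
parallel runs produce identical archives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ContractError, ModelSpec
from .objectives import ObjectiveResult, TaskSpec, evaluate_tasks

__all__ = [
    "SearchConfig", "IterationRecord", "SolutionArchive",
    "sample_parameters", "mutate", "run_iteration", "run_search",
]


@dataclass(frozen=True)
class SearchConfig:
    """Settings of the adaptive walk."""

    n_iterations: int = 100
    stall_limit: int = 100
    log10_step: float = 1.0          # |log10 fold-change| bound per mutation
    mode: str = "product"            # dual-objective combination
    seed: int = 0
    n_workers: int = 1
    max_mutations: int = 1500        # safety cap on moves per iteration

    def __post_init__(self):
        if self.stall_limit < 1:
            raise ContractError("stall_limit must be >= 1")
        if self.n_iterations < 0:
            raise ContractError("n_iterations must be >= 0")
        if self.mode not in ("product", "sum"):
            raise ContractError(f"unknown objective mode {self.mode!r}")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    seed: int
    outcome: str                    # solution | stalled | failed
    params: Mapping[str, float]
    result: ObjectiveResult
    n_tried: int
    n_accepted: int


@dataclass
class SolutionArchive:
    """Parameter sets that satisfied a task, with provenance."""

    task: str
    variant: str
    param_names: tuple
    records: list = field(default_factory=list)
    n_iterations: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    @property
    def solution_rate(self) -> float:
        return len(self.records) / self.n_iterations if self.n_iterations else 0.0

    def params_df(self) -> pd.DataFrame:
        """One row per solution, one column per parameter."""
        return pd.DataFrame(
            [[r.params[n] for n in self.param_names] for r in self.records],
            columns=list(self.param_names))

    def param_sets(self) -> list:
        return [dict(r.params) for r in self.records]

    def medians(self) -> dict:
        """Per-parameter median across solutions."""
        if not self.records:
            raise ContractError("empty archive has no medians")
        df = self.params_df()
        return {n: float(df[n].median()) for n in self.param_names}


def sample_parameters(ranges: Mapping[str, tuple], rng: np.random.Generator,
                      base: Mapping[str, float] | None = None,
                      free: Sequence[str] | None = None) -> dict:
    """Draws each free parameter log-uniformly over its range.

    Frozen parameters (those not in ``free``) keep their ``base`` value.
    """
    names = list(ranges)
    free = set(names if free is None else free)
    out = dict(base or {})
    for name in names:
        if name in free:
            lo, hi = ranges[name]
            out[name] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        elif name not in out:
            raise ContractError(f"frozen parameter {name!r} needs a base value")
    return out


def mutate(params: Mapping[str, float], ranges: Mapping[str, tuple],
           rng: np.random.Generator, log10_step: float = 1.0,
           free: Sequence[str] | None = None) -> dict:
    """One multiplicative mutation: a single uniformly chosen parameter
    is scaled by 10**u with u ~ Uniform(-step, step), then clamped into
    its search range."""
    free = list(ranges if free is None else free)
    name = free[rng.integers(len(free))]
    u = rng.uniform(-log10_step, log10_step)
    lo, hi = ranges[name]
    out = dict(params)
    out[name] = float(min(max(out[name] * 10 ** u, lo), hi))
    return out


def _iteration_seed(master_seed: int, iteration: int) -> int:
    ss = np.random.SeedSequence((int(master_seed), int(iteration)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def run_iteration(model: ModelSpec, tasks: Sequence[TaskSpec] | TaskSpec,
                  config: SearchConfig, seed: int,
                  scorer: Callable[[Mapping], ObjectiveResult] | None = None,
                  start: Mapping[str, float] | None = None) -> IterationRecord:
    """One greedy adaptive walk from a random (or given) starting point.

    ``scorer`` defaults to evaluating the given task(s) on the model;
    an injected scorer lets reduced models and toy landscapes reuse the
    walk.  The sequence of accepted scores is strictly increasing.
    """
    if isinstance(tasks, TaskSpec):
        tasks = [tasks]
    if scorer is None:
        scorer = lambda p: evaluate_tasks(model, p, tasks, mode=config.mode)
    rng = np.random.default_rng(seed)
    ranges = {n: model.ranges[n] for n in model.param_names}
    free = model.free_parameters
    if start is None:
        base = None
        if model.frozen:
            from .data import reference_params
            nominal = reference_params("reference_bistable")
            base = {n: nominal.get(n, nominal.get(n[:-2])) for n in model.frozen}
        params = sample_parameters(ranges, rng, base=base, free=free)
    else:
        params = dict(start)
    current = scorer(params)
    n_tried = n_accepted = 0
    stall = 0
    while not current.is_solution and n_tried < config.max_mutations:
        candidate = mutate(params, ranges, rng, config.log10_step, free=free)
        trial = scorer(candidate)
        n_tried += 1
        if trial.score > current.score:
            params, current = candidate, trial
            n_accepted += 1
            stall = 0
        else:
            stall += 1
            if stall >= config.stall_limit:
                break
    outcome = "solution" if current.is_solution else "stalled"
    return IterationRecord(iteration=-1, seed=seed, outcome=outcome,
                           params=params, result=current,
                           n_tried=n_tried, n_accepted=n_accepted)


def _task_tag(tasks) -> str:
    if isinstance(tasks, TaskSpec):
        return tasks.task
    return "+".join(t.task for t in tasks)


def run_search(model: ModelSpec, tasks: Sequence[TaskSpec] | TaskSpec,
               config: SearchConfig,
               scorer: Callable[[Mapping], ObjectiveResult] | None = None,
               warm_start: SolutionArchive | None = None,
               progress: Callable[[int, IterationRecord], None] | None = None,
               ) -> SolutionArchive:
    """Runs ``config.n_iterations`` independent adaptive walks.

    With ``warm_start`` the random initialisation is replaced by draws
    from an existing (typically single-task) archive, mimicking the
    successive elaboration of network tasks.  Results are independent
    of worker scheduling because every iteration derives its own seed
    from (master seed, iteration index).
    """
    archive = SolutionArchive(
        task=_task_tag(tasks), variant=model.variant,
        param_names=tuple(model.param_names), n_iterations=config.n_iterations,
        meta={"seed": config.seed, "stall_limit": config.stall_limit,
              "mode": config.mode,
              "warm_start": warm_start.task if warm_start is not None else None})

    def one(i: int) -> IterationRecord:
        seed_i = _iteration_seed(config.seed, i)
        start = None
        if warm_start is not None:
            if not warm_start.records:
                raise ContractError("warm-start archive is empty")
            pick = np.random.default_rng(seed_i).integers(len(warm_start.records))
            start = dict(warm_start.records[pick].params)
        rec = run_iteration(model, tasks, config, seed_i, scorer=scorer,
                            start=start)
        return IterationRecord(iteration=i, seed=rec.seed, outcome=rec.outcome,
                               params=rec.params, result=rec.result,
                               n_tried=rec.n_tried, n_accepted=rec.n_accepted)

    if config.n_workers > 1 and config.n_iterations > 1:
        from joblib import Parallel, delayed
        # per-iteration seeding makes scheduling irrelevant to results
        records = Parallel(n_jobs=config.n_workers, prefer="threads")(
            delayed(one)(i) for i in range(config.n_iterations))
    else:
        records = []
        for i in range(config.n_iterations):
            rec = one(i)
            records.append(rec)
            if progress is not None:
                progress(i, rec)
    archive.records = [r for r in records if r.outcome == "solution"]
    archive.meta["n_stalled"] = sum(r.outcome != "solution" for r in records)
    return archive
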