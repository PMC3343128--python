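"""Comparative metrics over solution archives.

Given archives of parameter sets solving different tasks, this module
quantifies how far apart the tasks' viable parameter spaces are
(*tension*, via median log-ratios or Kullback-Leibler divergence), how
easy it is to find parameter sets serving both tasks at once
(*accessibility*), how strongly each regulatory module is configured
(*module strength*), and how well a solution tolerates random parameter
perturbation (*resilience*).  A pairwise *adjacency* report collects
the metrics for every task pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ContractError, ModelSpec, ModuleMap
from .objectives import ObjectiveResult, TaskSpec, evaluate_tasks
from .search import SolutionArchive

__all__ = [
    "TensionReport", "ResilienceReport",
    "tension_median", "tension_kl",
    "accessibility", "accessibility_from_counts",
    "module_strength", "select_representatives", "substitute_module",
    "perturb_and_score", "notch_interval", "notches_overlap", "adjacency",
]


@dataclass(frozen=True)
class TensionReport:
    """Tension between two tasks' solution distributions.

    ``value`` is the weighted mean per-parameter contribution: absolute
    log10 median ratios (``median_logratio``, units: decades) or
    symmetrised KL divergences (``kl``, nats).
    """

    tasks: tuple
    value: float
    contributions: Mapping[str, float]
    weights: Mapping[str, float]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": list(self.contributions),
            "contribution": list(self.contributions.values()),
            "weight": [self.weights[n] for n in self.contributions],
        })


@dataclass(frozen=True)
class ResilienceReport:
    """Outcome of repeated random perturbation of one solution."""

    task: str
    original_score: float
    fraction: float                 # resilient fraction in [0, 1]
    records: pd.DataFrame           # columns: K, score, resilient
    retention: float
    sigma: float

    @property
    def n_perturbations(self) -> int:
        return len(self.records)


def _check_pair(a: SolutionArchive, b: SolutionArchive):
    if len(a) == 0 or len(b) == 0:
        raise ContractError("tension needs non-empty archives on both sides")
    if tuple(a.param_names) != tuple(b.param_names):
        raise ContractError("archives must share one free-parameter list")


def tension_median(a: SolutionArchive, b: SolutionArchive,
                   weights: Mapping[str, float] | None = None) -> TensionReport:
    """Weighted mean absolute log10-ratio of per-parameter medians.

    With equal weights 1/n this is the average number of decades each
    parameter's median shifts between the two tasks.
    """
    _check_pair(a, b)
    names = a.param_names
    if weights is None:
        weights = {n: 1.0 / len(names) for n in names}
    else:
        total = sum(weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ContractError("weights must sum to 1")
    med_a, med_b = a.medians(), b.medians()
    contrib = {n: abs(math.log10(med_a[n] / med_b[n])) for n in names}
    value = sum(weights[n] * contrib[n] for n in names)
    return TensionReport(tasks=(a.task, b.task), value=value,
                         contributions=contrib, weights=dict(weights),
                         method="median_logratio")


def _sym_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Symmetrised KL divergence (nats) between two discrete densities."""
    mask = (p > 0) | (q > 0)
    p, q = p[mask], q[mask]
    return float(0.5 * (np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))))


def tension_kl(a: SolutionArchive, b: SolutionArchive,
               ranges: Mapping[str, tuple] | None = None,
               bins: int = 20) -> TensionReport:
    """Mean symmetrised KL divergence between per-parameter histograms.

    Each parameter's log10 values are histogrammed on ``bins`` equal
    bins spanning its search range (or the pooled data range when no
    ranges are given), with an add-one pseudocount so empty bins stay
    finite.
    """
    _check_pair(a, b)
    names = a.param_names
    df_a, df_b = a.params_df(), b.params_df()
    contrib = {}
    for n in names:
        la, lb = np.log10(df_a[n].to_numpy()), np.log10(df_b[n].to_numpy())
        if ranges is not None and n in ranges:
            lo, hi = np.log10(ranges[n][0]), np.log10(ranges[n][1])
        else:
            lo, hi = min(la.min(), lb.min()), max(la.max(), lb.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, bins + 1)
        ha = np.histogram(np.clip(la, lo, hi), bins=edges)[0] + 1.0
        hb = np.histogram(np.clip(lb, lo, hi), bins=edges)[0] + 1.0
        contrib[n] = _sym_kl(ha / ha.sum(), hb / hb.sum())
    weights = {n: 1.0 / len(names) for n in names}
    value = sum(weights[n] * contrib[n] for n in names)
    return TensionReport(tasks=(a.task, b.task), value=value,
                         contributions=contrib, weights=weights, method="kl")


def accessibility_from_counts(n_a: int, n_b: int,
                              dual_in_a: int, dual_in_b: int) -> float:
    """Fraction of single-task solutions that are dual, pooled over both
    tasks: (dual_in_a + dual_in_b) / (n_a + n_b)."""
    if n_a + n_b == 0:
        raise ContractError("accessibility needs at least one solution")
    if dual_in_a > n_a or dual_in_b > n_b:
        raise ContractError("dual counts cannot exceed archive sizes")
    return (dual_in_a + dual_in_b) / (n_a + n_b)


def accessibility(a: SolutionArchive, b: SolutionArchive, model: ModelSpec,
                  task_a: TaskSpec, task_b: TaskSpec) -> tuple[float, dict]:
    """Cross-evaluates each archive on the other task.

    Every solution of task A is re-scored on task B and vice versa;
    the accessibility is the pooled fraction of single-task solutions
    that pass both criteria.
    """
    if len(a) == 0 and len(b) == 0:
        raise ContractError("accessibility needs at least one solution")
    dual_in_a = sum(
        evaluate_tasks(model, r.params, [task_b]).is_solution for r in a.records)
    dual_in_b = sum(
        evaluate_tasks(model, r.params, [task_a]).is_solution for r in b.records)
    frac = accessibility_from_counts(len(a), len(b), dual_in_a, dual_in_b)
    counts = {"n_a": len(a), "n_b": len(b),
              "dual_in_a": dual_in_a, "dual_in_b": dual_in_b}
    return frac, counts


def module_strength(params: Mapping[str, float], module_map: ModuleMap) -> dict:
    """log10 of the product of each module's parameters, degradation
    constants entering as reciprocals."""
    out = {}
    for mod, members in module_map.modules.items():
        log_strength = 0.0
        for name, orientation in members:
            v = math.log10(params[name])
            log_strength += v if orientation == "proportional" else -v
        out[mod] = log_strength
    return out


def select_representatives(archive: SolutionArchive, module_pair: tuple,
                           module_map: ModuleMap, k: int = 50) -> SolutionArchive:
    """The ``k`` solutions nearest the archive's median module state.

    Solutions are placed by their (log10) strengths of the two modules,
    each axis scaled by its interquartile range, and ranked by Chebyshev
    distance from the coordinate-wise median — i.e. the smallest
    IQR-scaled box centred on the median that contains ``k`` points.
    Ties break on the solution's position in the archive.
    """
    if len(archive) < k:
        raise ContractError(f"archive has {len(archive)} < k={k} solutions")
    coords = np.array([
        [module_strength(r.params, module_map)[m] for m in module_pair]
        for r in archive.records])
    center = np.median(coords, axis=0)
    q75, q25 = np.percentile(coords, [75, 25], axis=0)
    scale = np.where(q75 - q25 > 0, q75 - q25, 1.0)
    dist = np.max(np.abs(coords - center) / scale, axis=1)
    order = np.lexsort((np.arange(len(dist)), dist))[:k]
    sub = SolutionArchive(task=archive.task, variant=archive.variant,
                          param_names=archive.param_names,
                          n_iterations=archive.n_iterations,
                          meta=dict(archive.meta, representatives_of=len(archive)))
    sub.records = [archive.records[i] for i in sorted(order)]
    return sub


def substitute_module(params: Mapping[str, float], donor: SolutionArchive,
                      module: str, module_map: ModuleMap) -> dict:
    """Replaces every parameter of ``module`` by the donor archive's
    per-parameter median; all other parameters are untouched."""
    if len(donor) == 0:
        raise ContractError("donor archive is empty")
    members = module_map.members(module)
    medians = donor.medians()
    out = dict(params)
    for name, _ in members:
        out[name] = medians[name]
    return out


def perturb_and_score(model: ModelSpec, params: Mapping[str, float],
                      tasks: Sequence[TaskSpec] | TaskSpec,
                      n: int = 10_000, sigma: float = 0.2,
                      retention: float = 0.10,
                      rng: np.random.Generator | int | None = None,
                      scorer=None, mode: str = "product") -> ResilienceReport:
    """Resilience of one solution to joint random parameter perturbation.

    Each of ``n`` perturbations draws an independent log10 shift
    eps_i ~ Normal(0, sigma) for every free parameter, applies them all
    at once (clamped into the search ranges), and re-scores the task.
    A perturbation is *resilient* if the perturbed score retains at
    least ``retention`` of the original score; K records the total
    parameter variation sum_i |log10 fold-change_i| actually applied.
    """
    if isinstance(tasks, TaskSpec):
        tasks = [tasks]
    if scorer is None:
        scorer = lambda p: evaluate_tasks(model, p, tasks, mode=mode)
    rng = np.random.default_rng(rng)
    base = model.validate_params(params)
    original = scorer(base)
    if original.score <= 0:
        raise ContractError("resilience needs a positive original score")
    free = model.free_parameters
    rows = []
    for _ in range(n):
        eps = rng.normal(0.0, sigma, size=len(free))
        perturbed = dict(base)
        K = 0.0
        for name, e in zip(free, eps):
            lo, hi = model.ranges[name]
            newv = min(max(base[name] * 10 ** e, lo), hi)
            K += abs(math.log10(newv / base[name]))
            perturbed[name] = newv
        score = scorer(perturbed).score
        rows.append((K, score, score >= retention * original.score))
    records = pd.DataFrame(rows, columns=["K", "score", "resilient"])
    return ResilienceReport(
        task="+".join(t.task for t in tasks), original_score=original.score,
        fraction=float(records["resilient"].mean()), records=records,
        retention=retention, sigma=sigma)


def notch_interval(values: Sequence[float]) -> tuple[float, float, float]:
    """Notched-boxplot comparison interval median +/- 1.57 IQR / sqrt(n).

    Two medians differ at roughly the 5% level when their notch
    intervals do not overlap.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ContractError("notch interval needs at least 2 values")
    med = float(np.median(v))
    q75, q25 = np.percentile(v, [75, 25])
    half = 1.57 * (q75 - q25) / math.sqrt(v.size)
    return (med - half, med, med + half)


def notches_overlap(values_a: Sequence[float], values_b: Sequence[float]) -> bool:
    lo_a, _, hi_a = notch_interval(values_a)
    lo_b, _, hi_b = notch_interval(values_b)
    return not (hi_a < lo_b or hi_b < lo_a)


def adjacency(task_pairs: Sequence[tuple], archives: Mapping[str, SolutionArchive],
              model: ModelSpec, task_specs: Mapping[str, TaskSpec] | None = None,
              resilience: Mapping[tuple, float] | None = None,
              kl_bins: int = 20) -> pd.DataFrame:
    """Pairwise tension/accessibility summary table.

    One row per task pair with both tension estimates; accessibility is
    computed by cross-evaluation when task specs are supplied.  The
    diagonal convention is tension 0 and accessibility 1.  Optional
    pre-computed median resilience values may be attached per pair.
    """
    from .objectives import default_task_spec
    rows = []
    for pair in task_pairs:
        ta, tb = pair
        if ta == tb:
            if ta not in archives:
                raise ContractError(f"missing archive for task {ta!r}")
            rows.append({"task_a": ta, "task_b": tb, "tension_median": 0.0,
                         "tension_kl": 0.0, "accessibility": 1.0,
                         "median_resilience": np.nan})
            continue
        missing = [t for t in (ta, tb) if t not in archives]
        if missing:
            raise ContractError(f"missing archives for {missing}")
        a, b = archives[ta], archives[tb]
        t_med = tension_median(a, b).value
        t_kl = tension_kl(a, b, ranges=model.ranges, bins=kl_bins).value
        spec_a = (task_specs or {}).get(ta) or default_task_spec(ta)
        spec_b = (task_specs or {}).get(tb) or default_task_spec(tb)
        acc, _ = accessibility(a, b, model, spec_a, spec_b)
        rows.append({
            "task_a": ta, "task_b": tb, "tension_median": t_med,
            "tension_kl": t_kl, "accessibility": acc,
            "median_resilience": (resilience or {}).get(tuple(pair), np.nan)})
    return pd.DataFrame(rows)
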