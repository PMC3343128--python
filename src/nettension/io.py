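"""Archive and configuration serialization, plus synthetic archives.

Solution archives are stored as plain CSV (one row per solution, one
column per parameter) with a JSON sidecar carrying the run provenance,
so they stay diffable and portable across languages.  Run
configurations round-trip through YAML with every defaulted field
written out explicitly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import ConfigurationError, ContractError, ModelSpec, build_model
from .objectives import DEFAULT_DELTA_I_MIN, DEFAULT_THRESHOLDS, TaskSpec
from .search import IterationRecord, SearchConfig, SolutionArchive
from .objectives import ObjectiveResult

__all__ = [
    "FormatError", "RunConfig", "load_config",
    "write_archive", "read_archive", "synth_archive",
]

_META_COLUMNS = ("iteration", "seed", "outcome", "score")


class FormatError(ValueError):
    """An archive or config file does not match the expected schema."""


def write_archive(archive: SolutionArchive, path: str | Path) -> Path:
    """Writes the archive CSV and its JSON sidecar; returns the CSV path."""
    path = Path(path)
    rows = []
    for r in archive.records:
        row = {"iteration": r.iteration, "seed": r.seed, "outcome": r.outcome,
               "score": r.result.score}
        row.update({n: r.params[n] for n in archive.param_names})
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_META_COLUMNS) + list(archive.param_names))
    df.to_csv(path, index=False)   # default float repr round-trips exactly
    sidecar = {
        "task": archive.task, "variant": archive.variant,
        "param_names": list(archive.param_names),
        "n_iterations": archive.n_iterations,
        "meta": _jsonable(archive.meta), "version": __version__,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_archive(path: str | Path, model: ModelSpec | None = None) -> SolutionArchive:
    """Reads an archive CSV (+ sidecar when present).

    When ``model`` is given, the archive's parameter columns must match
    the model's parameter list exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise FormatError(f"archive {path} lacks columns {missing_meta}")
    param_cols = [c for c in df.columns if c not in _META_COLUMNS]

    sidecar_path = path.with_suffix(".json")
    task, variant, n_iterations, meta = "unknown", "base", len(df), {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        task = sidecar.get("task", task)
        variant = sidecar.get("variant", variant)
        n_iterations = sidecar.get("n_iterations", n_iterations)
        meta = sidecar.get("meta", {})
        declared = sidecar.get("param_names")
        if declared and list(declared) != param_cols:
            raise FormatError(
                f"archive {path}: sidecar parameter list {declared} does not "
                f"match CSV columns {param_cols}")
    if model is not None:
        expected = list(model.param_names)
        if param_cols != expected:
            missing = [c for c in expected if c not in param_cols]
            extra = [c for c in param_cols if c not in expected]
            raise FormatError(
                f"archive {path} does not fit model {model.variant!r}: "
                f"missing columns {missing}, unexpected {extra}")

    archive = SolutionArchive(task=task, variant=variant,
                              param_names=tuple(param_cols),
                              n_iterations=int(n_iterations), meta=meta)
    for _, row in df.iterrows():
        params = {n: float(row[n]) for n in param_cols}
        result = ObjectiveResult(task=task, score=float(row["score"]),
                                 components={}, is_solution=True,
                                 threshold=1.0)
        archive.records.append(IterationRecord(
            iteration=int(row["iteration"]), seed=int(row["seed"]),
            outcome=str(row["outcome"]), params=params, result=result,
            n_tried=0, n_accepted=0))
    return archive


def synth_archive(spec: Mapping[str, tuple], n: int,
                  rng: np.random.Generator | int | None = None,
                  task: str = "synthetic") -> SolutionArchive:
    """Synthetic archive with prescribed per-parameter log-normals.

    ``spec`` maps parameter name -> (median, sigma_log10); each
    parameter is drawn independently as 10**Normal(log10 median,
    sigma_log10).  Used to exercise the metrics layer against known
    ground truth without running the search.
    """
    if n <= 0:
        raise ContractError("synthetic archive size must be positive")
    rng = np.random.default_rng(rng)
    names = tuple(spec)
    archive = SolutionArchive(task=task, variant="synthetic", param_names=names,
                              n_iterations=n,
                              meta={"generator": {k: list(map(float, v))
                                                 for k, v in spec.items()}})
    medians = np.array([spec[n_][0] for n_ in names])
    sigmas = np.array([spec[n_][1] for n_ in names])
    draws = 10 ** (np.log10(medians) + rng.normal(size=(n, len(names))) * sigmas)
    for i in range(n):
        params = dict(zip(names, map(float, draws[i])))
        result = ObjectiveResult(task=task, score=1.0, components={},
                                 is_solution=True, threshold=1.0)
        archive.records.append(IterationRecord(
            iteration=i, seed=0, outcome="solution", params=params,
            result=result, n_tried=0, n_accepted=0))
    return archive


@dataclass
class RunConfig:
    """Complete, serialisable description of a run."""

    variant: str = "base"
    tasks: Sequence[str] = ("hysteresis",)
    thresholds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    delta_i_min: float = DEFAULT_DELTA_I_MIN
    n_doses: int = 21
    ranges: Mapping[str, Sequence[float]] = field(default_factory=dict)
    frozen: Sequence[str] = ()
    rtol: float = 1e-6
    atol: float = 1e-9
    n_iterations: int = 100
    stall_limit: int = 100
    log10_step: float = 1.0
    mode: str = "product"
    seed: int = 0
    n_workers: int = 1
    kl_bins: int = 20
    perturb_sigma: float = 0.2
    retention: float = 0.10
    n_perturbations: int = 10_000
    out_dir: str = "."

    def model(self) -> ModelSpec:
        return build_model(self.variant, {
            "ranges": dict(self.ranges), "frozen": list(self.frozen),
            "rtol": self.rtol, "atol": self.atol})

    def task_specs(self) -> list:
        from .objectives import default_task_spec
        return [TaskSpec(task=t, threshold=self.thresholds[t],
                         delta_i_min=self.delta_i_min, n_doses=self.n_doses)
                for t in self.tasks]

    def search_config(self) -> SearchConfig:
        return SearchConfig(n_iterations=self.n_iterations,
                            stall_limit=self.stall_limit,
                            log10_step=self.log10_step, mode=self.mode,
                            seed=self.seed, n_workers=self.n_workers)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["tasks"] = list(self.tasks)
        payload["frozen"] = list(self.frozen)
        payload["ranges"] = {k: list(map(float, v)) for k, v in self.ranges.items()}
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


_VALIDATORS = {
    "variant": lambda v: v in ("base", "dup_e2f"),
    "tasks": lambda v: isinstance(v, (list, tuple)) and len(v) >= 1,
    "n_iterations": lambda v: isinstance(v, int) and v >= 0,
    "stall_limit": lambda v: isinstance(v, int) and v >= 1,
    "seed": lambda v: isinstance(v, int),
    "mode": lambda v: v in ("product", "sum"),
}


def load_config(path: str | Path) -> RunConfig:
    """Loads and validates a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise FormatError(f"config {path} must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise FormatError(f"config {path}: unknown keys {sorted(unknown)}")
    for key, check in _VALIDATORS.items():
        if key in payload and not check(payload[key]):
            raise FormatError(f"config {path}: invalid value for {key!r}")
    cfg = RunConfig(**payload)
    bad = [t for t in cfg.tasks if t not in DEFAULT_THRESHOLDS]
    if bad:
        raise FormatError(f"config {path}: unknown tasks {bad}")
    return cfg
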