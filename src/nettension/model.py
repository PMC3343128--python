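"""RB-E2F restriction-point switch model and its simulation protocols.

The network couples serum growth signals to E2F activity through four
regulatory modules: a *sensor* (serum -> MYC -> CycD/E2F expression and
RB phosphorylation), *positive feedback* (E2F autoactivation and
E2F -> CycE -> RB inactivation), *negative feedback* (E2F-induced
CycA/SKP2 activity that degrades E2F protein, lumped into one effector
A), and a MYC-triggered *repression* module (miR-17-92 / ARF, lumped
into one effector X that represses E2F transcription only when MYC is
high, via Hill-2 activation).

Two variants are provided: ``base`` (9 species, 31 free kinetic
parameters) and ``dup_e2f`` (11 species, 36 parameters), the latter
adding a duplicated E2F gene (E2F') with independent synthesis and
degradation but identical biochemical activity; regulatory readouts use
the summed E2F output.

Units: first-order rates 1/h, synthesis rates uM/h, Michaelis/Hill
constants uM, serum and its half-saturation constant in % serum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

from . import _kernels

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "ContractError",
    "InputSignal",
    "Trajectory",
    "DoseResponse",
    "ModuleMap",
    "ModelSpec",
    "build_model",
    "canonical_params",
    "params_to_vector",
    "vector_to_params",
    "simulate",
    "quiescent_state",
    "serum_bidirectional_sweep",
    "myc_sweep",
    "default_serum_grid",
    "default_myc_grid",
]


class ConfigurationError(ValueError):
    """Invalid model variant, parameter range or run configuration."""


class ContractError(ValueError):
    """An operation was called with arguments violating its contract."""


class SimulationError(RuntimeError):
    """The stiff solver failed; carries the offending parameters/input."""

    def __init__(self, message, params=None, signal=None):
        super().__init__(message)
        self.params = params
        self.signal = signal


BASE_SPECIES = ("M", "D", "m", "P", "Rb", "Rp", "E", "A", "X")
DUP_SPECIES = BASE_SPECIES + ("m_p", "P_p")

BASE_PARAMS = (
    "ke_MYC", "d_MYC", "k_CDm", "k_CDs", "d_CD",
    "k_E2Fm", "k_auto", "k_tl", "d_E2Fm", "d_E2Fp",
    "k_Adeg", "k_RB", "d_RB", "k_phD", "K_phD",
    "k_phE", "K_phE", "k_deph", "d_RP", "k_CE",
    "d_CE", "k_A", "d_A", "k_X", "K_XM",
    "d_X", "K_S", "K_M", "K_P", "K_RB", "K_X",
)
DUP_EXTRA_PARAMS = ("k_E2Fm_p", "k_auto_p", "k_tl_p", "d_E2Fm_p", "d_E2Fp_p")
DUP_PARAMS = BASE_PARAMS + DUP_EXTRA_PARAMS

# Alternate spellings found in the literature for the same constants.
_ALIASES = {"ke_MC": "ke_MYC", "ke_const": None}


def resolve_param_name(name: str) -> str:
    """Maps aliases and primed spellings onto canonical parameter names."""
    name = name.replace("′", "_p").replace("'", "_p")
    name = _ALIASES.get(name, name) or name
    return name


def canonical_params(params: Mapping[str, float], names: Sequence[str]) -> dict:
    """Validates and returns ``params`` keyed by canonical names.

    Raises :class:`ConfigurationError` if any value is not a positive
    finite real, or if the key set does not exactly match ``names``.
    """
    out = {}
    for key, value in params.items():
        canon = resolve_param_name(key)
        if canon in out:
            raise ConfigurationError(f"duplicate parameter {key!r}")
        out[canon] = float(value)
    missing = [n for n in names if n not in out]
    extra = [n for n in out if n not in names]
    if missing or extra:
        raise ConfigurationError(
            f"parameter set mismatch: missing {missing}, unexpected {extra}")
    bad = [n for n, v in out.items() if not (np.isfinite(v) and v > 0)]
    if bad:
        raise ConfigurationError(f"non-positive parameter values for {bad}")
    return {n: out[n] for n in names}


def params_to_vector(params: Mapping[str, float], names: Sequence[str]) -> np.ndarray:
    return np.array([params[n] for n in names], dtype=float)


def vector_to_params(vec: np.ndarray, names: Sequence[str]) -> dict:
    return dict(zip(names, map(float, vec)))


@dataclass(frozen=True)
class InputSignal:
    """External drive for one simulation segment.

    ``S`` is the serum concentration (% serum, held constant within a
    segment; protocols with serum steps chain segments).  ``ke_const``
    is a constitutive MYC synthesis rate (uM/h) added on top of the
    serum-driven term; it is the dose variable of the biphasic
    protocol.  With ``serum_bypass`` the serum saturation factor
    sigma(S) = S/(K_S + S) is clamped to 1 ("direct MYC stimulation").
    """

    S: float = 0.0
    ke_const: float = 0.0
    serum_bypass: bool = False

    def __post_init__(self):
        if self.S < 0 or self.ke_const < 0:
            raise ContractError("serum level and ke_const must be >= 0")

    def serum_factor(self, K_S: float) -> float:
        if self.serum_bypass:
            return 1.0
        return self.S / (K_S + self.S)


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course on a reporting grid."""

    t: np.ndarray                # h, strictly increasing
    y: np.ndarray                # (len(t), n_species), clipped to >= 0
    species: tuple
    signal: InputSignal

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[:, self.species.index(name)]

    @property
    def e2f_mrna(self) -> np.ndarray:
        """Total E2F mRNA readout (m + m' for the duplicated variant)."""
        v = self["m"]
        if "m_p" in self.species:
            v = v + self["m_p"]
        return v

    @property
    def e2f_protein(self) -> np.ndarray:
        v = self["P"]
        if "P_p" in self.species:
            v = v + self["P_p"]
        return v


@dataclass(frozen=True)
class DoseResponse:
    """Endpoint readout of one species across a dose grid."""

    doses: np.ndarray
    values: np.ndarray
    direction: str = "none"       # up | down | none

    def __post_init__(self):
        if len(self.doses) != len(self.values):
            raise ContractError("doses and values must have equal length")
        if len(self.doses) > 1 and not np.all(np.diff(self.doses) > 0):
            raise ContractError("dose grid must be strictly increasing")


@dataclass(frozen=True)
class ModuleMap:
    """Assignment of free parameters to regulatory modules.

    Each module maps to ``(name, orientation)`` pairs; synthesis,
    translation and catalytic rates enter module strength
    proportionally, degradation constants (and the repression
    half-saturation K_X) inversely.  ``unassigned`` parameters are
    excluded from module strength.
    """

    modules: Mapping[str, tuple]
    unassigned: tuple

    MODULE_NAMES = ("sensor", "PFB", "NFB", "R")

    def members(self, module: str) -> tuple:
        if module not in self.modules:
            raise ContractError(f"unknown module {module!r}")
        return self.modules[module]

    def module_of(self, name: str) -> str:
        for mod, members in self.modules.items():
            if any(n == name for n, _ in members):
                return mod
        if name in self.unassigned:
            return "unassigned"
        raise ContractError(f"parameter {name!r} not in module map")


_BASE_MODULE_MAP = ModuleMap(
    modules={
        "sensor": (
            ("ke_MYC", "proportional"), ("k_CDm", "proportional"),
            ("k_CDs", "proportional"), ("k_E2Fm", "proportional"),
            ("k_tl", "proportional"), ("k_phD", "proportional"),
            ("d_MYC", "inverse"), ("d_CD", "inverse"),
            ("d_E2Fm", "inverse"), ("d_E2Fp", "inverse"),
        ),
        "PFB": (
            ("k_auto", "proportional"), ("k_CE", "proportional"),
            ("k_phE", "proportional"), ("d_CE", "inverse"),
        ),
        "NFB": (
            ("k_A", "proportional"), ("k_Adeg", "proportional"),
            ("d_A", "inverse"),
        ),
        "R": (
            ("k_X", "proportional"), ("d_X", "inverse"), ("K_X", "inverse"),
        ),
    },
    unassigned=("K_S", "K_M", "K_P", "K_RB", "K_phD", "K_phE", "K_XM",
                "k_RB", "d_RB", "k_deph", "d_RP"),
)

# E2F' synthesis/degradation mirror the sensor-assigned E2F parameters;
# the duplicated autoactivation rate mirrors PFB.
_DUP_MODULE_MAP = ModuleMap(
    modules={
        "sensor": _BASE_MODULE_MAP.modules["sensor"] + (
            ("k_E2Fm_p", "proportional"), ("k_tl_p", "proportional"),
            ("d_E2Fm_p", "inverse"), ("d_E2Fp_p", "inverse"),
        ),
        "PFB": _BASE_MODULE_MAP.modules["PFB"] + (("k_auto_p", "proportional"),),
        "NFB": _BASE_MODULE_MAP.modules["NFB"],
        "R": _BASE_MODULE_MAP.modules["R"],
    },
    unassigned=_BASE_MODULE_MAP.unassigned,
)


@dataclass(frozen=True)
class ModelSpec:
    """A model variant with its species, parameters and search ranges."""

    variant: str
    species: tuple
    param_names: tuple
    ranges: Mapping[str, tuple]          # name -> (lo, hi), log-uniform search
    module_map: ModuleMap
    frozen: tuple = ()                   # parameters excluded from the search
    rtol: float = 1e-6
    atol: float = 1e-9

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def free_parameters(self) -> tuple:
        return tuple(n for n in self.param_names if n not in self.frozen)

    def validate_params(self, params: Mapping[str, float]) -> dict:
        return canonical_params(params, self.param_names)

    def rhs(self) -> Callable:
        return _kernels.rhs_base if self.variant == "base" else _kernels.rhs_dup

    def rhs_batch(self) -> Callable:
        return (_kernels.rhs_base_batch if self.variant == "base"
                else _kernels.rhs_dup_batch)


def _load_nominal() -> dict:
    from .data import reference_params
    return reference_params("reference_bistable")


def build_model(variant: str, config: Mapping | None = None) -> ModelSpec:
    """Builds the RB-E2F model for ``variant`` in {'base', 'dup_e2f'}.

    ``config`` may carry ``ranges`` (name -> [lo, hi] overrides),
    ``frozen`` (parameter names excluded from the search), ``rtol`` and
    ``atol``.  Default search ranges span four decades centred on the
    bundled reference (bistable) parameter set; E2F' parameters share
    the ranges of their unprimed counterparts.
    """
    config = dict(config or {})
    if variant == "base":
        species, names, module_map = BASE_SPECIES, BASE_PARAMS, _BASE_MODULE_MAP
    elif variant == "dup_e2f":
        species, names, module_map = DUP_SPECIES, DUP_PARAMS, _DUP_MODULE_MAP
    else:
        raise ConfigurationError(f"unknown model variant {variant!r}")

    nominal = _load_nominal()
    ranges = {}
    for name in names:
        base_name = name[:-2] if name.endswith("_p") else name
        center = nominal[base_name]
        ranges[name] = (center / 100.0, center * 100.0)
    for name, bounds in (config.get("ranges") or {}).items():
        canon = resolve_param_name(name)
        if canon not in names:
            raise ConfigurationError(f"range given for unknown parameter {name!r}")
        lo, hi = float(bounds[0]), float(bounds[1])
        ranges[canon] = (lo, hi)
    for name, (lo, hi) in ranges.items():
        if not (0 < lo < hi):
            raise ConfigurationError(
                f"invalid range for {name!r}: require 0 < lo < hi, got ({lo}, {hi})")

    frozen = tuple(resolve_param_name(n) for n in config.get("frozen", ()))
    unknown = [n for n in frozen if n not in names]
    if unknown:
        raise ConfigurationError(f"cannot freeze unknown parameters {unknown}")

    return ModelSpec(
        variant=variant, species=species, param_names=names,
        ranges=ranges, module_map=module_map, frozen=frozen,
        rtol=float(config.get("rtol", 1e-6)), atol=float(config.get("atol", 1e-9)),
    )


# ---------------------------------------------------------------------------
# Integration

_MXSTEP = 50_000


def _integrate(model, pvec, y0, t, sig, ke_const, params=None, signal=None):
    """odeint/LSODA wrapper returning the state at the times in ``t``."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y, info = odeint(
                model.rhs(), y0, t, args=(pvec, sig, ke_const),
                rtol=model.rtol, atol=model.atol, mxstep=_MXSTEP,
                full_output=True, printmessg=False, tfirst=False,
            )
    except (ZeroDivisionError, OverflowError, ValueError) as exc:
        # extreme parameter draws can blow up inside the LSODA driver
        raise SimulationError(f"stiff solver failed: {exc!r}", params=params,
                              signal=signal) from exc
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"stiff solver failed: {info['message']}", params=params, signal=signal)
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state", params=params, signal=signal)
    return y


def _integrate_batch(model, pvec, y0_flat, t, sigs, kes, params=None):
    """Integrates independent dose replicas in one banded-Jacobian call."""
    ns = model.n_species
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y, info = odeint(
                model.rhs_batch(), y0_flat, t, args=(pvec, sigs, kes),
                rtol=model.rtol, atol=model.atol, mxstep=_MXSTEP,
                ml=ns - 1, mu=ns - 1, full_output=True, printmessg=False,
            )
    except (ZeroDivisionError, OverflowError, ValueError) as exc:
        raise SimulationError(f"stiff solver failed: {exc!r}",
                              params=params) from exc
    if info["message"] != "Integration successful.":
        raise SimulationError(f"stiff solver failed: {info['message']}",
                              params=params)
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state", params=params)
    return y


def simulate(model: ModelSpec, params: Mapping[str, float], signal: InputSignal,
             init_state: np.ndarray, duration: float,
             report_times: Sequence[float] | None = None) -> Trajectory:
    """Integrates the model for ``duration`` hours under a constant input.

    Deterministic for fixed inputs and tolerances.  Reported
    concentrations are clipped at zero (the solver may undershoot by up
    to its absolute tolerance).
    """
    if duration <= 0:
        raise ContractError("duration must be > 0")
    init_state = np.asarray(init_state, dtype=float)
    if init_state.shape != (model.n_species,):
        raise ContractError(
            f"init_state must have shape ({model.n_species},)")
    if np.any(init_state < 0):
        raise ContractError("init_state must be nonnegative")
    params = model.validate_params(params)
    pvec = params_to_vector(params, model.param_names)
    if report_times is None:
        t = np.array([0.0, float(duration)])
    else:
        t = np.asarray(report_times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
            raise ContractError("report_times must be strictly increasing")
        if t[0] != 0.0:
            t = np.concatenate([[0.0], t])
        if t[-1] > duration:
            raise ContractError("report_times exceed duration")
    sig = signal.serum_factor(params["K_S"])
    y = _integrate(model, pvec, init_state, t, sig, signal.ke_const,
                   params=params, signal=signal)
    if report_times is not None and len(y) > len(report_times):
        y, t = y[1:], t[1:]
    return Trajectory(t=t, y=np.clip(y, 0.0, None), species=model.species,
                      signal=signal)


QUIESCENT_SERUM = 0.01
ACTIVATED_SERUM = 10.0
EQUILIBRATION_H = 100.0


def _initial_state(model: ModelSpec, params: Mapping[str, float]) -> np.ndarray:
    y0 = np.zeros(model.n_species)
    y0[model.species.index("Rb")] = params["k_RB"] / params["d_RB"]
    return y0


def _endpoint(model, pvec, y0, sig, ke, duration, params=None):
    t = np.array([0.0, float(duration)])
    return _integrate(model, pvec, y0, t, sig, ke, params=params)[-1]


def quiescent_state(model: ModelSpec, params: Mapping[str, float]) -> np.ndarray:
    """Steady state at starvation-level serum (0.01%).

    Obtained by 100 h of pre-equilibration from the RB-dominant state
    (all species zero except Rb at its synthesis/decay balance); this is
    the initial condition of every protocol that starts "from 0.01%
    serum".
    """
    params = model.validate_params(params)
    pvec = params_to_vector(params, model.param_names)
    sig = InputSignal(S=QUIESCENT_SERUM).serum_factor(params["K_S"])
    y = _endpoint(model, pvec, _initial_state(model, params), sig, 0.0,
                  EQUILIBRATION_H, params=params)
    return np.clip(y, 0.0, None)


def default_serum_grid(n: int = 21) -> np.ndarray:
    return np.logspace(np.log10(QUIESCENT_SERUM), np.log10(ACTIVATED_SERUM), n)


def default_myc_grid(model: ModelSpec, n: int = 21) -> np.ndarray:
    lo, hi = model.ranges["ke_MYC"]
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _sweep_endpoints(model, params, init, doses_sig, kes, horizon):
    """24/36-h endpoints for a dose grid, integrated as one batch."""
    pvec = params_to_vector(params, model.param_names)
    ns = model.n_species
    n = len(doses_sig)
    y0 = np.tile(init, n)
    t = np.array([0.0, float(horizon)])
    y = _integrate_batch(model, pvec, y0, t, np.asarray(doses_sig),
                         np.asarray(kes), params=params)[-1]
    return np.clip(y.reshape(n, ns), 0.0, None)


def _mrna_readout(model, states):
    v = states[:, model.species.index("m")]
    if "m_p" in model.species:
        v = v + states[:, model.species.index("m_p")]
    return v


def serum_bidirectional_sweep(
    model: ModelSpec, params: Mapping[str, float],
    grid: np.ndarray | None = None, horizon: float = 24.0,
) -> tuple[DoseResponse, DoseResponse]:
    """Hysteresis protocol: E2F mRNA 24 h after a serum change.

    The *up* branch starts every dose from the quiescent state; the
    *down* branch starts from the state after 100 h at 10% serum.  A
    bistable parameter set separates the two branches over an interval
    of doses; a monostable one collapses them.
    """
    params = model.validate_params(params)
    grid = default_serum_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ContractError("serum grid must be strictly increasing")
    K_S = params["K_S"]
    sigs = grid / (K_S + grid)
    kes = np.zeros_like(grid)

    q = quiescent_state(model, params)
    pvec = params_to_vector(params, model.param_names)
    sig_hi = ACTIVATED_SERUM / (K_S + ACTIVATED_SERUM)
    active = np.clip(
        _endpoint(model, pvec, q, sig_hi, 0.0, EQUILIBRATION_H, params=params),
        0.0, None)

    up_states = _sweep_endpoints(model, params, q, sigs, kes, horizon)
    down_states = _sweep_endpoints(model, params, active, sigs, kes, horizon)
    up = DoseResponse(grid, _mrna_readout(model, up_states), "up")
    down = DoseResponse(grid, _mrna_readout(model, down_states), "down")
    return up, down


def myc_sweep(model: ModelSpec, params: Mapping[str, float],
              grid: np.ndarray | None = None, horizon: float = 36.0) -> DoseResponse:
    """Biphasic protocol: E2F mRNA 36 h after direct MYC stimulation.

    Each dose sets the constitutive MYC synthesis rate ``ke_const``
    with the serum saturation factor clamped to 1; the run starts from
    the quiescent state.
    """
    params = model.validate_params(params)
    grid = default_myc_grid(model) if grid is None else np.asarray(grid, dtype=float)
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise ContractError("MYC dose grid must be strictly increasing")
    q = quiescent_state(model, params)
    sigs = np.ones_like(grid)
    states = _sweep_endpoints(model, params, q, sigs, grid, horizon)
    return DoseResponse(grid, _mrna_readout(model, states), "none")
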