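"""Core signaling model of drug-induced glioma differentiation.

The model tracks ten normalized activation levels:

    PKA, CREB, PI3K, AKT, pGSK3b, IL6, JAK2, STAT3, CyclinD1, GFAP

driven by the cAMP inducer cholera toxin (CT, in ng/ml).  CT activates
PKA, which (i) phosphorylates CREB, (ii) inhibits PI3K/AKT and thereby
de-phosphorylates GSK3beta (raising the active pool aGSK3b), and
(iii) activates the IL6/JAK2/STAT3 axis.  Active GSK3beta drives cyclin D1
degradation; cyclin D1 sustains itself through a Hill-type positive
feedback loop, which makes its subsystem a bistable one-way switch.
GFAP, the astrocytic differentiation marker, is produced by CREB/STAT3
and aGSK3b but only once cyclin D1 has been degraded below its maximal
steady state C (the gate factor f0).

Time is in hours; species are dimensionless normalized concentrations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from types import SimpleNamespace
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "PARAM_NAMES",
    "N_SPECIES",
    "N_PARAMS",
    "ParameterSet",
    "Trajectory",
    "Ensemble",
    "michaelis_menten",
    "hill_activation",
    "differentiation_gate",
    "drift",
    "production_rates",
    "degradation_rates",
    "active_gsk3b",
    "default_parameters",
    "default_initial_state",
    "load_parameters",
    "save_parameters",
    "load_initial_state",
    "validate_state",
]

#: Fixed species ordering used by every state vector in the package.
SPECIES = (
    "PKA",
    "CREB",
    "PI3K",
    "AKT",
    "pGSK3b",
    "IL6",
    "JAK2",
    "STAT3",
    "CyclinD1",
    "GFAP",
)
N_SPECIES = len(SPECIES)

#: The 39 kinetic constants, one extrinsic-noise slot each.
PARAM_NAMES = (
    "a1",
    "V1", "V2", "V4", "V5", "V6", "V7", "V8", "V9", "V10ab", "V10c",
    "K1", "K2", "K3", "K4", "K5", "K6a", "K6b", "K7", "K8", "K9",
    "K10a", "K10b", "K10c",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8", "d9", "d10",
    "n1", "n2", "n3",
    "GSK3bT", "C",
)
N_PARAMS = len(PARAM_NAMES)
assert N_PARAMS == 39

_HILL_EXPONENTS = ("n1", "n2", "n3")
_POSITIVE = ("GSK3bT", "C")


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's domain constraints."""


class StateError(ValueError):
    """Raised when a species state violates the model's domain constraints."""


@dataclass(frozen=True)
class ParameterSet:
    """The 39 kinetic constants of the signaling model.

    Rates (a1, V*, d*) are in 1/h, Michaelis/Hill constants K* in
    normalized-concentration units (K1 in (ng/ml)^n1), Hill exponents
    dimensionless, GSK3bT the total GSK3beta pool and C the maximal
    steady-state cyclin D1 level (both normalized concentrations).
    """

    a1: float
    V1: float
    V2: float
    V4: float
    V5: float
    V6: float
    V7: float
    V8: float
    V9: float
    V10ab: float
    V10c: float
    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    K6a: float
    K6b: float
    K7: float
    K8: float
    K9: float
    K10a: float
    K10b: float
    K10c: float
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    d6: float
    d7: float
    d8: float
    d9: float
    d10: float
    n1: float
    n2: float
    n3: float
    GSK3bT: float
    C: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ParameterError(f"parameter {name} is not finite: {value}")
            if value < 0:
                raise ParameterError(f"parameter {name} must be >= 0, got {value}")
        for name in _HILL_EXPONENTS:
            if getattr(self, name) < 1:
                raise ParameterError(f"Hill exponent {name} must be >= 1")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ParameterError(f"parameter {name} must be > 0")

    def as_array(self) -> np.ndarray:
        """Parameter values as a (39,) array in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (N_PARAMS,):
            raise ParameterError(f"expected shape ({N_PARAMS},), got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def with_updates(self, **updates: float) -> "ParameterSet":
        unknown = set(updates) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameters: {sorted(unknown)}")
        return replace(self, **updates)


def _param_view(params) -> SimpleNamespace:
    """Pass-through for objects already exposing parameter attributes."""
    if isinstance(params, Mapping):
        return SimpleNamespace(**params)
    return params


# ---------------------------------------------------------------------------
# Elementary rate laws
# ---------------------------------------------------------------------------

def michaelis_menten(S, V, K):
    """Michaelis-Menten rate V*S/(K+S).

    Scalar or array-valued; bounded by V; raises on negative input.
    """
    S, V, K = (np.asarray(x, dtype=float) for x in (S, V, K))
    if np.any(S < 0) or np.any(V < 0) or np.any(K < 0):
        raise ParameterError("michaelis_menten requires non-negative S, V, K")
    denom = K + S
    if np.any(denom <= 0):
        raise ParameterError("michaelis_menten requires K + S > 0")
    out = V * S / denom
    return float(out) if out.ndim == 0 else out


def hill_activation(S, V, K, n, *, shifted_K: bool = False):
    """Hill activation rate.

    Default form V*S^n/(K^n + S^n): half-maximal at S=K, used by the
    cyclin D1 positive feedback.  With ``shifted_K=True`` the denominator
    is K + S^n (the form used for the CT input on PKA and for the
    aGSK3b arm of GFAP production, where K carries the units of S^n).
    """
    S, V, K, n = (np.asarray(x, dtype=float) for x in (S, V, K, n))
    if np.any(S < 0) or np.any(V < 0) or np.any(K < 0):
        raise ParameterError("hill_activation requires non-negative S, V, K")
    if np.any(n < 1):
        raise ParameterError("hill_activation requires Hill exponent n >= 1")
    Sn = S ** n
    denom = (K if shifted_K else K ** n) + Sn
    out = np.where(denom > 0, V * Sn / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def differentiation_gate(cyclinD1, C):
    """Gate factor f0 = ((C - CyclinD1)/C)^+ on GFAP production.

    Fully open (1) when cyclin D1 is absent, closed (0) at or above the
    maximal steady state C.  Proliferating cells (high cyclin D1) cannot
    express the differentiation program.
    """
    cyclinD1 = np.asarray(cyclinD1, dtype=float)
    C = np.asarray(C, dtype=float)
    if np.any(C <= 0):
        raise ParameterError("differentiation_gate requires C > 0")
    if np.any(cyclinD1 < 0):
        raise ParameterError("differentiation_gate requires cyclinD1 >= 0")
    out = np.clip((C - cyclinD1) / C, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def active_gsk3b(pGSK3b, GSK3bT):
    """Active (unphosphorylated) GSK3beta pool: GSK3bT - pGSK3b."""
    return GSK3bT - pGSK3b


# ---------------------------------------------------------------------------
# Drift / reaction channels
# ---------------------------------------------------------------------------

def production_rates(state, CT, params) -> np.ndarray:
    """Per-species production channel rates (the positive term of each ODE).

    ``state`` may be a (10,) vector or an (n, 10) batch; parameter
    attributes may themselves be arrays broadcasting against the batch
    (used for per-trajectory extrinsic perturbations).
    """
    p = _param_view(params)
    y = np.asarray(state, dtype=float)
    PKA, CREB, PI3K, AKT, pG = (y[..., i] for i in range(5))
    IL6, JAK2, STAT3, CD, _GFAP = (y[..., i] for i in range(5, 10))
    aG = np.maximum(p.GSK3bT - pG, 0.0)

    out = np.empty_like(y)
    CTn = np.asarray(float(CT), dtype=float) ** p.n1
    out[..., 0] = p.a1 + p.V1 * CTn / (p.K1 + CTn)
    out[..., 1] = p.V2 * PKA / (p.K2 + PKA)
    out[..., 2] = 1.0 / (1.0 + PKA / p.K3)
    out[..., 3] = p.V4 * PI3K / (p.K4 + PI3K)
    free_g = np.maximum(p.GSK3bT - pG, 0.0)
    out[..., 4] = p.V5 * free_g / (p.K5 + free_g) * AKT
    out[..., 5] = p.V7 * PKA / (p.K7 + PKA)
    out[..., 6] = p.V8 * IL6 / (p.K8 + IL6)
    out[..., 7] = p.V9 * JAK2 / (p.K9 + JAK2)
    CDn = CD ** p.n2
    out[..., 8] = p.V6 * CDn / (p.K6a ** p.n2 + CDn)
    f0 = np.clip((p.C - CD) / p.C, 0.0, 1.0)
    aGn = aG ** p.n3
    out[..., 9] = f0 * (
        p.V10ab * CREB / (p.K10a + CREB) * STAT3 / (p.K10b + STAT3)
        + p.V10c * aGn / (p.K10c + aGn)
    )
    return out


def degradation_rates(state, CT, params) -> np.ndarray:
    """Per-species degradation channel rates (the removal term of each ODE)."""
    p = _param_view(params)
    y = np.asarray(state, dtype=float)
    pG = y[..., 4]
    CD = y[..., 8]
    aG = np.maximum(p.GSK3bT - pG, 0.0)
    d = np.empty_like(y)
    # species 0..7 decay linearly; cyclin D1 (8) and GFAP (9) below
    for i, rate in enumerate((p.d1, p.d2, p.d3, p.d4, p.d5, p.d7, p.d8, p.d9)):
        d[..., i] = rate * y[..., i]
    d[..., 8] = p.d6 * aG / (p.K6b + aG) * CD
    d[..., 9] = p.d10 * y[..., 9]
    return d


def drift(state, CT, params) -> np.ndarray:
    """Deterministic drift F(t, Y): production minus degradation.

    Raises :class:`StateError` if the phosphorylated GSK3beta pool
    exceeds the total pool (the state is then outside the model domain).
    """
    p = _param_view(params)
    y = np.asarray(state, dtype=float)
    if np.any(y[..., 4] > np.asarray(p.GSK3bT) * (1 + 1e-12)):
        raise StateError("pGSK3b exceeds total GSK3b pool")
    return production_rates(y, CT, p) - degradation_rates(y, CT, p)


def validate_state(state, params: ParameterSet) -> np.ndarray:
    """Check a species vector against the model invariants; returns it."""
    y = np.asarray(state, dtype=float)
    if y.shape[-1] != N_SPECIES:
        raise StateError(f"state must have {N_SPECIES} species, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise StateError("state contains non-finite values")
    if np.any(y < 0):
        raise StateError("species levels must be non-negative")
    if np.any(y[..., 4] > params.GSK3bT + 1e-12):
        raise StateError("pGSK3b exceeds total GSK3b pool")
    return y


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A single simulated path of the ten species.

    ``states`` has shape (len(t), 10) in :data:`SPECIES` order.
    """

    t: np.ndarray
    states: np.ndarray
    CT: float
    regime: str = "ode"
    seed: int | None = None
    dt: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.t.ndim != 1 or np.any(np.diff(self.t) <= 0) or self.t[0] != 0:
            raise ValueError("time grid must be strictly increasing from 0")
        if self.states.shape != (self.t.size, N_SPECIES):
            raise ValueError("states must have shape (len(t), 10)")

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    def at(self, time: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[idx] - time) > 1e-9 + 1e-6 * max(1.0, abs(time)):
            raise ValueError(f"time {time} not on trajectory grid")
        return self.states[idx]


@dataclass
class Ensemble:
    """A set of trajectories on a common time grid (one simulated cell each).

    ``states`` has shape (n_traj, len(t), 10).
    """

    t: np.ndarray
    states: np.ndarray
    CT: float
    regime: str
    master_seed: int | None = None
    trajectory_seeds: list[int] = field(default_factory=list)
    noise_spec: object | None = None
    clamp_count: int = 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 3 or self.states.shape[1:] != (self.t.size, N_SPECIES):
            raise ValueError("states must have shape (n_traj, len(t), 10)")
        if self.trajectory_seeds and len(set(self.trajectory_seeds)) != len(self.trajectory_seeds):
            raise ValueError("per-trajectory seeds must be distinct")

    @property
    def n_traj(self) -> int:
        return self.states.shape[0]

    def species(self, name: str) -> np.ndarray:
        """(n_traj, len(t)) matrix of one species."""
        return self.states[:, :, SPECIES.index(name)]

    def time_index(self, time: float) -> int:
        idx = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[idx] - time) > 1e-9 + 1e-6 * max(1.0, abs(time)):
            raise ValueError(f"time {time} not on ensemble grid")
        return idx

    def to_frame(self):
        """Long-format DataFrame (trajectory, time, species, value)."""
        import pandas as pd

        n, m, _ = self.states.shape
        return pd.DataFrame(
            {
                "trajectory": np.repeat(np.arange(n), m * N_SPECIES),
                "time": np.tile(np.repeat(self.t, N_SPECIES), n),
                "species": np.tile(SPECIES, n * m),
                "value": self.states.reshape(-1),
            }
        )


# ---------------------------------------------------------------------------
# Defaults and serialization
# ---------------------------------------------------------------------------

# Calibrated default parameter values.  Anchors: apparent Hill
# coefficients ~40 (cyclin D1) and ~43 (GFAP) for the 48-h dose
# response, the GFAP switch window inside CT in [6, 7] ng/ml, a
# bistable cyclin D1 subsystem without drug and a monostable low state
# at CT = 10 ng/ml.  See gliodiff.synthetic.calibrate_default_parameters
# for the procedure that produced them.
_DEFAULT_PARAMS = {
    "a1": 0.1,
    "V1": 3.0, "V2": 1.0, "V4": 1.0, "V5": 16.0, "V6": 0.4,
    "V7": 1.0, "V8": 1.0, "V9": 1.0, "V10ab": 0.52, "V10c": 0.476,
    "K1": 437000.0, "K2": 0.05, "K3": 0.2, "K4": 0.5, "K5": 5.0,
    "K6a": 0.5, "K6b": 1.0, "K7": 0.3, "K8": 0.3, "K9": 0.3,
    "K10a": 0.05, "K10b": 0.05, "K10c": 0.02,
    "d1": 1.0, "d2": 1.0, "d3": 1.0, "d4": 1.0, "d5": 1.0,
    "d6": 1.613, "d7": 1.0, "d8": 1.0, "d9": 1.0, "d10": 1.0,
    "n1": 5.0, "n2": 4.0, "n3": 2.0,
    "GSK3bT": 1.0, "C": 0.89,
}

# Basal (CT = 0) steady state with cyclin D1 on its high branch;
# recomputable via gliodiff.deterministic.basal_steady_state.
_DEFAULT_INITIAL = {
    "PKA": 0.100000000,
    "CREB": 0.666666667,
    "PI3K": 0.666666667,
    "AKT": 0.571428571,
    "pGSK3b": 0.629982507,
    "IL6": 0.250000000,
    "JAK2": 0.454545455,
    "STAT3": 0.602409639,
    "CyclinD1": 0.792718238,
    "GFAP": 0.094218860,
}


def default_parameters() -> ParameterSet:
    """The calibrated default :class:`ParameterSet` shipped with the package."""
    return ParameterSet(**_DEFAULT_PARAMS)


def default_initial_state() -> np.ndarray:
    """Default initial condition: the untreated (CT=0) steady state."""
    return np.array([_DEFAULT_INITIAL[name] for name in SPECIES], dtype=float)


def _read_structured(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_parameters(path) -> ParameterSet:
    """Load a parameter file (YAML or JSON, flat symbol->value mapping)."""
    data = _read_structured(Path(path))
    if not isinstance(data, dict):
        raise ParameterError(f"parameter file {path} must be a flat mapping")
    missing = sorted(set(PARAM_NAMES) - set(data))
    extra = sorted(set(data) - set(PARAM_NAMES))
    if missing or extra:
        raise ParameterError(
            f"parameter file {path}: missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}"
        )
    return ParameterSet(**{k: float(v) for k, v in data.items()})


def save_parameters(params: ParameterSet, path) -> None:
    path = Path(path)
    data = params.as_dict()
    if str(path).endswith(".json"):
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_initial_state(path, params: ParameterSet) -> np.ndarray:
    """Load an initial-state file (flat species->value mapping)."""
    data = _read_structured(Path(path))
    missing = sorted(set(SPECIES) - set(data))
    extra = sorted(set(data) - set(SPECIES))
    if missing or extra:
        raise StateError(
            f"initial-state file {path}: missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}"
        )
    y0 = np.array([float(data[name]) for name in SPECIES])
    return validate_state(y0, params)
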