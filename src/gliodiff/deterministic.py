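"""Deterministic engine: ODE integration, dose-response analysis,
ultrasensitivity quantification, parameter sensitivity, and the
cyclin D1 steady-state (bistability) scan.

The headline statistic here is the apparent Hill coefficient

    H = ln 81 / ln(EC90 / EC10)

of a 48-h dose-response curve, where EC10 and EC90 are the doses
producing 10% and 90% of the maximal normalized response.  For an exact
Hill curve x^n/(K^n + x^n) the identity EC90/EC10 = 81^(1/n) makes
H equal to n; for the switch-like curves produced by the bistable
cyclin D1 subsystem H reaches the tens, so EC quantiles are refined by
bisection against the ODE rather than read off a fixed dose grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import (
    N_PARAMS,
    N_SPECIES,
    PARAM_NAMES,
    SPECIES,
    ParameterSet,
    Trajectory,
    drift,
    validate_state,
)

__all__ = [
    "solve_ode",
    "steady_state",
    "basal_steady_state",
    "DoseResponseCurve",
    "dose_response",
    "ec_quantile",
    "apparent_hill",
    "sensitivity_timecourse",
    "time_averaged_sensitivity",
    "sensitivity_ranking",
    "SensitivityTable",
    "cyclind1_steady_states",
    "cyclind1_degradation_slope",
]


class IntegrationError(RuntimeError):
    pass


def solve_ode(
    params: ParameterSet,
    initial,
    CT: float,
    T: float,
    grid=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the deterministic model over [0, T] hours.

    Uses a stiffness-tolerant implicit solver; the system becomes locally
    stiff near the cyclin D1 fold.  Tiny negative excursions within solver
    tolerance are clamped to zero.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if CT < 0:
        raise ValueError("CT dose must be non-negative")
    y0 = validate_state(initial, params)
    if grid is None:
        grid = np.linspace(0.0, T, max(int(round(T / 0.1)) + 1, 25))
    grid = np.asarray(grid, dtype=float)

    sol = solve_ivp(
        lambda t, y: drift(np.maximum(y, 0.0), CT, params),
        (0.0, T),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = np.clip(sol.y.T, 0.0, None)
    return Trajectory(t=grid, states=states, CT=CT, regime="ode")


def steady_state(
    params: ParameterSet,
    initial,
    CT: float,
    T: float = 2000.0,
    tol: float = 1e-9,
) -> np.ndarray:
    """Long-time integration until the drift norm falls below ``tol``."""
    y = np.asarray(initial, dtype=float)
    for _ in range(8):
        traj = solve_ode(params, y, CT, T, grid=np.array([0.0, T]))
        y = traj.states[-1]
        if np.max(np.abs(drift(y, CT, params))) < tol:
            return y
    raise IntegrationError("steady state not reached")


def basal_steady_state(params: ParameterSet) -> np.ndarray:
    """Untreated (CT = 0) steady state with cyclin D1 on its high branch.

    Starting cyclin D1 at C places it in the basin of the high fixed
    point when the subsystem is bistable, which is the proliferative
    resting state of the untreated cell.
    """
    # the PKA/CREB/PI3K/AKT/GSK3b and IL6/JAK2/STAT3 chains are
    # feed-forward (cyclin D1 does not feed back on them), so settle
    # them first; otherwise the equilibration transient (aGSK3b
    # maximal while AKT builds up) would spuriously collapse the
    # cyclin D1 switch
    upstream = steady_state(params, np.zeros(N_SPECIES), CT=0.0)
    y0 = upstream.copy()
    y0[SPECIES.index("CyclinD1")] = params.C
    y0[SPECIES.index("GFAP")] = 0.0
    return steady_state(params, y0, CT=0.0)


# ---------------------------------------------------------------------------
# Dose response and ultrasensitivity
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseCurve:
    """Response of one species at a fixed read-out time vs CT dose."""

    doses: np.ndarray
    response: np.ndarray
    species: str
    t_read: float
    params: ParameterSet | None = None
    initial: np.ndarray | None = None

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.doses.size < 2:
            raise ValueError("a dose-response curve needs at least 2 doses")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("dose grid must be strictly increasing")
        if self.doses.size != self.response.size:
            raise ValueError("doses and response must have equal length")

    @property
    def increasing(self) -> bool:
        return bool(self.response[-1] >= self.response[0])

    def normalized(self) -> np.ndarray:
        """Response rescaled to [0, 1] between the zero-dose baseline and
        the extreme response; decreasing curves use the fractional
        decrease so that 1 always means full effect."""
        lo, hi = self.response[0], self.response[-1]
        if hi == lo:
            raise ValueError("flat response cannot be normalized")
        return (self.response - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose": self.doses, "response": self.response})


def _readout(params, initial, dose, species_idx, t_read, rtol=1e-8):
    traj = solve_ode(
        params, initial, dose, t_read, grid=np.array([0.0, t_read]), rtol=rtol
    )
    return traj.states[-1, species_idx]


def dose_response(
    params: ParameterSet,
    doses,
    species: str = "GFAP",
    t_read: float = 48.0,
    initial=None,
) -> DoseResponseCurve:
    """Species level at ``t_read`` hours as a function of CT dose.

    Every dose starts from the same initial state (the untreated steady
    state by default), mirroring acute drug treatment of a resting
    population.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 doses")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if initial is None:
        initial = basal_steady_state(params)
    idx = SPECIES.index(species)
    response = np.array(
        [_readout(params, initial, d, idx, t_read) for d in doses]
    )
    return DoseResponseCurve(
        doses=doses,
        response=response,
        species=species,
        t_read=t_read,
        params=params,
        initial=np.asarray(initial, dtype=float),
    )


class NonMonotoneResponseError(ValueError):
    pass


def _check_monotone(curve: DoseResponseCurve, tol: float) -> np.ndarray:
    norm = curve.normalized()
    if np.any(np.diff(norm) < -tol):
        raise NonMonotoneResponseError(
            f"{curve.species} response is not monotone beyond tolerance {tol}"
        )
    return norm


def ec_quantile(
    curve: DoseResponseCurve,
    q: float,
    dose_tol: float = 1e-3,
    monotone_tol: float = 1e-3,
) -> float:
    """Dose producing fraction ``q`` of the maximal normalized response.

    Brackets the quantile on the curve's grid by monotone interpolation,
    then (when the curve carries its generating model) refines by
    bisection against fresh ODE read-outs until the dose bracket is
    tighter than ``dose_tol`` ng/ml.  Required because switch-like
    curves (H ~ 40 means EC90/EC10 ~ 1.12) cannot be resolved on any
    reasonable fixed grid.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    norm = _check_monotone(curve, monotone_tol)
    norm = np.maximum.accumulate(norm)  # iron out sub-tolerance ripples
    if q < norm[0] or q > norm[-1]:
        raise ValueError(f"quantile {q} outside achieved response range")
    k = int(np.searchsorted(norm, q))
    if k == 0:
        return float(curve.doses[0])
    lo, hi = curve.doses[k - 1], curve.doses[k]
    flo, fhi = norm[k - 1], norm[k]

    if curve.params is None or curve.initial is None:
        # pure interpolation (log-dose when possible)
        if lo > 0:
            t = (q - flo) / (fhi - flo) if fhi > flo else 0.5
            return float(lo * (hi / lo) ** t)
        return float(lo + (q - flo) / (fhi - flo) * (hi - lo))

    idx = SPECIES.index(curve.species)
    y_lo, y_hi = curve.response[0], curve.response[-1]

    # normalized response is increasing in dose for monotone curves of
    # either direction, so plain bisection applies
    def f(dose):
        y = _readout(curve.params, curve.initial, dose, idx, curve.t_read)
        return (y - y_lo) / (y_hi - y_lo) - q

    while hi - lo > dose_tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def apparent_hill(
    curve: DoseResponseCurve,
    dose_tol: float = 1e-3,
) -> float:
    """Apparent Hill coefficient H = ln81 / ln(EC90/EC10) of a curve."""
    ec10 = ec_quantile(curve, 0.1, dose_tol=dose_tol)
    ec90 = ec_quantile(curve, 0.9, dose_tol=dose_tol)
    if ec90 <= ec10:
        raise ValueError(f"EC90 ({ec90}) must exceed EC10 ({ec10})")
    return math.log(81.0) / math.log(ec90 / ec10)


# ---------------------------------------------------------------------------
# Parameter sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityTable:
    """Time-averaged sensitivities of one output species, one row per
    perturbed parameter, sorted descending by the mean over repeats."""

    table: pd.DataFrame  # columns: parameter, mean, sd
    timecourses: dict[str, np.ndarray] = field(default_factory=dict)
    grid: np.ndarray | None = None
    delta: float = 0.05
    target: str = "GFAP"

    def top(self, k: int) -> list[str]:
        return list(self.table["parameter"].iloc[:k])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sensitivity_timecourse(
    params: ParameterSet,
    p_name: str,
    delta: float = 0.05,
    target: str = "GFAP",
    CT: float = 6.5,
    T: float = 48.0,
    L: int = 100,
    initial=None,
    central: bool = False,
    zero_tol: float = 1e-9,
    _baseline=None,
):
    """Time-dependent relative sensitivity of ``target`` to ``p_name``.

    Forward finite difference (d[out]/[out]) / (dP/P) with a fractional
    perturbation ``delta`` (default +5%).  Points where the baseline
    output is below ``zero_tol`` are masked (NaN) and their count
    returned, not silently dropped.

    Returns (grid, S(t), n_excluded).
    """
    if p_name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {p_name}")
    if initial is None:
        initial = basal_steady_state(params)
    grid = np.linspace(0.0, T, L)
    idx = SPECIES.index(target)
    if _baseline is None:
        _baseline = solve_ode(params, initial, CT, T, grid=grid).states[:, idx]
    base = _baseline

    def run(factor):
        pset = params.with_updates(**{p_name: getattr(params, p_name) * factor})
        return solve_ode(pset, initial, CT, T, grid=grid).states[:, idx]

    if central:
        up, down = run(1 + delta), run(1 - delta)
        diff = (up - down) / 2.0
    else:
        diff = run(1 + delta) - base

    mask = base > zero_tol
    S = np.full(L, np.nan)
    S[mask] = (diff[mask] / base[mask]) / delta
    return grid, S, int(np.sum(~mask))


def time_averaged_sensitivity(S_t: np.ndarray) -> float:
    """Mean absolute sensitivity over the (equal-partition) time grid,
    ignoring masked points."""
    S_t = np.asarray(S_t, dtype=float)
    valid = S_t[np.isfinite(S_t)]
    if valid.size == 0:
        return float("nan")
    return float(np.mean(np.abs(valid)))


def sensitivity_ranking(
    params: ParameterSet,
    delta: float = 0.05,
    target: str = "GFAP",
    CT: float = 6.5,
    T: float = 48.0,
    L: int = 100,
    repeats: int = 1,
    regime: str = "ode",
    noise_percent: float = 5.0,
    seed: int | None = None,
    parameters=None,
) -> SensitivityTable:
    """Rank all 39 parameters by time-averaged |sensitivity| of ``target``.

    ``regime='ode'`` is deterministic (repeats collapse to one);
    ``regime='anm'`` perturbs on top of additive-noise simulations with
    shared noise streams per repeat, and reports mean and sd across
    ``repeats`` independent repeats.
    """
    names = list(parameters) if parameters is not None else list(PARAM_NAMES)
    initial = basal_steady_state(params)
    grid = np.linspace(0.0, T, L)
    idx = SPECIES.index(target)

    def outputs_for(pset, rng_seed):
        if regime == "ode":
            return solve_ode(pset, initial, CT, T, grid=grid).states[:, idx]
        elif regime == "anm":
            from .anm import ANMNoiseSpec, simulate_anm

            spec = ANMNoiseSpec(percent=noise_percent, seed=rng_seed)
            traj = simulate_anm(pset, initial, CT, spec, T, grid=grid)
            return traj.states[:, idx]
        raise ValueError(f"unknown regime {regime!r}")

    n_rep = 1 if regime == "ode" else max(int(repeats), 1)
    per_repeat = {name: [] for name in names}
    timecourses: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for r in range(n_rep):
        rep_seed = int(rng.integers(0, 2**31 - 1)) if regime != "ode" else None
        base = outputs_for(params, rep_seed)
        mask = base > 1e-9
        for name in names:
            pset = params.with_updates(**{name: getattr(params, name) * (1 + delta)})
            out = outputs_for(pset, rep_seed)
            S = np.full(L, np.nan)
            S[mask] = (out[mask] - base[mask]) / base[mask] / delta
            per_repeat[name].append(time_averaged_sensitivity(S))
            if r == 0:
                timecourses[name] = S
    rows = [
        {
            "parameter": name,
            "mean": float(np.mean(per_repeat[name])),
            "sd": float(np.std(per_repeat[name], ddof=1)) if n_rep > 1 else 0.0,
        }
        for name in names
    ]
    table = (
        pd.DataFrame(rows)
        .sort_values("mean", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return SensitivityTable(
        table=table, timecourses=timecourses, grid=grid, delta=delta, target=target
    )


# ---------------------------------------------------------------------------
# Cyclin D1 steady-state scan (the one-way switch)
# ---------------------------------------------------------------------------

def cyclind1_degradation_slope(params: ParameterSet, aGSK3b_level: float) -> float:
    """Effective linear degradation rate g = d6 * aG/(K6b + aG) (1/h)."""
    if not 0 <= aGSK3b_level <= params.GSK3bT:
        raise ValueError("aGSK3b level must lie in [0, GSK3bT]")
    return params.d6 * aGSK3b_level / (params.K6b + aGSK3b_level)


def cyclind1_steady_states(
    params: ParameterSet,
    aGSK3b_level: float,
    n_scan: int = 20000,
) -> list[tuple[float, bool]]:
    """All non-negative fixed points of the isolated cyclin D1 subsystem.

    Solves V6 x^n2/(K6a^n2 + x^n2) = g x for the degradation slope g
    implied by the given active-GSK3beta level, by dense sign-change
    scanning plus bisection.  Returns (root, stable) pairs sorted by
    root; with n2 > 1, x = 0 is always a (stable) root, and depending
    on g the system has one or three fixed points — the bistable
    one-way switch.
    """
    g = cyclind1_degradation_slope(params, aGSK3b_level)

    def f(x):
        return (
            params.V6 * x ** params.n2 / (params.K6a ** params.n2 + x ** params.n2)
            - g * x
        )

    roots = [0.0]
    if g > 0:
        x_max = params.V6 / g * 1.05 + params.K6a
        xs = np.linspace(1e-12, x_max, n_scan)
        fs = f(xs)
        for i in range(len(xs) - 1):
            if fs[i] == 0.0:
                roots.append(float(xs[i]))
            elif fs[i] * fs[i + 1] < 0:
                roots.append(float(brentq(f, xs[i], xs[i + 1], xtol=1e-12)))

    # deduplicate and label stability by the sign of f'(x)
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or r - uniq[-1] > 1e-9:
            uniq.append(r)
    labeled = []
    for r in uniq:
        h = max(1e-7, 1e-7 * r)
        if r == 0.0:
            stable = f(h) < 0 or g > 0
        else:
            stable = (f(r + h) - f(r - h)) < 0
        labeled.append((r, bool(stable)))
    return labeled
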