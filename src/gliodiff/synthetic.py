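"""Synthetic data generation, parameter fitting, and calibration.

This module produces every input the analysis pipeline needs:

* noisy 48-h dose-response observations of cyclin D1 and GFAP, emulating
  quantified immunoblot data points around the model curve;
* least-squares parameter fitting against such observations, used for
  parameter-recovery testing (can the sensitive pair K6a/d6 be
  identified from dose-response data alone?);
* the anchor-based calibration that produced the package's default
  parameter set.  The anchors are the headline features of the system:
  apparent Hill coefficients near 40 (cyclin D1) and 43 (GFAP) at 48 h,
  a GFAP switch window inside CT in [6, 7] ng/ml, a bistable cyclin D1
  subsystem without drug, and a monostable low cyclin D1 state under
  CT = 10 ng/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .deterministic import (
    apparent_hill,
    basal_steady_state,
    cyclind1_steady_states,
    dose_response,
    ec_quantile,
    steady_state,
)
from .model import PARAM_NAMES, SPECIES, ParameterSet

__all__ = [
    "SyntheticObservation",
    "generate_dose_response_observations",
    "FitResult",
    "fit_parameters",
    "CalibrationAnchors",
    "CalibrationError",
    "calibrate_default_parameters",
    "check_anchors",
]


@dataclass
class SyntheticObservation:
    """Noisy dose-response observations at a fixed read-out time."""

    doses: np.ndarray
    cyclinD1: np.ndarray
    gfap: np.ndarray
    obs_sd: float
    seed: int | None
    t_read: float = 48.0

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.cyclinD1 = np.asarray(self.cyclinD1, dtype=float)
        self.gfap = np.asarray(self.gfap, dtype=float)
        if np.any(self.cyclinD1 < 0) or np.any(self.gfap < 0):
            raise ValueError("observed levels must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose": self.doses, "cyclinD1": self.cyclinD1, "GFAP": self.gfap}
        )


def _model_readouts(params, doses, t_read, initial=None):
    """(cyclinD1, GFAP) levels at t_read for each dose, from the basal state."""
    cd = dose_response(params, doses, "CyclinD1", t_read, initial=initial)
    gf = dose_response(params, doses, "GFAP", t_read, initial=initial)
    return cd.response, gf.response


def generate_dose_response_observations(
    params: ParameterSet,
    doses,
    obs_sd: float = 0.02,
    seed: int | None = None,
    t_read: float = 48.0,
) -> SyntheticObservation:
    """ODE read-outs plus independent Gaussian observation noise.

    Noise is truncated at zero (protein quantifications cannot be
    negative); ``obs_sd=0`` returns the model curve exactly.
    """
    if obs_sd < 0:
        raise ValueError("obs_sd must be >= 0")
    doses = np.asarray(doses, dtype=float)
    cd, gf = _model_readouts(params, doses, t_read)
    rng = np.random.default_rng(seed)
    if obs_sd > 0:
        cd = np.clip(cd + obs_sd * rng.standard_normal(cd.size), 0.0, None)
        gf = np.clip(gf + obs_sd * rng.standard_normal(gf.size), 0.0, None)
    return SyntheticObservation(
        doses=doses, cyclinD1=cd, gfap=gf, obs_sd=obs_sd, seed=seed, t_read=t_read
    )


@dataclass
class FitResult:
    params: ParameterSet
    loss: float
    converged: bool
    message: str
    n_evaluations: int


def fit_parameters(
    observed: SyntheticObservation,
    free_names,
    bounds: dict[str, tuple[float, float]],
    init: ParameterSet,
    xtol: float = 1e-10,
    ftol: float = 1e-12,
) -> FitResult:
    """Least-squares fit of selected parameters to dose-response data.

    Minimizes the summed squared residuals of the 48-h cyclin D1 and
    GFAP read-outs over ``free_names``, all other parameters held at
    their ``init`` values.  Deterministic given ``init`` and the data.
    """
    free_names = list(free_names)
    unknown = set(free_names) - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    x0 = np.array([getattr(init, n) for n in free_names])
    target = np.concatenate([observed.cyclinD1, observed.gfap])
    n_eval = 0

    def residuals(x):
        nonlocal n_eval
        n_eval += 1
        pset = init.with_updates(**dict(zip(free_names, x)))
        cd, gf = _model_readouts(pset, observed.doses, observed.t_read)
        return np.concatenate([cd, gf]) - target

    result = least_squares(
        residuals,
        np.clip(x0, lo, hi),
        bounds=(lo, hi),
        xtol=xtol,
        ftol=ftol,
        diff_step=1e-4,
    )
    fitted = init.with_updates(**dict(zip(free_names, result.x)))
    return FitResult(
        params=fitted,
        loss=float(np.sum(result.fun**2)),
        converged=bool(result.success),
        message=str(result.message),
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# Anchor calibration
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationAnchors:
    """Target features the default parameter set must reproduce."""

    H_cyclinD1: float = 40.0
    H_GFAP: float = 43.0
    H_rel_tol: float = 0.15
    ec10_min: float = 6.0  # GFAP EC10 lower bound, ng/ml
    ec90_max: float = 7.0  # GFAP EC90 upper bound, ng/ml
    CT_treated: float = 10.0
    dose_max: float = 10.0
    t_read: float = 48.0

    def __post_init__(self):
        if self.ec10_min > self.ec90_max:
            raise CalibrationError(
                "infeasible anchors: EC10 lower bound exceeds EC90 upper bound"
            )
        if self.H_cyclinD1 <= 0 or self.H_GFAP <= 0:
            raise CalibrationError("Hill-coefficient anchors must be positive")


def _dose_grid(anchors: CalibrationAnchors) -> np.ndarray:
    coarse = np.linspace(0.0, anchors.dose_max, 21)
    fine = np.linspace(5.0, 8.0, 61)
    return np.unique(np.concatenate([coarse, fine]))


def anchor_metrics(
    params: ParameterSet, anchors: CalibrationAnchors = CalibrationAnchors()
) -> dict:
    """Measure every anchored quantity for a candidate parameter set."""
    initial = basal_steady_state(params)
    doses = _dose_grid(anchors)
    curves = {
        name: dose_response(params, doses, name, anchors.t_read, initial=initial)
        for name in ("CyclinD1", "GFAP")
    }
    gfap = curves["GFAP"]

    def _try(fn, *args):
        # a broken candidate (e.g. no switch at all) yields NaN metrics,
        # which the anchor check then reports as violations rather than
        # aborting the whole calibration search
        try:
            return fn(*args)
        except ValueError:
            return float("nan")

    metrics = {
        "H_cyclinD1": _try(apparent_hill, curves["CyclinD1"]),
        "H_GFAP": _try(apparent_hill, gfap),
        "EC10_GFAP": _try(ec_quantile, gfap, 0.1),
        "EC90_GFAP": _try(ec_quantile, gfap, 0.9),
    }
    aG_basal = params.GSK3bT - initial[SPECIES.index("pGSK3b")]
    roots_basal = cyclind1_steady_states(params, aG_basal)
    treated = steady_state(params, initial, anchors.CT_treated)
    aG_treated = params.GSK3bT - treated[SPECIES.index("pGSK3b")]
    roots_treated = cyclind1_steady_states(params, aG_treated)
    metrics["bistable_basal"] = len(roots_basal) >= 3
    metrics["monostable_low_treated"] = (
        len(roots_treated) == 1 and roots_treated[0][0] == 0.0
    )
    return metrics


def check_anchors(
    params: ParameterSet, anchors: CalibrationAnchors = CalibrationAnchors()
) -> tuple[bool, dict]:
    """Whether a parameter set satisfies every calibration anchor."""
    m = anchor_metrics(params, anchors)
    ok = (
        abs(m["H_cyclinD1"] - anchors.H_cyclinD1)
        <= anchors.H_rel_tol * anchors.H_cyclinD1
        and abs(m["H_GFAP"] - anchors.H_GFAP) <= anchors.H_rel_tol * anchors.H_GFAP
        and m["EC10_GFAP"] >= anchors.ec10_min
        and m["EC90_GFAP"] <= anchors.ec90_max
        and m["bistable_basal"]
        and m["monostable_low_treated"]
    )
    return bool(ok), m


#: Parameters adjusted by the calibration search.  K1 places the dose
#: threshold, d6 sets the degradation pressure relative to the feedback
#: fold, V6 the height of that fold.
CALIBRATION_FREE = ("K1", "d6", "V6")


def calibrate_default_parameters(
    anchors: CalibrationAnchors = CalibrationAnchors(),
    start: ParameterSet | None = None,
    free_names=CALIBRATION_FREE,
    rel_bounds: float = 0.5,
    maxiter: int = 60,
) -> tuple[ParameterSet, dict]:
    """Bounded local search meeting the calibration anchors.

    Minimizes a scalar loss combining the relative Hill-coefficient
    errors and hinge penalties on the EC bounds, over ``free_names``
    within +/- ``rel_bounds`` of the starting values (Nelder-Mead on a
    log-parameter scale).  Returns the calibrated set and its metrics;
    raises :class:`CalibrationError` if the result violates an anchor.
    """
    from .model import default_parameters

    start = start or default_parameters()
    x0 = np.log([getattr(start, n) for n in free_names])
    lo, hi = x0 + np.log(1 - rel_bounds), x0 + np.log(1 + rel_bounds)

    def loss(x):
        x = np.clip(x, lo, hi)
        pset = start.with_updates(**dict(zip(free_names, np.exp(x))))
        try:
            m = anchor_metrics(pset, anchors)
        except Exception:
            return 1e3
        value = (
            ((m["H_cyclinD1"] - anchors.H_cyclinD1) / anchors.H_cyclinD1) ** 2
            + ((m["H_GFAP"] - anchors.H_GFAP) / anchors.H_GFAP) ** 2
            + max(0.0, anchors.ec10_min - m["EC10_GFAP"]) ** 2 * 10
            + max(0.0, m["EC90_GFAP"] - anchors.ec90_max) ** 2 * 10
        )
        if not m["bistable_basal"]:
            value += 10.0
        if not m["monostable_low_treated"]:
            value += 10.0
        return value

    result = minimize(
        loss,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-4},
    )
    best = start.with_updates(
        **dict(zip(free_names, np.exp(np.clip(result.x, lo, hi))))
    )
    ok, metrics = check_anchors(best, anchors)
    if not ok:
        raise CalibrationError(
            f"calibration failed to meet anchors; metrics: {metrics}"
        )
    return best, metrics
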