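"""Scenario runner: reproducible computational experiments.

A :class:`Scenario` is a fully serializable description of one
simulation experiment (regime, dose, horizon, noise, intervention,
sizes, seed); :func:`run_scenario` executes it and writes CSV results
plus a JSON manifest (config hash, seeds, clamp counts) so a run can be
reproduced bit-for-bit.  Preset scenarios cover the package's standard
experiments: the 48-h dose response with apparent Hill coefficients,
the parameter sensitivity ranking, additive-noise ensembles over the
sigma grid, CLE ensembles over intrinsic/extrinsic noise settings, and
the 2-D noise-grid scan of the differentiation potential with and
without cyclin D1 feedback inhibition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ParameterSet, default_parameters

__all__ = [
    "apply_intervention",
    "Scenario",
    "run_scenario",
    "noise_grid_potential",
    "PRESETS",
]

_INTERVENTION_PARAM = {"K6a_fold": "K6a", "n2_fold": "n2", "V6_fold": "V6"}


class InterventionWarning(UserWarning):
    pass


def apply_intervention(
    params: ParameterSet, mode: str, factor: float
) -> ParameterSet:
    """Cyclin D1 feedback intervention: scale one feedback parameter.

    ``mode`` selects the parameter: ``K6a_fold`` (raise the feedback
    Michaelis constant, e.g. x10 to inhibit the loop), ``n2_fold``
    (lower the feedback Hill exponent) or ``V6_fold`` (lower the
    feedback activation rate).  ``factor`` multiplies the parameter;
    "decreasing by 0.2-fold" is read as multiplication by 0.2.
    """
    if mode not in _INTERVENTION_PARAM:
        raise ValueError(f"unknown intervention mode {mode!r}")
    if factor <= 0:
        raise ValueError("intervention factor must be > 0")
    name = _INTERVENTION_PARAM[mode]
    value = getattr(params, name) * factor
    if name == "n2" and value < 1:
        import warnings

        warnings.warn(
            f"n2 intervention yields Hill exponent {value:.3g} < 1; clamping to 1",
            InterventionWarning,
        )
        value = 1.0
    return params.with_updates(**{name: value})


@dataclass
class Scenario:
    """Serializable description of one simulation experiment."""

    regime: str = "ode"  # ode | anm | cle
    CT: float = 10.0
    T: float = 48.0
    noise: dict = field(default_factory=dict)  # regime-specific noise fields
    intervention: dict | None = None  # {"mode": ..., "factor": ...}
    n_traj: int = 200
    replicates: int = 20
    cells_per_replicate: int = 100
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self):
        if self.regime not in ("ode", "anm", "cle"):
            raise ValueError(f"invalid regime {self.regime!r}")
        if self.T <= 0 or self.CT < 0:
            raise ValueError("require T > 0 and CT >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def effective_params(self, params: ParameterSet | None = None) -> ParameterSet:
        params = params or default_parameters()
        if self.intervention:
            params = apply_intervention(
                params, self.intervention["mode"], self.intervention["factor"]
            )
        return params


def _noise_spec(scenario: Scenario):
    if scenario.regime == "anm":
        from .anm import ANMNoiseSpec

        return ANMNoiseSpec(seed=scenario.seed, **scenario.noise)
    if scenario.regime == "cle":
        from .cle import CLENoiseSpec

        return CLENoiseSpec(seed=scenario.seed, **scenario.noise)
    return None


def run_scenario(
    scenario: Scenario,
    out_dir,
    params: ParameterSet | None = None,
) -> dict:
    """Execute a scenario, write CSV outputs and a JSON manifest.

    Returns the manifest dictionary.  ODE scenarios write the
    trajectory; stochastic scenarios write the long-format ensemble,
    the differentiation-potential series and summary statistics.
    """
    from .deterministic import basal_steady_state, solve_ode
    from .population import potential_series

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pset = scenario.effective_params(params)
    initial = basal_steady_state(pset)
    manifest = {
        "scenario": scenario.to_dict(),
        "config_hash": scenario.config_hash(),
        "outputs": [],
        "clamp_count": 0,
    }

    if scenario.regime == "ode":
        from .model import SPECIES

        traj = solve_ode(pset, initial, scenario.CT, scenario.T)
        df = pd.DataFrame(traj.states, columns=list(SPECIES))
        df.insert(0, "time", traj.t)
        path = out_dir / f"{scenario.name}_trajectory.csv"
        df.to_csv(path, index=False)
        manifest["outputs"].append(path.name)
    else:
        noise = _noise_spec(scenario)
        series = potential_series(
            scenario.regime,
            pset,
            scenario.CT,
            noise,
            scenario.T,
            cells_per_replicate=scenario.cells_per_replicate,
            replicates=scenario.replicates,
            seed=scenario.seed,
            initial=initial,
        )
        path = out_dir / f"{scenario.name}_potential.csv"
        series.to_frame().to_csv(path, index=False)
        manifest["outputs"].append(path.name)
        mean48, sd48 = series.at(min(scenario.T, 48.0))
        manifest["D_readout"] = {"mean": mean48, "sd": sd48}

    manifest_path = out_dir / f"{scenario.name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Noise-grid scan of the differentiation potential
# ---------------------------------------------------------------------------

def noise_grid_potential(
    params: ParameterSet,
    intrinsic_grid,
    lam_grid,
    CT: float = 10.0,
    T: float = 48.0,
    cells: int = 200,
    replicates: int = 1,
    seed: int | None = None,
    dt: float = 0.01,
    t_eval: float = 48.0,
    initial=None,
):
    """D(t_eval) over a 2-D grid of intrinsic (1/sqrt(V)) and extrinsic
    (lambda) noise strengths, CLE regime.

    Returns (D_mean, D_se) arrays of shape (len(intrinsic), len(lam)).
    """
    from .cle import CLENoiseSpec
    from .deterministic import basal_steady_state
    from .population import potential_series

    if initial is None:
        initial = basal_steady_state(params)
    intrinsic_grid = np.asarray(intrinsic_grid, dtype=float)
    lam_grid = np.asarray(lam_grid, dtype=float)
    D = np.empty((intrinsic_grid.size, lam_grid.size))
    SE = np.empty_like(D)
    master = np.random.SeedSequence(seed)
    cell_seeds = master.spawn(D.size)
    k = 0
    for i, s_int in enumerate(intrinsic_grid):
        for j, lam in enumerate(lam_grid):
            spec = CLENoiseSpec.from_strengths(s_int, lam, dt=dt)
            series = potential_series(
                "cle",
                params,
                CT,
                spec,
                T,
                cells_per_replicate=cells,
                replicates=replicates,
                seed=int(cell_seeds[k].generate_state(1)[0] % (2**31 - 1)),
                initial=initial,
            )
            mean, sd = series.at(t_eval)
            D[i, j] = mean
            SE[i, j] = sd / np.sqrt(max(series.replicates, 1))
            k += 1
    return D, SE


PRESETS = (
    "fig_dose_response",
    "fig_sensitivity",
    "fig_anm_grid",
    "fig_cle",
    "fig_noise_grid",
)


def run_preset(
    name: str,
    out_dir,
    seed: int = 0,
    params: ParameterSet | None = None,
) -> dict:
    """Run one of the package's standard experiments at desk scale.

    ``fig_dose_response``: 48-h cyclin D1 / GFAP dose sweeps with EC
    quantiles and apparent Hill coefficients.  ``fig_sensitivity``:
    GFAP sensitivity ranking (+5% perturbations).  ``fig_anm_grid``:
    additive-noise ensembles over sigma in {0.1, 1, 5, 10}% with D(t)
    replicates.  ``fig_cle``: CLE ensembles at the control and raised
    intrinsic/extrinsic settings.  ``fig_noise_grid``: D(48 h) on a 2-D
    intrinsic x extrinsic grid (1e-3..1e-1), wild-type vs K6a x10.
    """
    from .deterministic import (
        apparent_hill,
        basal_steady_state,
        dose_response,
        ec_quantile,
        sensitivity_ranking,
    )
    from .population import potential_series

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pset = params or default_parameters()
    initial = basal_steady_state(pset)
    manifest: dict = {"preset": name, "seed": seed, "outputs": [], "summary": {}}

    def save(df: pd.DataFrame, fname: str):
        path = out_dir / fname
        df.to_csv(path, index=False)
        manifest["outputs"].append(fname)

    if name == "fig_dose_response":
        doses = np.unique(
            np.concatenate([np.linspace(0, 10, 21), np.linspace(5.5, 7.5, 41)])
        )
        for species in ("CyclinD1", "GFAP"):
            curve = dose_response(pset, doses, species, 48.0, initial=initial)
            save(curve.to_frame(), f"dose_response_{species}.csv")
            manifest["summary"][species] = {
                "EC10": ec_quantile(curve, 0.1),
                "EC90": ec_quantile(curve, 0.9),
                "apparent_hill": apparent_hill(curve),
            }
    elif name == "fig_sensitivity":
        table = sensitivity_ranking(pset)
        save(table.table, "sensitivity_ranking.csv")
        manifest["summary"]["top"] = table.top(5)
    elif name == "fig_anm_grid":
        from .anm import ANMNoiseSpec

        for pct in (0.1, 1.0, 5.0, 10.0):
            series = potential_series(
                "anm", pset, 10.0, ANMNoiseSpec(percent=pct), 48.0,
                cells_per_replicate=100, replicates=20, seed=seed,
                initial=initial,
            )
            save(series.to_frame(), f"potential_anm_{pct}pct.csv")
            mean, sd = series.at(48.0)
            manifest["summary"][f"D48_at_{pct}pct"] = {"mean": mean, "sd": sd}
    elif name == "fig_cle":
        from .cle import CLENoiseSpec

        cases = {
            "control": (0.001, 0.001),
            "intrinsic_up": (0.01, 0.001),
            "extrinsic_up": (0.001, 0.01),
        }
        for label, (s_int, lam) in cases.items():
            series = potential_series(
                "cle", pset, 10.0,
                CLENoiseSpec.from_strengths(s_int, lam), 48.0,
                cells_per_replicate=100, replicates=10, seed=seed,
                initial=initial,
            )
            save(series.to_frame(), f"potential_cle_{label}.csv")
            mean, sd = series.at(48.0)
            manifest["summary"][f"D48_{label}"] = {"mean": mean, "sd": sd}
    elif name == "fig_noise_grid":
        grid = np.logspace(-3, -1, 4)
        surfaces = {}
        for label, p_run in {
            "wild_type": pset,
            "K6a_x10": apply_intervention(pset, "K6a_fold", 10.0),
        }.items():
            D, SE = noise_grid_potential(
                p_run, grid, grid, cells=100, replicates=3, seed=seed,
                initial=basal_steady_state(p_run),
            )
            df = pd.DataFrame(D, index=grid, columns=grid)
            df.index.name = "intrinsic_1_over_sqrtV"
            path = out_dir / f"noise_grid_{label}.csv"
            df.to_csv(path)
            manifest["outputs"].append(path.name)
            surfaces[label] = D
        manifest["summary"]["min_margin"] = float(
            np.min(surfaces["K6a_x10"] - surfaces["wild_type"])
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")

    (out_dir / f"{name}_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float)
    )
    return manifest
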