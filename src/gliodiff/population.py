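"""Population-level statistics of simulated cell ensembles.

The headline quantity is the differentiation potential

    D(t) = integral of u(x) p_GFAP(x, t) dx,

the fraction of cells whose GFAP level exceeds the differentiation
threshold x_c (0.8 by default), with u a Heaviside indicator.  For an
empirical ensemble the indicator mean is the exact value of the
integral under the empirical measure, so D never goes through a density
estimate; histograms are provided for display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Ensemble, ParameterSet, SPECIES

__all__ = [
    "DifferentiationConfig",
    "differentiation_potential",
    "PotentialSeries",
    "potential_series",
    "gfap_distribution",
    "ensemble_stats",
]


@dataclass(frozen=True)
class DifferentiationConfig:
    """Threshold defining a differentiated cell: GFAP > x_c (strict)."""

    x_c: float = 0.8

    def __post_init__(self):
        if self.x_c <= 0:
            raise ValueError("x_c must be positive")


def differentiation_potential(
    ensemble: Ensemble,
    t: float,
    config: DifferentiationConfig = DifferentiationConfig(),
) -> float:
    """Fraction of cells with GFAP above x_c at time t (on the grid)."""
    if ensemble.n_traj == 0:
        raise ValueError("empty ensemble")
    idx = ensemble.time_index(t)
    gfap = ensemble.species("GFAP")[:, idx]
    return float(np.mean(gfap > config.x_c))


def potential_curve(
    ensemble: Ensemble,
    config: DifferentiationConfig = DifferentiationConfig(),
) -> np.ndarray:
    """D(t) on the full ensemble grid."""
    return np.mean(ensemble.species("GFAP") > config.x_c, axis=0)


@dataclass
class PotentialSeries:
    """Replicated time courses of the differentiation potential.

    ``curves`` has shape (replicates, len(t)); mean and sd are across
    replicates, emulating repeated finite-population experiments.
    """

    t: np.ndarray
    curves: np.ndarray
    config: DifferentiationConfig = field(default_factory=DifferentiationConfig)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape[1] != self.t.size:
            raise ValueError("curves and grid length mismatch")
        if np.any(self.curves < 0) or np.any(self.curves > 1):
            raise ValueError("differentiation potential must lie in [0, 1]")

    @property
    def replicates(self) -> int:
        return self.curves.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        if self.replicates < 2:
            return np.zeros_like(self.t)
        return self.curves.std(axis=0, ddof=1)

    def at(self, time: float) -> tuple[float, float]:
        idx = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[idx] - time) > 1e-6 * max(1.0, abs(time)) + 1e-9:
            raise ValueError(f"time {time} not on grid")
        return float(self.mean[idx]), float(self.sd[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.curves.T,
            columns=[f"replicate_{i}" for i in range(self.replicates)],
        )
        df.insert(0, "time", self.t)
        df["mean"] = self.mean
        df["sd"] = self.sd
        return df


def potential_series(
    regime: str,
    params: ParameterSet,
    CT: float,
    noise,
    T: float,
    cells_per_replicate: int = 100,
    replicates: int = 20,
    seed: int | None = None,
    initial=None,
    config: DifferentiationConfig = DifferentiationConfig(),
    save_every: int = 10,
) -> PotentialSeries:
    """Replicated stochastic evolution of the differentiation potential.

    Each replicate simulates an independent finite ensemble of cells
    (ANM or CLE regime, per ``noise``) and evaluates D(t) on the shared
    grid; replicate seeds are spawned from ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from dataclasses import replace as _replace

    if initial is None:
        from .deterministic import basal_steady_state

        initial = basal_steady_state(params)

    if regime == "anm":
        from .anm import simulate_anm_ensemble as simulate
    elif regime == "cle":
        from .cle import simulate_cle_ensemble as simulate
    else:
        raise ValueError("regime must be 'anm' or 'cle'")

    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(replicates)
    ]
    curves = []
    t = None
    for rep_seed in rep_seeds:
        ens = simulate(
            params,
            initial,
            CT,
            _replace(noise, seed=rep_seed),
            T,
            n_traj=cells_per_replicate,
            save_every=save_every,
        )
        curves.append(potential_curve(ens, config))
        t = ens.t
    return PotentialSeries(t=t, curves=np.array(curves), config=config)


def gfap_distribution(
    ensemble: Ensemble, t: float, bins: int = 20, range_=None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram (masses sum to 1) of GFAP levels at time t."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    idx = ensemble.time_index(t)
    values = ensemble.species("GFAP")[:, idx]
    counts, edges = np.histogram(values, bins=bins, range=range_)
    return counts / counts.sum(), edges


def ensemble_stats(ensemble: Ensemble) -> pd.DataFrame:
    """Per-species mean, sd and CV over time (long format).

    CV = sd/mean is NaN wherever the mean is zero.
    """
    records = []
    for name in SPECIES:
        values = ensemble.species(name)
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=1) if ensemble.n_traj > 1 else np.zeros_like(mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
        records.append(
            pd.DataFrame(
                {"time": ensemble.t, "species": name, "mean": mean, "sd": sd, "cv": cv}
            )
        )
    return pd.concat(records, ignore_index=True)
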