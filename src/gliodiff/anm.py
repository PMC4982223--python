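"""Additive-noise model (ANM): dY = F(t, Y) dt + sigma dW.

The simplest way to put molecular fluctuations into the signaling
model: each species receives an independent Wiener increment with a
state-independent amplitude sigma_k.  Noise intensity is quoted as a
percentage p of signal variation, sigma_k = (p/100) * scale_k, with a
per-species reference scale of 1 (the normalized species range) unless
overridden.  Integration is Euler-Maruyama with full truncation:
negative excursions are clamped to zero after every step and the
clamp events counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _em
from .model import (
    N_SPECIES,
    Ensemble,
    ParameterSet,
    Trajectory,
    degradation_rates,
    production_rates,
    validate_state,
)

__all__ = [
    "ANMNoiseSpec",
    "wiener_increment",
    "sigma_from_percent",
    "simulate_anm",
    "simulate_anm_ensemble",
]


def wiener_increment(rng: np.random.Generator, dt: float, size=None):
    """Wiener increment(s) over a step dt: sqrt(dt) * N(0, 1)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.sqrt(dt) * rng.standard_normal(size)


def sigma_from_percent(p: float, reference_scales=None) -> np.ndarray:
    """Per-species noise amplitudes from a percent intensity.

    sigma_k = (p/100) * scale_k; the default reference scale 1.0 is the
    normalized species range.  Pass e.g. the deterministic maxima under
    treatment to scale noise per species instead.
    """
    if p < 0:
        raise ValueError("noise percent must be >= 0")
    scales = (
        np.ones(N_SPECIES)
        if reference_scales is None
        else np.asarray(reference_scales, dtype=float)
    )
    if scales.shape != (N_SPECIES,):
        raise ValueError(f"reference scales must have shape ({N_SPECIES},)")
    if np.any(scales < 0):
        raise ValueError("reference scales must be >= 0")
    return (p / 100.0) * scales


@dataclass
class ANMNoiseSpec:
    """Additive-noise regime: percent intensity, step size, seed."""

    percent: float = 5.0
    dt: float = 0.01
    seed: int | None = None
    reference_scales: np.ndarray | None = None

    def __post_init__(self):
        if self.percent < 0:
            raise ValueError("noise percent must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def sigmas(self) -> np.ndarray:
        return sigma_from_percent(self.percent, self.reference_scales)


def _run_anm_batch(params, y0, CT, noise, T, save_every):
    """Vectorized full-truncation Euler-Maruyama for a batch of cells."""
    dt = noise.dt
    n_traj = y0.shape[0]
    sigma = noise.sigmas()
    sqdt = np.sqrt(dt)
    n_steps, saved_idx, t_saved = _em.time_grid(T, dt, save_every)
    rngs, traj_seeds = _em.spawn_trajectory_rngs(noise.seed, n_traj)

    out = np.empty((n_traj, t_saved.size, N_SPECIES))
    out[:, 0] = y0
    y = y0.copy()
    clamp_count = 0
    save_pos = 1
    GT = params.GSK3bT

    step = 0
    while step < n_steps:
        chunk = min(_em.CHUNK_STEPS, n_steps - step)
        xi = _em.draw_chunk(rngs, chunk, N_SPECIES)
        for k in range(chunk):
            F = production_rates(y, CT, params) - degradation_rates(y, CT, params)
            y = y + F * dt + sigma * sqdt * xi[:, k]
            neg = y < 0
            over = y[:, 4] > GT
            clamp_count += int(neg.sum()) + int(over.sum())
            np.clip(y, 0.0, None, out=y)
            y[:, 4] = np.minimum(y[:, 4], GT)
            step += 1
            if save_pos < saved_idx.size and step == saved_idx[save_pos]:
                out[:, save_pos] = y
                save_pos += 1
        if not np.all(np.isfinite(y)):
            raise _em.StepSizeError(
                f"non-finite state at t={step * dt:.3f} h; reduce dt"
            )
    return t_saved, out, traj_seeds, clamp_count


def simulate_anm(
    params: ParameterSet,
    initial,
    CT: float,
    noise: ANMNoiseSpec,
    T: float,
    grid=None,
    save_every: int = 10,
) -> Trajectory:
    """Single-cell additive-noise simulation over [0, T] hours.

    With ``grid`` given, states are linearly interpolated from the saved
    step grid onto it.
    """
    y0 = validate_state(initial, params)[None, :]
    t, out, seeds, _ = _run_anm_batch(params, y0, CT, noise, T, save_every)
    states = out[0]
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        states = np.column_stack(
            [np.interp(grid, t, states[:, j]) for j in range(N_SPECIES)]
        )
        t = grid
    return Trajectory(
        t=t, states=states, CT=CT, regime="anm", seed=noise.seed, dt=noise.dt
    )


def simulate_anm_ensemble(
    params: ParameterSet,
    initial,
    CT: float,
    noise: ANMNoiseSpec,
    T: float,
    n_traj: int = 200,
    save_every: int = 10,
) -> Ensemble:
    """Ensemble of independent single-cell ANM simulations.

    Each cell owns a random stream spawned from ``noise.seed``, so the
    ensemble is reproducible and individual cells are independent.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    y0 = np.broadcast_to(
        validate_state(initial, params), (n_traj, N_SPECIES)
    ).copy()
    t, out, seeds, clamps = _run_anm_batch(params, y0, CT, noise, T, save_every)
    return Ensemble(
        t=t,
        states=out,
        CT=CT,
        regime="anm",
        master_seed=noise.seed,
        trajectory_seeds=seeds,
        noise_spec=noise,
        clamp_count=clamps,
    )
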