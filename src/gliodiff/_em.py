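"""Shared Euler-Maruyama plumbing for the stochastic engines.

Trajectories are vectorized across the ensemble, but every trajectory
owns an independent, reproducible random stream: per-trajectory seeds
are spawned from the master seed, and Gaussian increments are drawn
per-stream in time chunks so that the simulated law of any single cell
does not depend on how many cells were simulated alongside it.
"""

from __future__ import annotations

import numpy as np

CHUNK_STEPS = 400


class StepSizeError(RuntimeError):
    """Raised when the explicit scheme produced a non-finite state."""


def spawn_trajectory_rngs(master_seed, n_traj):
    """Independent generators and their seeds, derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_traj)
    rngs = [np.random.default_rng(c) for c in children]
    seeds = [int(c.generate_state(1)[0]) for c in children]
    return rngs, seeds


def draw_chunk(rngs, n_steps: int, width: int) -> np.ndarray:
    """Standard-normal block of shape (n_traj, n_steps, width)."""
    return np.stack([rng.standard_normal((n_steps, width)) for rng in rngs])


def time_grid(T: float, dt: float, save_every: int):
    """Number of steps and the saved time grid for horizon T at step dt."""
    n_steps = int(round(T / dt))
    if n_steps < 1:
        raise ValueError("T must exceed dt")
    saved = np.arange(0, n_steps + 1, save_every)
    if saved[-1] != n_steps:
        saved = np.append(saved, n_steps)
    return n_steps, saved, saved * dt
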