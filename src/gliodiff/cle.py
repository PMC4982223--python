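"""Chemical Langevin Equation (CLE) model with intrinsic and extrinsic noise.

Each species equation is split into its production and degradation
channels; the Langevin noise adds, per channel, a term

    (1/sqrt(V)) * sqrt(channel rate) * zeta(t)

with independent Gaussian white noise zeta for each of the 20 channels,
V being the total number of molecules per protein pool, so that the
intrinsic noise strength is 1/sqrt(V).  Extrinsic variability rescales
every kinetic parameter as P_j * (1 + lambda * eps), eps ~ N(0, 1)
independently for each of the 39 parameters, drawn once per trajectory (static mode, the default: persistent
cell-to-cell variability) or redrawn at every step (white mode; note
that a per-step redraw contributes only O(lambda*sqrt(dt)) to the
integrated dynamics and so has vanishing effect as dt -> 0).

Integration is full-truncation Euler-Maruyama: channel rates are
clamped at zero inside the square roots and species at zero after each
step, with clamp events counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np

from . import _em
from .model import (
    N_PARAMS,
    N_SPECIES,
    PARAM_NAMES,
    Ensemble,
    ParameterSet,
    Trajectory,
    degradation_rates,
    production_rates,
    validate_state,
)

__all__ = [
    "CLENoiseSpec",
    "reaction_channels",
    "perturb_extrinsic",
    "simulate_cle",
    "simulate_cle_ensemble",
]

_HILL_IDX = [PARAM_NAMES.index(n) for n in ("n1", "n2", "n3")]
# pool sizes/ceilings must stay strictly positive (C divides the gate)
_POSITIVE_IDX = [PARAM_NAMES.index(n) for n in ("GSK3bT", "C")]
_POSITIVE_FLOOR = 1e-9


@dataclass
class CLENoiseSpec:
    """Intrinsic/extrinsic noise regime for the CLE engine.

    ``V`` is the molecule count per protein pool (intrinsic strength
    1/sqrt(V)); ``lam`` the extrinsic strength; ``extrinsic_mode``
    either ``"static"`` (one draw per trajectory, the default) or
    ``"white"`` (parameters redrawn every step).  ``verbatim_gfap_noise`` reproduces, for
    comparison, a variant GFAP degradation noise proportional to
    d10*[GFAP] instead of its square root.
    """

    V: float = 1e6
    lam: float = 0.001
    extrinsic_mode: str = "static"
    dt: float = 0.01
    seed: int | None = None
    verbatim_gfap_noise: bool = False

    def __post_init__(self):
        if self.V <= 0:
            raise ValueError("system size V must be > 0")
        if self.lam < 0:
            raise ValueError("extrinsic strength lambda must be >= 0")
        if self.extrinsic_mode not in ("white", "static"):
            raise ValueError("extrinsic_mode must be 'white' or 'static'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def from_strengths(
        cls, intrinsic: float, lam: float, **kwargs
    ) -> "CLENoiseSpec":
        """Build a spec from the intrinsic strength 1/sqrt(V) directly."""
        if intrinsic <= 0:
            raise ValueError("intrinsic strength must be > 0")
        return cls(V=intrinsic**-2, lam=lam, **kwargs)

    @property
    def intrinsic_strength(self) -> float:
        return 1.0 / np.sqrt(self.V)


def reaction_channels(state, CT, params):
    """Production and degradation channel rates, shape (..., 10) each.

    production - degradation reproduces the deterministic drift exactly;
    numerically negative rates are clamped to zero (and counted via the
    returned clamp count) before they reach the Langevin square roots.
    """
    prod = production_rates(state, CT, params)
    deg = degradation_rates(state, CT, params)
    clamped = int(np.sum(prod < 0)) + int(np.sum(deg < 0))
    return np.clip(prod, 0.0, None), np.clip(deg, 0.0, None), clamped


def _perturbed_view(base: np.ndarray, lam: float, eps: np.ndarray):
    """Parameter view with every entry multiplied by (1 + lam*eps).

    ``base`` is the (39,) nominal vector, ``eps`` an (n_traj, 39) draw.
    Rates are clamped at 0 and Hill exponents at 1 to stay inside the
    model domain; returns (view, clamp count).
    """
    values = base * (1.0 + lam * eps)
    clamps = int(np.sum(values < 0))
    np.clip(values, 0.0, None, out=values)
    for j in _HILL_IDX:
        clamps += int(np.sum(values[..., j] < 1))
        values[..., j] = np.maximum(values[..., j], 1.0)
    for j in _POSITIVE_IDX:
        values[..., j] = np.maximum(values[..., j], _POSITIVE_FLOOR)
    view = SimpleNamespace(
        **{name: values[..., j] for j, name in enumerate(PARAM_NAMES)}
    )
    return view, clamps


def perturb_extrinsic(
    params: ParameterSet,
    lam: float,
    rng: np.random.Generator,
    mode: str = "static",
) -> ParameterSet:
    """One extrinsic draw: every parameter scaled by (1 + lam*eps).

    ``mode`` is documentation of intent only — a single call always
    produces one draw; the white/static distinction lives in the
    simulation loop, which calls this per step or per trajectory.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if mode not in ("white", "static"):
        raise ValueError("mode must be 'white' or 'static'")
    eps = rng.standard_normal(N_PARAMS)
    view, _ = _perturbed_view(params.as_array(), lam, eps)
    return ParameterSet(**{n: float(getattr(view, n)) for n in PARAM_NAMES})


def _run_cle_batch(params, y0, CT, noise, T, save_every):
    dt = noise.dt
    n_traj = y0.shape[0]
    sq_dt = np.sqrt(dt)
    inv_sqV = 1.0 / np.sqrt(noise.V)
    n_steps, saved_idx, t_saved = _em.time_grid(T, dt, save_every)
    rngs, traj_seeds = _em.spawn_trajectory_rngs(noise.seed, n_traj)
    base = params.as_array()

    white = noise.extrinsic_mode == "white" and noise.lam > 0
    width = 2 * N_SPECIES + (N_PARAMS if white else 0)

    clamp_count = 0
    if noise.lam > 0 and not white:
        eps = np.stack([rng.standard_normal(N_PARAMS) for rng in rngs])
        pview, c = _perturbed_view(base, noise.lam, eps)
        clamp_count += c
    else:
        pview = SimpleNamespace(**dict(zip(PARAM_NAMES, base)))

    out = np.empty((n_traj, t_saved.size, N_SPECIES))
    out[:, 0] = y0
    y = y0.copy()
    save_pos = 1
    GT_nominal = params.GSK3bT

    step = 0
    while step < n_steps:
        chunk = min(_em.CHUNK_STEPS, n_steps - step)
        xi = _em.draw_chunk(rngs, chunk, width)
        for k in range(chunk):
            if white:
                pview, c = _perturbed_view(
                    base, noise.lam, xi[:, k, 2 * N_SPECIES :]
                )
                clamp_count += c
            prod, deg, c = reaction_channels(y, CT, pview)
            clamp_count += c
            z1 = xi[:, k, :N_SPECIES]
            z2 = xi[:, k, N_SPECIES : 2 * N_SPECIES]
            deg_noise = np.sqrt(deg)
            if noise.verbatim_gfap_noise:
                deg_noise = deg_noise.copy()
                deg_noise[..., 9] = deg[..., 9]
            y = (
                y
                + (prod - deg) * dt
                + inv_sqV * (np.sqrt(prod) * z1 - deg_noise * z2) * sq_dt
            )
            neg = y < 0
            clamp_count += int(neg.sum())
            np.clip(y, 0.0, None, out=y)
            # keep the phosphorylated pool inside the (possibly perturbed) total
            GT = np.asarray(getattr(pview, "GSK3bT", GT_nominal))
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


def simulate_cle(
    params: ParameterSet,
    initial,
    CT: float,
    noise: CLENoiseSpec,
    T: float,
    grid=None,
    save_every: int = 10,
) -> Trajectory:
    """Single-cell CLE simulation over [0, T] hours."""
    y0 = validate_state(initial, params)[None, :]
    t, out, seeds, _ = _run_cle_batch(params, y0, CT, noise, T, save_every)
    states = out[0]
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        states = np.column_stack(
            [np.interp(grid, t, states[:, j]) for j in range(N_SPECIES)]
        )
        t = grid
    return Trajectory(
        t=t, states=states, CT=CT, regime="cle", seed=noise.seed, dt=noise.dt
    )


def simulate_cle_ensemble(
    params: ParameterSet,
    initial,
    CT: float,
    noise: CLENoiseSpec,
    T: float,
    n_traj: int = 200,
    save_every: int = 10,
) -> Ensemble:
    """Ensemble of independent single-cell CLE simulations."""
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    y0 = np.broadcast_to(
        validate_state(initial, params), (n_traj, N_SPECIES)
    ).copy()
    t, out, seeds, clamps = _run_cle_batch(params, y0, CT, noise, T, save_every)
    return Ensemble(
        t=t,
        states=out,
        CT=CT,
        regime="cle",
        master_seed=noise.seed,
        trajectory_seeds=seeds,
        noise_spec=noise,
        clamp_count=clamps,
    )
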