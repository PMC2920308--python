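"""Chemical-Langevin (SDE) treatment of the minimal network.

Each reaction channel with mass-action rate ``r`` contributes drift ``-r`` to
its consumed (inactive) species and an independent Gaussian noise of
amplitude ``sqrt(r)`` — the diffusion approximation of the chemical master
equation, interpreted in the Ito sense.  The notable feature of this noise is
that its *relative* size on a channel, ``sqrt(r)/r = 1/sqrt(r)``, is set by
the rate and not by the copy number: a slow rate constant keeps fluctuations
order-one even with many molecules.

Three solvers live here:

* :func:`euler_maruyama_simulate` / :func:`euler_maruyama_ensemble` — explicit
  Euler-Maruyama integration of the full four-channel system, with reflecting
  clamps onto [0, total] after every step;
* :func:`one_step_analytic_path` — the one-step channel solved through the
  square-root change of variable u = sqrt(x), which linearizes the SDE to an
  Ornstein-Uhlenbeck equation integrated exactly on the grid (the O(1/x) Ito
  correction from the change of variable is dropped; the Euler-Maruyama
  integrator is the cross-check for that approximation);
* :func:`mean_field_solution` — the deterministic (zero-noise) activation
  curve of the pure type A network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkParameters

__all__ = [
    "ContinuousState",
    "IntegratorConfig",
    "ContinuousTrajectory",
    "drift_diffusion",
    "euler_maruyama_simulate",
    "euler_maruyama_ensemble",
    "one_step_analytic_path",
    "one_step_analytic_ensemble",
    "mean_field_solution",
    "default_dt",
]

#: Channel order shared with the SSA engine: (A, B1, B2, B3).
_N_CHANNELS = 4


@dataclass
class ContinuousState:
    """Continuum state: inactive abundances of the three species at time t.

    Active abundances are ``total - inactive`` by construction, so
    conservation is exact.
    """

    t: float
    y1: float
    y2: float
    y3: float


@dataclass
class IntegratorConfig:
    """Euler-Maruyama settings.

    ``dt`` must be well below the fastest deterministic timescale; Gaussian
    increments have variance ``dt`` per channel (independent channels).
    ``noise=False`` switches the integrator into its deterministic (mean-field)
    limit.  ``record_stride`` subsamples the output grid: state is stored
    every ``record_stride``-th step.
    """

    dt: float
    t_max: float
    seed: int = 0
    noise: bool = True
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def warn_if_coarse(self, params: NetworkParameters) -> str | None:
        """Return a warning string when dt is not small against the fastest
        deterministic timescale (rate constant x largest possible pair
        product), else None."""
        x0 = params.x0 or 0.0
        fastest = max(
            params.k_a * x0,
            params.k_b1 * x0,
            params.k_b2 * params.x1_total,
            params.k_b3 * params.x2_total,
        )
        if fastest > 0 and self.dt > 0.1 / fastest:
            return (
                f"dt = {self.dt:g} is coarse against the fastest timescale "
                f"1/{fastest:g}; expect discretization bias"
            )
        return None


def default_dt(params: NetworkParameters) -> float:
    """Default step size: 0.01 / (k_b3 * largest total) — well below the
    fastest per-molecule hazard the final fast step can reach."""
    m = max(params.x1_total, params.x2_total, params.x3_total, 1)
    fastest = params.k_b3 * m
    if fastest <= 0:
        x0 = params.x0 or 1.0
        fastest = max(params.k_a * x0, params.k_b1 * x0, 1.0)
    return 0.01 / fastest


@dataclass
class ContinuousTrajectory:
    """A chemical-Langevin path on a uniform grid.

    ``inactive`` has shape (n_records, 3) with columns (y1, y2, y3);
    ``active`` is ``totals - inactive``.
    """

    seed: int
    times: np.ndarray
    inactive: np.ndarray
    totals: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def active(self) -> np.ndarray:
        return self.totals[None, :] - self.inactive

    @property
    def x3a(self) -> np.ndarray:
        return self.active[:, 2]


def _rates(
    y1: np.ndarray, y2: np.ndarray, y3: np.ndarray, params: NetworkParameters
) -> np.ndarray:
    """Per-channel mass-action rates (A, B1, B2, B3), clamped at >= 0.

    Active abundances are reconstructed as total - inactive.
    """
    x0 = params.x0
    if x0 is None:
        raise ValueError("x0 must be set")
    y1c = np.clip(y1, 0.0, params.x1_total)
    y2c = np.clip(y2, 0.0, params.x2_total)
    y3c = np.clip(y3, 0.0, params.x3_total)
    return np.array(
        [
            params.k_a * x0 * y3c,
            params.k_b1 * x0 * y1c,
            params.k_b2 * (params.x1_total - y1c) * y2c,
            params.k_b3 * (params.x2_total - y2c) * y3c,
        ]
    )


def drift_diffusion(
    state: ContinuousState, params: NetworkParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Drift vector and per-channel diffusion amplitudes over (y1, y2, y3).

    Returns ``(drift, diffusion)`` where ``drift`` has shape (3,) and
    ``diffusion`` shape (3, 4): entry [i, c] is the noise amplitude sqrt(r_c)
    channel c contributes to species i (channels carry independent Brownian
    motions; y3 receives both the A and B3 contributions).
    """
    r = _rates(
        np.asarray(state.y1), np.asarray(state.y2), np.asarray(state.y3), params
    ).ravel()
    drift = np.array([-r[1], -r[2], -(r[0] + r[3])])
    diffusion = np.zeros((3, _N_CHANNELS))
    s = np.sqrt(r)
    diffusion[0, 1] = s[1]  # B1 consumes y1
    diffusion[1, 2] = s[2]  # B2 consumes y2
    diffusion[2, 0] = s[0]  # A consumes y3
    diffusion[2, 3] = s[3]  # B3 consumes y3
    return drift, diffusion


def euler_maruyama_ensemble(
    params: NetworkParameters,
    config: IntegratorConfig,
    n_paths: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``n_paths`` independent Euler-Maruyama paths.

    Returns ``(times, inactive)`` with ``inactive`` of shape
    (n_paths, n_records, 3).  Each step applies drift ``-r*dt`` and, per
    channel, an independent Gaussian increment of standard deviation
    ``sqrt(r*dt)``; states are clamped back onto [0, total] after every step
    (reflecting boundary).  Fixed seed => identical paths.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.t_max / config.dt))
    rec_idx = np.arange(0, n_steps + 1, config.record_stride)
    if rec_idx[-1] != n_steps:
        rec_idx = np.append(rec_idx, n_steps)
    times = rec_idx * config.dt
    totals = np.array(
        [params.x1_total, params.x2_total, params.x3_total], dtype=float
    )
    y = np.tile(totals, (n_paths, 1))  # everything starts inactive
    out = np.empty((n_paths, rec_idx.size, 3))
    out[:, 0] = y
    dt = config.dt
    sqrt_dt = math.sqrt(dt)
    next_rec = 1
    for step in range(1, n_steps + 1):
        r = _rates(y[:, 0], y[:, 1], y[:, 2], params)  # (4, n_paths)
        y[:, 0] -= r[1] * dt
        y[:, 1] -= r[2] * dt
        y[:, 2] -= (r[0] + r[3]) * dt
        if config.noise:
            dw = rng.standard_normal((4, n_paths)) * sqrt_dt
            amp = np.sqrt(r)
            y[:, 0] -= amp[1] * dw[1]
            y[:, 1] -= amp[2] * dw[2]
            y[:, 2] -= amp[0] * dw[0] + amp[3] * dw[3]
        np.clip(y, 0.0, totals[None, :], out=y)
        if next_rec < rec_idx.size and step == rec_idx[next_rec]:
            out[:, next_rec] = y
            next_rec += 1
    return times, out


def euler_maruyama_simulate(
    params: NetworkParameters, config: IntegratorConfig
) -> ContinuousTrajectory:
    """Integrate a single chemical-Langevin path (see
    :func:`euler_maruyama_ensemble`)."""
    times, paths = euler_maruyama_ensemble(params, config, n_paths=1)
    totals = np.array(
        [params.x1_total, params.x2_total, params.x3_total], dtype=float
    )
    return ContinuousTrajectory(
        seed=config.seed, times=times, inactive=paths[0], totals=totals
    )


def one_step_analytic_ensemble(
    k: float,
    x0: float,
    x_init: float,
    t_grid: np.ndarray,
    n_paths: int,
    seed: int,
    noise: bool = True,
) -> np.ndarray:
    """Exact-in-distribution paths of the one-step Langevin equation.

    The one-step SDE dx = -k_eff x dt + sqrt(k_eff x) dW (k_eff = k*x0)
    linearizes under u = sqrt(x) to du = -(k_eff/2) u dt + (sqrt(k_eff)/2) dW
    (dropping the O(1/u) Ito correction).  That Ornstein-Uhlenbeck equation is
    integrated exactly between grid points: over a step of length D,

        u' = u * exp(-k_eff D / 2) + eta,   eta ~ N(0, (1 - exp(-k_eff D))/4),

    the variance being the exact covariance of the stochastic convolution.
    Returns inactive abundance x = u**2 clamped onto [0, x_init], shape
    (n_paths, len(t_grid)).
    """
    if x_init <= 0:
        raise ValueError("x_init must be positive")
    grid = np.asarray(t_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D grid")
    if grid[0] < 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    k_eff = k * x0
    rng = np.random.default_rng(seed)
    u = np.full(n_paths, math.sqrt(x_init))
    out = np.empty((n_paths, grid.size))
    t_prev = 0.0
    for j, t in enumerate(grid):
        delta = t - t_prev
        if delta > 0:
            decay = math.exp(-0.5 * k_eff * delta)
            u *= decay
            if noise and k_eff > 0:
                sd = math.sqrt(-math.expm1(-k_eff * delta)) / 2.0
                u += rng.standard_normal(n_paths) * sd
        out[:, j] = u * u
        t_prev = t
    return np.clip(out, 0.0, x_init)


def one_step_analytic_path(
    k: float,
    x0: float,
    x_init: float,
    t_grid: np.ndarray,
    seed: int,
    noise: bool = True,
) -> np.ndarray:
    """One path of :func:`one_step_analytic_ensemble` (inactive abundance on
    the grid; active abundance is ``x_init`` minus the return value)."""
    return one_step_analytic_ensemble(
        k, x0, x_init, t_grid, n_paths=1, seed=seed, noise=noise
    )[0]


def mean_field_solution(
    params: NetworkParameters, t_grid: np.ndarray
) -> np.ndarray:
    """Deterministic activated-X3 curve of the pure type A network:
    ``x3a(t) = x3_total * (1 - exp(-k_a * x0 * t))``.  Type B contributions
    are ignored by construction."""
    if params.x0 is None:
        raise ValueError("x0 must be set")
    t = np.asarray(t_grid, dtype=float)
    return params.x3_total * -np.expm1(-params.k_a * params.x0 * t)
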