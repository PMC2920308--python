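"""Exact stochastic simulation (Gillespie direct method) of the minimal network.

Single cells are continuous-time Markov jump processes over integer copy
numbers; populations are collections of independent cells with seeds derived
from one master seed.  A closed-form master-equation solution for the
one-step subnetwork (:func:`one_step_exact_distribution`) serves as an exact
oracle against which the sampler is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .network import NetworkParameters, build_reaction_channels

__all__ = [
    "SystemState",
    "Trajectory",
    "Ensemble",
    "AbsorbingStateError",
    "COUNT_COLUMNS",
    "CHANNEL_NAMES",
    "initial_state",
    "propensities",
    "ssa_step",
    "simulate_cell",
    "simulate_population",
    "one_step_exact_distribution",
    "derive_cell_seed",
]

#: Fixed channel order used everywhere a propensity vector appears.
CHANNEL_NAMES = ("A", "B1", "B2", "B3")

#: Column order of the per-record count matrix in :class:`Trajectory`.
COUNT_COLUMNS = (
    "x1", "x1a", "x2", "x2a", "x3", "x3a",
    "fireA", "fireB1", "fireB2", "fireB3",
)


class AbsorbingStateError(RuntimeError):
    """Raised by :func:`ssa_step` when total propensity is zero (no channel
    can fire; every substrate reachable by an active channel is exhausted)."""


@dataclass
class SystemState:
    """Integer copy-number state of one cell, plus cumulative firing counters.

    Conservation holds by construction: ``x1 + x1a == x1_total`` (and likewise
    for species 2 and 3), and every activated molecule is accounted for by a
    counter: ``x3a == fireA + fireB3``, ``x1a == fireB1``, ``x2a == fireB2``.
    """

    t: float
    x1: int
    x1a: int
    x2: int
    x2a: int
    x3: int
    x3a: int
    fireA: int = 0
    fireB1: int = 0
    fireB2: int = 0
    fireB3: int = 0


def initial_state(params: NetworkParameters) -> SystemState:
    """All molecules inactive at t = 0 (the initial active counts are zero)."""
    return SystemState(
        t=0.0,
        x1=params.x1_total, x1a=0,
        x2=params.x2_total, x2a=0,
        x3=params.x3_total, x3a=0,
    )


@dataclass
class Trajectory:
    """Piecewise-constant sampling of one cell's jump process on a time grid.

    ``counts[i, j]`` is the value of ``COUNT_COLUMNS[j]`` at ``record_times[i]``
    — the state immediately after the last event at or before that time.
    ``engine`` distinguishes exact SSA samples from chemical-Langevin paths
    serialized through the same schema.
    """

    cell_id: int
    seed: int
    record_times: np.ndarray
    counts: np.ndarray
    engine: str = "ssa"

    def __post_init__(self) -> None:
        self.record_times = np.asarray(self.record_times, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.record_times.size, len(COUNT_COLUMNS)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({self.record_times.size}, {len(COUNT_COLUMNS)})"
            )

    def column(self, name: str) -> np.ndarray:
        return self.counts[:, COUNT_COLUMNS.index(name)]

    @property
    def x3a(self) -> np.ndarray:
        return self.column("x3a")

    @property
    def states(self) -> list[SystemState]:
        """Materialize per-record :class:`SystemState` views (small grids only)."""
        return [
            SystemState(float(t), *(int(v) for v in row))
            for t, row in zip(self.record_times, self.counts)
        ]


@dataclass
class Ensemble:
    """A population of independent single-cell trajectories sharing parameters.

    All trajectories share ``params`` and the record grid; cell ``i`` was
    simulated with ``derive_cell_seed(master_seed, i)``.
    """

    params: NetworkParameters
    master_seed: int
    trajectories: list[Trajectory] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.trajectories)

    @property
    def record_times(self) -> np.ndarray:
        return self.trajectories[0].record_times

    def count_matrix(self, name: str) -> np.ndarray:
        """Stack one count column across cells: shape (n_cells, n_records)."""
        return np.stack([tr.column(name) for tr in self.trajectories])

    def x3a_matrix(self) -> np.ndarray:
        return self.count_matrix("x3a")


def propensities(state: SystemState, params: NetworkParameters) -> np.ndarray:
    """Mass-action propensities in channel order (A, B1, B2, B3).

    a_A = k_a*x0*x3, a_B1 = k_b1*x0*x1, a_B2 = k_b2*x1a*x2, a_B3 = k_b3*x2a*x3.
    Zero counts give zero propensity; no state is an error.
    """
    x0 = params.x0
    if x0 is None:
        raise ValueError("x0 must be set to evaluate propensities")
    return np.array(
        [
            params.k_a * x0 * state.x3,
            params.k_b1 * x0 * state.x1,
            params.k_b2 * state.x1a * state.x2,
            params.k_b3 * state.x2a * state.x3,
        ],
        dtype=float,
    )


_UPDATES = {
    "A": {"x3": -1, "x3a": +1, "fireA": +1},
    "B1": {"x1": -1, "x1a": +1, "fireB1": +1},
    "B2": {"x2": -1, "x2a": +1, "fireB2": +1},
    "B3": {"x3": -1, "x3a": +1, "fireB3": +1},
}


def ssa_step(
    state: SystemState,
    params: NetworkParameters,
    rng: np.random.Generator,
) -> tuple[float, str, SystemState]:
    """One Gillespie direct-method step.

    Draws the waiting time ~ Exponential(total propensity) and the firing
    channel with probability proportional to its propensity, then applies the
    channel's update vector.

    Returns ``(waiting_time, channel_name, next_state)``.

    Raises
    ------
    AbsorbingStateError
        If the total propensity is zero.
    """
    a = propensities(state, params)
    a0 = a.sum()
    if a0 <= 0.0:
        raise AbsorbingStateError("total propensity is zero: absorbing state")
    tau = rng.exponential(1.0 / a0)
    which = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0), side="right"))
    which = min(which, 3)
    name = CHANNEL_NAMES[which]
    updates = _UPDATES[name]
    next_state = replace(
        state,
        t=state.t + tau,
        **{f: getattr(state, f) + d for f, d in updates.items()},
    )
    return tau, name, next_state


def _check_grid(record_times: Sequence[float], t_max: float) -> np.ndarray:
    grid = np.asarray(record_times, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("record_times must be a non-empty 1-D grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("record_times must be strictly increasing")
    if grid[0] < 0 or grid[-1] > t_max:
        raise ValueError("record_times must lie within [0, t_max]")
    return grid


def simulate_cell(
    params: NetworkParameters,
    t_max: float,
    record_times: Sequence[float],
    seed: int,
    cell_id: int = 0,
) -> Trajectory:
    """Simulate one cell exactly up to ``t_max``, sampled on ``record_times``.

    The recorded state at grid time tau is the state immediately after the
    last event with event time <= tau (piecewise-constant sampling).  The
    simulation stops early when every propensity is zero; the remaining grid
    points copy the absorbing state.  Identical seeds give bitwise-identical
    trajectories.
    """
    grid = _check_grid(record_times, t_max)
    # Channel construction validates parameters (raises on errors).
    channels = build_reaction_channels(params)
    k = [ch.rate_constant for ch in channels]
    x0 = float(params.x0)  # type: ignore[arg-type]  # validated above
    rng = np.random.default_rng(seed)

    # Local integer state for the hot loop.
    x1, x1a = params.x1_total, 0
    x2, x2a = params.x2_total, 0
    x3, x3a = params.x3_total, 0
    fired = [0, 0, 0, 0]
    t = 0.0

    n_rec = grid.size
    counts = np.empty((n_rec, len(COUNT_COLUMNS)), dtype=np.int64)
    next_rec = 0

    def flush(upto: float) -> None:
        # Record the current state at every grid point strictly before `upto`.
        nonlocal next_rec
        while next_rec < n_rec and grid[next_rec] < upto:
            counts[next_rec] = (x1, x1a, x2, x2a, x3, x3a, *fired)
            next_rec += 1

    exponential = rng.exponential
    uniform = rng.uniform
    while True:
        a0_parts = (k[0] * x0 * x3, k[1] * x0 * x1, k[2] * x1a * x2, k[3] * x2a * x3)
        a0 = a0_parts[0] + a0_parts[1] + a0_parts[2] + a0_parts[3]
        if a0 <= 0.0:
            break
        tau = exponential(1.0 / a0)
        t_next = t + tau
        if t_next > t_max:
            break
        flush(t_next)
        r = uniform(0.0, a0)
        if r < a0_parts[0]:
            x3 -= 1; x3a += 1; fired[0] += 1
        elif r < a0_parts[0] + a0_parts[1]:
            x1 -= 1; x1a += 1; fired[1] += 1
        elif r < a0_parts[0] + a0_parts[1] + a0_parts[2]:
            x2 -= 1; x2a += 1; fired[2] += 1
        else:
            x3 -= 1; x3a += 1; fired[3] += 1
        t = t_next
        if next_rec >= n_rec:
            break
    # Remaining grid points see the final (possibly absorbing) state.
    while next_rec < n_rec:
        counts[next_rec] = (x1, x1a, x2, x2a, x3, x3a, *fired)
        next_rec += 1
    return Trajectory(cell_id=cell_id, seed=seed, record_times=grid, counts=counts)


def derive_cell_seed(master_seed: int, cell_id: int) -> int:
    """Per-cell seed from the master seed.

    Uses numpy's seed-sequence splitting: cell ``i`` gets the first output
    word of ``SeedSequence(master_seed, spawn_key=(i,))``.  The derivation
    depends only on ``(master_seed, cell_id)``, so populations are
    reproducible and independent of simulation order.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_id,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_population(
    params: NetworkParameters,
    n_cells: int,
    t_max: float,
    record_times: Sequence[float],
    master_seed: int,
) -> Ensemble:
    """Simulate ``n_cells`` independent cells sharing parameters and grid.

    Cell ``i`` (cell_id ``0..n_cells-1``) runs with
    :func:`derive_cell_seed`(master_seed, i); the same master seed always
    reproduces the same ensemble.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    trajectories = [
        simulate_cell(
            params, t_max, record_times,
            seed=derive_cell_seed(master_seed, i), cell_id=i,
        )
        for i in range(n_cells)
    ]
    return Ensemble(params=params, master_seed=master_seed, trajectories=trajectories)


def one_step_exact_distribution(
    k: float, x0: float, n_total: int, t: float
) -> np.ndarray:
    """Exact master-equation solution for the one-step subnetwork.

    With a constant catalytic activator, each of the ``n_total`` substrate
    copies converts independently at hazard ``k * x0``, so the activated
    count at time ``t`` is Binomial(n_total, p) with ``p = 1 - exp(-k*x0*t)``.
    Returns the probability vector over activated counts ``0..n_total``
    (sums to 1).
    """
    if k < 0 or x0 < 0 or t < 0:
        raise ValueError("k, x0 and t must be nonnegative")
    p = -np.expm1(-k * x0 * t)
    return stats.binom.pmf(np.arange(n_total + 1), n_total, p)
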