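"""Population-level statistics for ensembles of single-cell trajectories.

Covers first-passage activation times, cross-cell moments and the Fano
factor, the sharp-rising (all-or-none) moment estimates, snapshot histograms
with a transparent modality classifier, attribution of X3 activation events
to the two pathways, and the (k_b2, x0) phase-diagram scan comparing the
analytic regime thresholds against simulated pathway dominance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .gillespie import Ensemble, simulate_population
from .network import (
    NetworkParameters,
    RegimeLabel,
    classify_regime_analytic,
)

__all__ = [
    "EnsembleSummary",
    "HistogramSnapshot",
    "Modality",
    "Attribution",
    "PhaseDiagram",
    "SharpRisingEstimate",
    "activation_times",
    "rise_times",
    "ensemble_moments",
    "fano_sharp_rising",
    "snapshot_distribution",
    "classify_modality",
    "channel_attribution",
    "phase_diagram_scan",
]


class Modality(Enum):
    """Shape class of a snapshot distribution of activated X3."""

    UNIMODAL_LOW = "unimodal_low"
    UNIMODAL_HIGH = "unimodal_high"
    BIMODAL = "bimodal"
    TRANSITIONAL = "transitional"


@dataclass
class EnsembleSummary:
    """Per-record-time cross-cell moments of activated X3.

    ``fano`` is variance/mean, reported as NaN exactly where the mean is zero;
    ``fraction_activated`` is the fraction of cells past half-activation
    (n/N at theta = 0.5).
    """

    record_times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray
    fraction_activated: np.ndarray


@dataclass
class HistogramSnapshot:
    """Snapshot distribution of activated X3 across cells at one time."""

    time: float
    bin_edges: np.ndarray
    probabilities: np.ndarray
    modality: Modality


@dataclass
class SharpRisingEstimate:
    """Moment estimates under the all-or-none approximation (see
    :func:`fano_sharp_rising`)."""

    mean: float
    variance: float
    fano: float


@dataclass
class Attribution:
    """Fraction of X3-activation events fired through the type A channel.

    ``pooled`` aggregates firing counters over all cells; ``per_cell`` holds
    each cell's own fraction (NaN for cells with no X3 activation events).
    """

    pooled: float
    per_cell: np.ndarray


@dataclass
class PhaseDiagram:
    """Regime labels over a (k_b2, x0) grid.

    ``analytic`` comes from the closed-form thresholds; ``empirical`` from the
    pooled channel attribution of an SSA ensemble at each grid cell
    (>= 0.9 -> TYPE_A, <= 0.1 -> TYPE_B, else MIXED).  Arrays are indexed
    [i_k_b2, j_x0].
    """

    k_b2_values: np.ndarray
    x0_values: np.ndarray
    analytic: np.ndarray
    empirical: np.ndarray
    attribution: np.ndarray


def activation_times(ensemble: Ensemble, theta: float = 0.5) -> np.ndarray:
    """Per-cell first-passage time to ``theta * x3_total`` activated X3.

    Returns, for each cell, the earliest record time at which
    ``x3a >= theta * x3_total`` (NaN when the cell never reaches it on the
    grid).  Monotone in theta by construction.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    threshold = theta * ensemble.params.x3_total
    mat = ensemble.x3a_matrix()
    hit = mat >= threshold
    first = hit.argmax(axis=1)
    times = ensemble.record_times[first].astype(float)
    times[~hit.any(axis=1)] = np.nan
    return times


def rise_times(
    ensemble: Ensemble, low: float = 0.1, high: float = 0.9
) -> np.ndarray:
    """Per-cell time spent between ``low`` and ``high`` fractional activation
    (first passage to high minus first passage to low; NaN if either is never
    reached)."""
    return activation_times(ensemble, high) - activation_times(ensemble, low)


def ensemble_moments(ensemble: Ensemble) -> EnsembleSummary:
    """Cross-cell mean, unbiased variance, Fano factor, and activated fraction
    of x3a at every record time.

    Raises
    ------
    ValueError
        For single-cell ensembles (sample variance undefined).
    """
    if ensemble.n_cells < 2:
        raise ValueError("ensemble_moments requires at least 2 cells")
    mat = ensemble.x3a_matrix().astype(float)
    mean = mat.mean(axis=0)
    variance = mat.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, variance / np.where(mean > 0, mean, 1.0), np.nan)
    fraction = (mat >= 0.5 * ensemble.params.x3_total).mean(axis=0)
    return EnsembleSummary(
        record_times=ensemble.record_times,
        mean=mean,
        variance=variance,
        fano=fano,
        fraction_activated=fraction,
    )


def fano_sharp_rising(
    n: int, N: int, x3_total: int
) -> SharpRisingEstimate:
    """Moment estimates treating each cell as fully off or fully on.

    With ``n`` of ``N`` cells activated within the observation window, the
    all-or-none (sharp-rising) approximation gives

        mean     = (n/N) * x3_total
        <X^2>    = (n/N) * x3_total**2
        variance = (n/N) * (1 - n/N) * x3_total**2
        Fano     = (1 - n/N) * x3_total     (NaN at n = 0: mean is zero)

    so the Fano factor stays far above 1 whenever a nontrivial fraction of
    cells has yet to activate, and scales linearly with ``x3_total``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= n <= N:
        raise ValueError("n must satisfy 0 <= n <= N")
    f = n / N
    mean = f * x3_total
    second = f * x3_total**2
    variance = second - mean**2
    fano = (1.0 - f) * x3_total if n > 0 else math.nan
    return SharpRisingEstimate(mean=mean, variance=variance, fano=fano)


def snapshot_distribution(
    ensemble: Ensemble, t: float, n_bins: int = 20
) -> HistogramSnapshot:
    """Histogram of activated X3 across cells at record time ``t``.

    Bins are equal-width over [0, x3_total]; probabilities are counts / N.
    ``t`` must be on the record grid.

    Raises
    ------
    ValueError
        If ``t`` is off-grid (message names the nearest grid times).
    """
    grid = ensemble.record_times
    idx = np.flatnonzero(np.isclose(grid, t, rtol=1e-12, atol=1e-12))
    if idx.size == 0:
        pos = np.searchsorted(grid, t)
        near = grid[max(pos - 1, 0): pos + 1]
        raise ValueError(
            f"time {t!r} is not on the record grid; nearest grid times: "
            f"{', '.join(f'{v:g}' for v in near)}"
        )
    values = ensemble.x3a_matrix()[:, idx[0]]
    edges = np.linspace(0.0, ensemble.params.x3_total, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    probs = counts / values.size
    snapshot = HistogramSnapshot(
        time=float(grid[idx[0]]),
        bin_edges=edges,
        probabilities=probs,
        modality=Modality.TRANSITIONAL,
    )
    snapshot.modality = classify_modality(snapshot)
    return snapshot


def classify_modality(
    snapshot: HistogramSnapshot,
    low_cut: float = 0.1,
    high_cut: float = 0.9,
    min_mass: float = 0.05,
) -> Modality:
    """Threshold-mass modality classifier for all-or-none distributions.

    With ``p_low`` the probability mass below ``low_cut`` of the maximum and
    ``p_high`` the mass above ``high_cut``:

    * bimodal        if both tails hold >= ``min_mass`` and together >= 0.8,
    * unimodal_low   if the low tail alone holds >= 0.8,
    * unimodal_high  if the high tail alone holds >= 0.8,
    * transitional   otherwise (e.g. a traveling central peak).
    """
    if not 0.0 < low_cut < high_cut < 1.0:
        raise ValueError("need 0 < low_cut < high_cut < 1")
    edges = snapshot.bin_edges
    span = edges[-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = snapshot.probabilities
    p_low = float(p[centers < low_cut * span].sum())
    p_high = float(p[centers > high_cut * span].sum())
    if p_low >= min_mass and p_high >= min_mass and p_low + p_high >= 0.8:
        return Modality.BIMODAL
    if p_low >= 0.8:
        return Modality.UNIMODAL_LOW
    if p_high >= 0.8:
        return Modality.UNIMODAL_HIGH
    return Modality.TRANSITIONAL


def channel_attribution(ensemble: Ensemble) -> Attribution:
    """Fraction of X3-activation events fired through channel A.

    Uses the cumulative firing counters at the final record time:
    pooled = sum(fireA) / sum(fireA + fireB3).  NaN when no X3 activation
    event fired anywhere (pooled) or in a given cell (per-cell).
    """
    fire_a = ensemble.count_matrix("fireA")[:, -1].astype(float)
    fire_b3 = ensemble.count_matrix("fireB3")[:, -1].astype(float)
    total = fire_a + fire_b3
    with np.errstate(divide="ignore", invalid="ignore"):
        per_cell = np.where(total > 0, fire_a / np.where(total > 0, total, 1.0), np.nan)
    pooled = float(fire_a.sum() / total.sum()) if total.sum() > 0 else math.nan
    return Attribution(pooled=pooled, per_cell=per_cell)


_EMPIRICAL_TYPE_A_CUT = 0.9
_EMPIRICAL_TYPE_B_CUT = 0.1


def _empirical_label(fraction: float) -> RegimeLabel:
    if math.isnan(fraction):
        return RegimeLabel.MIXED
    if fraction >= _EMPIRICAL_TYPE_A_CUT:
        return RegimeLabel.TYPE_A
    if fraction <= _EMPIRICAL_TYPE_B_CUT:
        return RegimeLabel.TYPE_B
    return RegimeLabel.MIXED


def _grid_seed(master_seed: int, i: int, j: int) -> int:
    # Documented splitting: grid cell (i, j) -> SeedSequence spawn key (i, j, 1).
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(i, j, 1))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def phase_diagram_scan(
    k_b2_grid: Sequence[float],
    x0_grid: Sequence[float],
    base_params: NetworkParameters,
    n_cells: int,
    t_max: float,
    master_seed: int,
    n_records: int = 2,
) -> PhaseDiagram:
    """Scan the (k_b2, x0) plane: analytic vs simulated regime labels.

    For each grid cell the analytic label comes from the closed-form
    thresholds; the empirical label from the pooled channel attribution of an
    SSA ensemble (``n_cells`` cells up to ``t_max``), with cuts 0.9 / 0.1.
    Each grid cell simulates with an independent seed derived from
    ``master_seed`` and the grid indices.
    """
    kb2 = np.asarray(k_b2_grid, dtype=float)
    x0s = np.asarray(x0_grid, dtype=float)
    if kb2.size == 0 or x0s.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(kb2) <= 0) or np.any(np.diff(x0s) <= 0):
        raise ValueError("grids must be strictly increasing")
    record_times = np.linspace(0.0, t_max, max(n_records, 2))
    shape = (kb2.size, x0s.size)
    analytic = np.empty(shape, dtype=object)
    empirical = np.empty(shape, dtype=object)
    attribution = np.full(shape, np.nan)
    from dataclasses import replace

    for i, k2 in enumerate(kb2):
        for j, x0 in enumerate(x0s):
            params = replace(base_params, k_b2=float(k2), x0=float(x0))
            analytic[i, j] = classify_regime_analytic(params).label
            ens = simulate_population(
                params, n_cells, t_max, record_times,
                master_seed=_grid_seed(master_seed, i, j),
            )
            frac = channel_attribution(ens).pooled
            attribution[i, j] = frac
            empirical[i, j] = _empirical_label(frac)
    return PhaseDiagram(
        k_b2_values=kb2,
        x0_values=x0s,
        analytic=analytic,
        empirical=empirical,
        attribution=attribution,
    )
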