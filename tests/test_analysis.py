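import dataclasses
import math

import numpy as np
import pytest

from minsig import (
    Ensemble,
    Modality,
    NetworkParameters,
    RegimeLabel,
    Trajectory,
    activation_times,
    channel_attribution,
    classify_modality,
    ensemble_moments,
    fano_sharp_rising,
    phase_diagram_scan,
    preset,
    rise_times,
    simulate_population,
    snapshot_distribution,
)
from minsig.analysis import HistogramSnapshot


def make_ensemble(x3a_by_cell, record_times, x3_total=100, fire=None):
    """Hand-built ensemble: x3a per cell on a shared grid; all x3a events are
    attributed to channel A unless explicit counters are given."""
    params = NetworkParameters(x0=1.0, x3_total=x3_total)
    trajectories = []
    for cid, x3a in enumerate(x3a_by_cell):
        x3a = np.asarray(x3a)
        counts = np.zeros((x3a.size, 10), dtype=np.int64)
        counts[:, 4] = x3_total - x3a  # x3
        counts[:, 5] = x3a
        counts[:, 0] = params.x1_total  # x1 untouched
        counts[:, 2] = params.x2_total
        if fire is None:
            counts[:, 6] = x3a  # fireA
        else:
            counts[:, 6] = fire[cid][0]
            counts[:, 9] = fire[cid][1]
        trajectories.append(
            Trajectory(cell_id=cid, seed=cid, record_times=record_times,
                       counts=counts)
        )
    return Ensemble(params=params, master_seed=0, trajectories=trajectories)


class TestActivationTimes:
    def test_zero_stimulus_never_activates(self):
        ens = simulate_population(
            preset("base").with_x0(0.0), 5, 5.0, [0.0, 5.0], master_seed=0
        )
        assert np.all(np.isnan(activation_times(ens)))

    def test_first_passage_on_grid(self):
        grid = np.array([0.0, 1.0, 2.0, 3.0])
        ens = make_ensemble([[0, 0, 60, 100], [0, 70, 100, 100]], grid)
        assert activation_times(ens, 0.5).tolist() == [2.0, 1.0]

    def test_raising_theta_never_decreases_times(self):
        grid = np.array([0.0, 1.0, 2.0, 3.0])
        ens = make_ensemble([[0, 20, 60, 100], [0, 70, 80, 100]], grid)
        t_lo = activation_times(ens, 0.2)
        t_hi = activation_times(ens, 0.9)
        assert np.all(t_hi >= t_lo)

    def test_type_a_population_activates_in_concert(self, strong_ensemble):
        times = activation_times(strong_ensemble)
        spread = np.percentile(times, 90) - np.percentile(times, 10)
        assert spread <= 0.5 * np.median(times)

    def test_type_b_all_or_none(self, deep_b_ensemble):
        # Population onset spread dwarfs each cell's own rise time once the
        # aggregate slow-step rate sits far below the fast per-molecule
        # hazard (k_b2*x1*x2 << k_b3).
        halves = activation_times(deep_b_ensemble)
        spread = np.nanpercentile(halves, 90) - np.nanpercentile(halves, 10)
        rise = np.nanmedian(rise_times(deep_b_ensemble))
        assert spread >= 10 * rise

    def test_moderate_slow_step_blurs_all_or_none(self, weak_ensemble):
        # At k_b2 = 1e-4 the aggregate slow rate (k_b2*x1*x2 = 1) matches
        # k_b3, so onset and rise share one time scale and the spread/rise
        # ratio stays small.
        halves = activation_times(weak_ensemble)
        spread = np.nanpercentile(halves, 90) - np.nanpercentile(halves, 10)
        rise = np.nanmedian(rise_times(weak_ensemble))
        assert 0.5 <= spread / rise <= 5


class TestEnsembleMoments:
    def test_identical_cells_have_zero_variance_and_fano(self):
        grid = np.array([0.0, 1.0, 2.0])
        ens = make_ensemble([[0, 50, 100]] * 4, grid)
        s = ensemble_moments(ens)
        assert np.all(s.variance == 0.0)
        assert np.isnan(s.fano[0])  # mean is zero at t = 0
        assert s.fano[1] == 0.0 and s.fano[2] == 0.0

    def test_two_cell_textbook_values(self):
        grid = np.array([0.0, 1.0])
        ens = make_ensemble([[0, 0], [0, 100]], grid)
        s = ensemble_moments(ens)
        assert s.mean[1] == 50.0
        assert s.variance[1] == 5000.0  # unbiased: (50^2 + 50^2) / (2 - 1)
        assert s.fano[1] == 100.0
        assert s.fraction_activated[1] == 0.5

    def test_single_cell_is_an_error(self):
        ens = make_ensemble([[0, 100]], np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            ensemble_moments(ens)

    def test_empirical_fano_matches_sharp_rising_at_half_activation(
        self, deep_b_ensemble
    ):
        # Where activation really is all-or-none, the sharp-rising moment
        # estimate tracks the simulated cross-cell Fano factor.
        s = ensemble_moments(deep_b_ensemble)
        idx = np.argmin(np.abs(s.fraction_activated - 0.5))
        n = round(s.fraction_activated[idx] * 100)
        expected = fano_sharp_rising(n, 100, 100).fano
        assert s.fano[idx] == pytest.approx(expected, rel=0.3)


class TestFanoSharpRising:
    def test_all_cells_activated_kills_variance(self):
        est = fano_sharp_rising(100, 100, 100)
        assert est.variance == 0.0 and est.fano == 0.0

    def test_half_activated_population(self):
        est = fano_sharp_rising(50, 100, 100)
        assert (est.mean, est.variance, est.fano) == (50.0, 2500.0, 50.0)

    def test_rare_activation_gives_fano_far_above_one(self):
        assert fano_sharp_rising(1, 100, 100).fano == pytest.approx(99.0)

    def test_no_activation_leaves_fano_undefined(self):
        assert math.isnan(fano_sharp_rising(0, 100, 100).fano)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fano_sharp_rising(101, 100, 100)

    def test_fano_scales_linearly_with_total_copy_number(self):
        # (1 - n/N) * x3_total: doubling the total doubles the estimate.
        f = [fano_sharp_rising(40, 100, x3).fano for x3 in (50, 100, 200)]
        assert f[1] == pytest.approx(2 * f[0])
        assert f[2] == pytest.approx(2 * f[1])

    def test_simulated_fano_scales_with_total_copy_number(self):
        # At matched activated fraction, the cross-cell Fano grows ~linearly
        # in x3_total (checked loosely: x4 totals -> x2..8 Fano).
        fanos = []
        for x3_total, seed in ((50, 1), (200, 2)):
            params = dataclasses.replace(preset("weak"), x3_total=x3_total)
            ens = simulate_population(
                params, 100, 10.0, np.linspace(0, 10, 101), master_seed=seed
            )
            s = ensemble_moments(ens)
            idx = np.argmin(np.abs(s.fraction_activated - 0.5))
            fanos.append(s.fano[idx])
        assert 2.0 <= fanos[1] / fanos[0] <= 8.0


class TestSnapshots:
    def test_time_zero_mass_in_lowest_bin(self, weak_ensemble):
        snap = snapshot_distribution(weak_ensemble, 0.0)
        assert snap.probabilities[0] == pytest.approx(1.0)
        assert snap.modality is Modality.UNIMODAL_LOW

    def test_probabilities_sum_to_one(self, weak_ensemble):
        snap = snapshot_distribution(weak_ensemble, 5.0)
        assert snap.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_off_grid_time_names_neighbors(self, weak_ensemble):
        with pytest.raises(ValueError, match="nearest grid times"):
            snapshot_distribution(weak_ensemble, 5.017)

    def test_type_a_completes_in_highest_bin(self, strong_ensemble):
        snap = snapshot_distribution(strong_ensemble, 3.0)
        assert snap.probabilities[-1] == pytest.approx(1.0)
        assert snap.modality is Modality.UNIMODAL_HIGH

    def test_type_b_half_activated_is_bimodal(self, deep_b_ensemble):
        s = ensemble_moments(deep_b_ensemble)
        idx = np.argmin(np.abs(s.fraction_activated - 0.5))
        snap = snapshot_distribution(deep_b_ensemble, s.record_times[idx])
        assert snap.modality is Modality.BIMODAL
        centers = 0.5 * (snap.bin_edges[:-1] + snap.bin_edges[1:])
        outer = (centers < 10) | (centers > 90)
        assert snap.probabilities[outer].sum() >= 0.8

    def test_type_b_modality_sequence_with_peak_crossing(self, deep_b_ensemble):
        labels = []
        p_low, p_high = [], []
        for t in deep_b_ensemble.record_times[::20]:
            snap = snapshot_distribution(deep_b_ensemble, t)
            labels.append(snap.modality)
            p_low.append(snap.probabilities[0:2].sum())
            p_high.append(snap.probabilities[-2:].sum())
        assert labels[0] is Modality.UNIMODAL_LOW
        assert Modality.BIMODAL in labels
        assert labels[-1] is Modality.UNIMODAL_HIGH
        # One peak grows while the other shrinks, and they cross.
        diff = np.array(p_high) - np.array(p_low)
        assert diff[0] < 0 < diff[-1]

    def test_type_a_mid_activation_is_transitional_with_traveling_mode(
        self, strong_ensemble
    ):
        modes, labels = [], []
        for t in strong_ensemble.record_times[::10]:
            snap = snapshot_distribution(strong_ensemble, t)
            labels.append(snap.modality)
            modes.append(int(np.argmax(snap.probabilities)))
        assert Modality.BIMODAL not in labels
        assert Modality.TRANSITIONAL in labels
        assert modes[0] < modes[-1]  # the single peak travels upward


class TestClassifyModality:
    def edges(self):
        return np.linspace(0.0, 100.0, 21)

    def snap(self, probs):
        p = np.asarray(probs, dtype=float)
        return HistogramSnapshot(0.0, self.edges(), p / p.sum(),
                                 Modality.TRANSITIONAL)

    def test_point_mass_low(self):
        p = np.zeros(20); p[0] = 1.0
        assert classify_modality(self.snap(p)) is Modality.UNIMODAL_LOW

    def test_even_split_is_bimodal(self):
        p = np.zeros(20); p[0] = 0.5; p[-1] = 0.5
        assert classify_modality(self.snap(p)) is Modality.BIMODAL

    def test_central_peak_is_transitional(self):
        p = np.zeros(20); p[9] = 0.7; p[10] = 0.3
        assert classify_modality(self.snap(p)) is Modality.TRANSITIONAL

    def test_bad_cuts_rejected(self):
        p = np.zeros(20); p[0] = 1.0
        with pytest.raises(ValueError):
            classify_modality(self.snap(p), low_cut=0.9, high_cut=0.1)


class TestChannelAttribution:
    def test_pure_type_b_fraction_is_exactly_zero(self):
        params = dataclasses.replace(preset("weak"), k_a=0.0)
        ens = simulate_population(params, 20, 10.0, [0.0, 10.0], master_seed=1)
        assert channel_attribution(ens).pooled == 0.0

    def test_pure_type_a_fraction_is_exactly_one(self):
        params = dataclasses.replace(preset("strong"), k_b3=0.0)
        ens = simulate_population(params, 20, 1.0, [0.0, 1.0], master_seed=1)
        assert channel_attribution(ens).pooled == 1.0

    def test_no_activation_events_is_missing(self):
        ens = simulate_population(
            preset("base").with_x0(0.0), 3, 1.0, [0.0, 1.0], master_seed=1
        )
        assert math.isnan(channel_attribution(ens).pooled)

    def test_per_cell_fractions_bounded(self, weak_ensemble):
        att = channel_attribution(weak_ensemble)
        per = att.per_cell[~np.isnan(att.per_cell)]
        assert np.all((per >= 0) & (per <= 1))


class TestPhaseDiagram:
    def test_analytic_labels_on_small_grid(self):
        diagram = phase_diagram_scan(
            [1e-5, 1e-4], [50.0, 2e5], preset("base"),
            n_cells=5, t_max=50.0, master_seed=3,
        )
        # Row for k_b2 = 1e-4: thresholds are 1e3 and 1e5.
        assert diagram.analytic[1, 0] is RegimeLabel.TYPE_B
        assert diagram.analytic[1, 1] is RegimeLabel.TYPE_A

    def test_type_a_region_lies_at_larger_stimulus(self):
        diagram = phase_diagram_scan(
            [1e-5, 1e-4], [10.0, 1e4, 1e7], preset("base"),
            n_cells=2, t_max=10.0, master_seed=4,
        )
        order = {RegimeLabel.TYPE_B: 0, RegimeLabel.MIXED: 1, RegimeLabel.TYPE_A: 2}
        for row in diagram.analytic:
            ranks = [order[label] for label in row]
            assert ranks == sorted(ranks)

    def test_empirical_agrees_far_from_thresholds(self):
        diagram = phase_diagram_scan(
            [1e-5, 1e-4], [10.0, 1e6], preset("base"),
            n_cells=30, t_max=500.0, master_seed=5,
        )
        # Every grid point is >= 10x beyond both thresholds in x0.
        assert np.all(diagram.analytic == diagram.empirical)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            phase_diagram_scan([], [1.0], preset("base"), 2, 1.0, 0)
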