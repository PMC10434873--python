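import numpy as np
import pytest
from scipy import stats

from presynvar.analysis import (
    active_input_decomposition,
    circular_resultant,
    delta_po,
    ensemble_active_curves,
    estimate_po_from_weighted_sum,
    estimate_tuning,
    pre_post_activity_correlation,
    weight_vs_dpo_correlation,
)
from presynvar.exceptions import UndefinedStatisticError
from presynvar.population import InputPopulation, sample_population
from presynvar.protocol import ProtocolParams, SimulationRecord, run_simulation


def make_record(population, thetas, weights_row, output_rate=None):
    """Assemble a minimal record with frozen weights for analysis tests."""
    n = len(thetas)
    rates = population.rates(np.asarray(thetas))
    traj = np.tile(np.asarray(weights_row, dtype=float), (n, 1))
    if output_rate is None:
        output_rate = rates @ np.ones(population.size)
    return SimulationRecord(
        population=population,
        stimulus_sequence=np.asarray(thetas, dtype=float),
        weight_trajectory=traj,
        per_stimulus_input_rates=rates,
        per_stimulus_output_rate=np.asarray(output_rate, dtype=float),
        initial_weights=traj[0].copy(),
        warmup_final_weights=traj[0].copy(),
        seed=0,
        mode="fast",
        protocol=ProtocolParams(warmup_duration=0.0, n_stimuli=n),
    )


class TestCircularResultant:
    def test_uniform_curve_has_zero_selectivity_and_undefined_po(self):
        centers = np.linspace(-np.pi / 2, np.pi / 2, 20, endpoint=False) + np.pi / 40
        po, sel = circular_resultant(np.ones(20), centers)
        assert sel == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(po)

    def test_single_bin_is_perfectly_selective(self):
        centers = np.linspace(-np.pi / 2, np.pi / 2, 20, endpoint=False)
        values = np.zeros(20)
        values[7] = 3.2
        po, sel = circular_resultant(values, centers)
        assert po == pytest.approx(centers[7])
        assert sel == pytest.approx(1.0)

    def test_first_harmonic_curve(self):
        # c(theta) = 1 + cos(2 theta): PO 0, selectivity = half the modulation
        grid = np.linspace(-np.pi / 2, np.pi / 2, 2000, endpoint=False)
        po, sel = circular_resultant(1 + np.cos(2 * grid), grid)
        assert po == pytest.approx(0.0, abs=1e-9)
        assert sel == pytest.approx(0.5, abs=1e-9)

    def test_selectivity_invariant_under_scaling(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(-np.pi / 2, np.pi / 2, 50, endpoint=False)
        values = rng.uniform(0, 1, 50)
        _, s1 = circular_resultant(values, grid)
        _, s2 = circular_resultant(1000 * values, grid)
        assert s1 == pytest.approx(s2)

    def test_all_zero_curve_raises(self):
        with pytest.raises(UndefinedStatisticError):
            circular_resultant(np.zeros(5), np.linspace(-1, 1, 5))


@pytest.fixture(scope="module")
def record():
    pop = sample_population(20, seed=7)
    return run_simulation(pop, protocol=ProtocolParams(warmup_duration=5.0), seed=2)


class TestEstimateTuning:
    def test_input_po_recovered_within_bin_width(self, record):
        pop = record.population
        sharp = int(np.argmax(pop.kappa))
        est = estimate_tuning(record, target=sharp)
        assert abs(delta_po(est.preferred_orientation,
                            pop.preferred_orientation[sharp])) < np.pi / 20

    def test_flat_input_has_low_selectivity(self):
        pop = InputPopulation([0.2, -0.4], [1e-6, 1.0])
        thetas = np.random.default_rng(0).uniform(-np.pi / 2, np.pi / 2, 500)
        rec = make_record(pop, thetas, [1.0, 1.0])
        est = estimate_tuning(rec, target=0)
        assert est.selectivity < 0.05

    def test_estimated_selectivity_increases_with_kappa(self, record):
        pop = record.population
        sel = np.array(
            [estimate_tuning(record, target=i).selectivity for i in range(pop.size)]
        )
        assert stats.spearmanr(sel, pop.kappa).statistic > 0.95

    def test_record_shorter_than_window_rejected(self):
        pop = sample_population(3, seed=0)
        thetas = np.zeros(100)
        rec = make_record(pop, thetas, np.ones(3))
        with pytest.raises(ValueError):
            estimate_tuning(rec, last_k=500)


class TestWeightDpoCorrelation:
    def test_synthetic_weights_equal_dpo_give_correlation_one(self):
        pop = sample_population(50, seed=9)
        rec = run_simulation(pop, protocol=ProtocolParams(warmup_duration=5.0), seed=3)
        post_po = estimate_tuning(rec).preferred_orientation
        rigged = np.abs(delta_po(pop.preferred_orientation, post_po)) + 1e-6
        rec.weight_trajectory[-1] = rigged
        assert weight_vs_dpo_correlation([rec]) == pytest.approx(1.0, abs=1e-9)


class TestPrePostCorrelation:
    def test_output_proportional_to_one_input(self):
        pop = sample_population(5, seed=11)
        thetas = np.random.default_rng(1).uniform(-np.pi / 2, np.pi / 2, 600)
        rates = pop.rates(thetas)
        rec = make_record(pop, thetas, np.ones(5), output_rate=3.0 * rates[:, 2])
        corr = pre_post_activity_correlation(rec)
        assert corr[2] == pytest.approx(1.0, abs=1e-12)

    def test_independent_output_has_near_zero_correlation(self):
        pop = sample_population(5, seed=11)
        rng = np.random.default_rng(4)
        thetas = rng.uniform(-np.pi / 2, np.pi / 2, 600)
        rec = make_record(pop, thetas, np.ones(5),
                          output_rate=rng.uniform(0, 10, 600))
        corr = pre_post_activity_correlation(rec)
        assert np.all(np.abs(corr) < 3 / np.sqrt(500))

    def test_constant_series_reported_missing(self):
        pop = InputPopulation([0.0, 0.5], [0.0, 1.0])  # flat input: constant rate
        thetas = np.random.default_rng(0).uniform(-np.pi / 2, np.pi / 2, 600)
        rec = make_record(pop, thetas, np.ones(2))
        corr = pre_post_activity_correlation(rec)
        assert np.isnan(corr[0]) and np.isfinite(corr[1])


class TestActiveInputs:
    def test_flat_input_never_active_at_base_threshold(self):
        # a kappa=0 input sits exactly at beta; strict comparison keeps it inactive
        pop = InputPopulation([0.0, 0.3], [0.0, 1.0])
        thetas = np.linspace(-np.pi / 2, np.pi / 2, 600, endpoint=False)
        rec = make_record(pop, thetas, np.ones(2))
        summary = active_input_decomposition(rec, last_k=600)
        flat_active = rec.per_stimulus_input_rates[:, 0] > summary.threshold
        assert not flat_active.any()
        assert summary.n_active.max() == 1

    def test_kappa_one_active_window(self):
        # active iff |theta - po| < 0.5*arccos(ln I0(1)) ~ 0.6665 rad
        pop = InputPopulation([0.0], [1.0])
        thetas = np.linspace(-np.pi / 2, np.pi / 2, 2000, endpoint=False)
        rec = make_record(pop, thetas, np.ones(1))
        summary = active_input_decomposition(rec, last_k=2000)
        active = rec.per_stimulus_input_rates[:, 0] > summary.threshold
        window = np.abs(thetas[active])
        assert window.max() < 0.6665 + 2e-3
        assert window.max() > 0.6665 - 2e-3

    def test_ensemble_curves_peak_at_postsynaptic_po(self, variance_ensemble_10):
        curves = ensemble_active_curves(variance_ensemble_10)
        mid = np.argmin(np.abs(curves["delta"].to_numpy()))
        for col in ("n_active", "total_input_current", "mean_active_weight"):
            values = curves[col].to_numpy()
            assert values[mid] > values[0]  # PO beats orthogonal


class TestWeightedSumPo:
    def test_single_input_returns_its_po(self):
        pop = InputPopulation([0.37], [0.8])
        assert estimate_po_from_weighted_sum(pop, [2.5]) == pytest.approx(0.37, abs=1e-6)

    def test_two_equal_inputs_average(self):
        pop = InputPopulation([0.0, np.pi / 4], [1.0, 1.0])
        po = estimate_po_from_weighted_sum(pop, [1.0, 1.0])
        assert po == pytest.approx(np.pi / 8, abs=1e-6)

    def test_zero_weights_undefined(self):
        pop = InputPopulation([0.0, 0.5], [1.0, 1.0])
        with pytest.raises(UndefinedStatisticError):
            estimate_po_from_weighted_sum(pop, [0.0, 0.0])

    def test_full_estimate_beats_stripped_estimate(self, variance_ensemble_10):
        errs = {"none": [], "both": []}
        for rec in variance_ensemble_10:
            post = estimate_tuning(rec).preferred_orientation
            if np.isnan(post):
                continue
            for override in errs:
                est = estimate_po_from_weighted_sum(
                    rec.population, rec.final_weights, override
                )
                errs[override].append(abs(delta_po(est, post)))
        assert np.mean(errs["none"]) < np.mean(errs["both"])
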