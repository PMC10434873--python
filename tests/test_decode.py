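import numpy as np
import pytest

from presynvar.decode import (
    DecoderSpec,
    NoiseModel,
    compare_decoders,
    decoder_responses,
    evaluate_decoder,
    performance_from_responses,
    resolve_weights,
    sample_response,
    weighted_decode,
    weights_from_record,
)
from presynvar.exceptions import ConfigurationError, UndefinedEstimateError
from presynvar.orientation import delta_po, wrap_orientation
from presynvar.population import InputPopulation, sample_population, tuning_rate


class TestSampleResponse:
    def test_zero_rate_poisson_is_zero(self, rng):
        out = sample_response(np.zeros(20), NoiseModel("poisson"), rng)
        assert np.all(out == 0)

    def test_poisson_moments(self, rng):
        rate = 42.715
        draws = sample_response(np.full(100_000, rate), NoiseModel("poisson"), rng)
        assert draws.mean() == pytest.approx(rate, abs=3 * np.sqrt(rate / 100_000))
        assert draws.var() == pytest.approx(rate, rel=0.05)

    def test_none_noise_is_identity(self, rng):
        rates = np.array([1.0, 5.0, 20.0])
        assert np.array_equal(sample_response(rates, NoiseModel("none"), rng), rates)

    def test_negative_rates_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_response(np.array([-1.0]), NoiseModel("poisson"), rng)

    def test_po_jitter_recomputes_rates(self, rng):
        pop = InputPopulation([0.0, 0.4], [1.0, 0.5])
        offsets = np.array([0.1, -0.2])
        out = sample_response(
            pop.rates(0.3), NoiseModel("po_jitter"), rng,
            population=pop, theta=0.3, jitter_offsets=offsets,
        )
        expected = tuning_rate(0.3 + offsets, pop.preferred_orientation, pop.kappa)
        assert out == pytest.approx(expected)


class TestWeightedDecode:
    def test_single_input_returns_its_po(self):
        assert weighted_decode([3.0], [0.7], [0.25]) == pytest.approx(0.25)

    def test_two_equal_masses_average(self):
        est = weighted_decode([1.0, 1.0], [1.0, 1.0], [0.0, np.pi / 4])
        assert est == pytest.approx(np.pi / 8)

    def test_orthogonal_equal_masses_are_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            weighted_decode([1.0, 1.0], [1.0, 1.0], [0.0, np.pi / 2])

    def test_scale_invariance(self, rng):
        p = rng.uniform(0, 30, 50)
        w = rng.uniform(0, 1, 50)
        po = rng.uniform(-np.pi / 2, np.pi / 2, 50)
        assert weighted_decode(p, w, po) == pytest.approx(weighted_decode(p, 17.3 * w, po))

    @pytest.mark.parametrize("delta", [-1.2, -0.3, 0.45, 1.5])
    def test_equivariance_under_rotation(self, rng, delta):
        pop = sample_population(30, seed=3)
        theta = 0.2
        p = rng.poisson(pop.rates(theta)).astype(float)
        base = weighted_decode(p, pop.kappa, pop.preferred_orientation)
        rotated = weighted_decode(p, pop.kappa,
                                  wrap_orientation(pop.preferred_orientation + delta))
        assert delta_po(rotated, base) == pytest.approx(
            delta_po(wrap_orientation(base + delta), base), abs=1e-9
        )

    def test_ml_exact_on_symmetric_population(self):
        # equal kappas + equally spaced POs + noiseless rates: exact identity
        n = 50
        pos = -np.pi / 2 + np.pi * np.arange(n) / n
        grid = np.linspace(-np.pi / 2, np.pi / 2, 100, endpoint=False)
        rates = tuning_rate(grid[:, None], pos[None, :], 1.0)
        est = weighted_decode(rates, np.ones(n), pos)
        assert np.max(np.abs(delta_po(est, grid))) < 1e-10


class TestResolveWeights:
    def test_ml_and_uniform(self):
        pop = InputPopulation([0.0, 0.3], [0.2, 0.9])
        assert resolve_weights(DecoderSpec("ml"), pop) == pytest.approx([0.2, 0.9])
        assert resolve_weights(DecoderSpec("uniform"), pop) == pytest.approx([1.0, 1.0])

    def test_shuffled_is_seeded_permutation(self):
        pop = sample_population(20, seed=0)
        w = np.arange(20.0)
        a = resolve_weights(DecoderSpec("shuffled", shuffle_seed=5), pop, variance_weights=w)
        b = resolve_weights(DecoderSpec("shuffled", shuffle_seed=5), pop, variance_weights=w)
        assert np.array_equal(a, b)
        assert sorted(a) == sorted(w)
        assert not np.array_equal(a, w)

    def test_missing_record_weights_rejected(self):
        pop = sample_population(5, seed=0)
        with pytest.raises(ConfigurationError):
            resolve_weights(DecoderSpec("variance"), pop)


class TestEvaluateDecoder:
    def test_noiseless_symmetric_population_has_zero_error(self):
        n = 40
        pop = InputPopulation(-np.pi / 2 + np.pi * np.arange(n) / n, np.ones(n))
        perf = evaluate_decoder(pop.kappa, pop, NoiseModel("none"), n_trials=2, rng=0)
        assert perf.mean_error == pytest.approx(0.0, abs=1e-20)
        assert perf.mean_abs_bias == pytest.approx(0.0, abs=1e-10)

    def test_error_identity_holds_exactly(self, rng):
        pop = sample_population(50, seed=8)
        perf = evaluate_decoder(pop.kappa, pop, NoiseModel("poisson"), rng=rng)
        assert perf.error == pytest.approx(perf.variance + perf.bias**2, abs=1e-15)

    def test_ml_consistency_with_population_size(self):
        # symmetric populations: bias ~ 0 and variance shrinks as N grows
        variances = []
        for n in (10, 50, 200):
            pop = InputPopulation(-np.pi / 2 + np.pi * np.arange(n) / n, np.ones(n))
            perf = evaluate_decoder(pop.kappa, pop, NoiseModel("poisson"), rng=7)
            assert perf.mean_abs_bias < 0.05
            variances.append(perf.mean_variance)
        assert variances[0] > variances[1] > variances[2]


@pytest.fixture(scope="module")
def frame():
    return compare_decoders(n_populations=5, base_seed=0)


class TestCompareDecoders:
    def test_all_schemes_reported(self, frame):
        assert set(frame["scheme"]) == {"variance", "ml", "uniform", "shuffled", "covariance"}
        assert len(frame) == 25

    def test_shuffling_degrades_the_variance_decoder(self, frame):
        err = frame.groupby("scheme")["error"].mean()
        assert err["shuffled"] > err["variance"]

    def test_matched_responses_are_reproducible(self):
        a = compare_decoders(n_populations=2, base_seed=4)
        b = compare_decoders(n_populations=2, base_seed=4)
        assert a.equals(b)


def test_weights_from_record_sums_contacts(variance_ensemble_10):
    rec = variance_ensemble_10[0]
    w = weights_from_record(rec)
    assert w == pytest.approx(rec.final_weights)  # single-contact population
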