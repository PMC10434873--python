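"""Population decoding of orientation from noisy input responses.

For independent Poisson responses p_i of von Mises-tuned inputs, the maximum-
likelihood estimate of the stimulus has the closed form

    theta_hat = 1/2 * atan2( sum_i p_i k_i sin(2 po_i),
                             sum_i p_i k_i cos(2 po_i) ),

i.e. each input's response is weighted by its tuning width kappa.  The same
resultant-vector estimator with arbitrary weights w_i defines a family of
decoders; the ones compared here are

* ``variance`` — weights from a variance-rule plasticity run (correlate
  with kappa),
* ``ml`` — w_i = kappa_i (maximum likelihood),
* ``uniform`` — w_i = 1,
* ``shuffled`` — the variance weights permuted (decorrelated from kappa),
* ``covariance`` — weights from a covariance-rule plasticity run.

Decoders are scored per test orientation by bias, trial variance and error
(= variance + bias^2), computed on differences wrapped to the orientation
circle, then averaged over a grid of test orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UndefinedEstimateError
from .orientation import wrap_orientation
from .plasticity import PlasticityParams
from .population import InputPopulation, sample_population, tuning_rate
from .protocol import OutputNeuronParams, ProtocolParams, derive_seed, run_simulation

SCHEMES = ("variance", "ml", "uniform", "shuffled", "covariance")
NOISE_KINDS = ("poisson", "gaussian_rate", "po_jitter", "none")


@dataclass(frozen=True)
class NoiseModel:
    """Response-noise model applied to the input rates before decoding.

    ``poisson`` draws each response from a Poisson with mean r_i(theta);
    ``gaussian_rate`` adds N(0, gaussian_sd) to the rates (negative values
    are kept unless ``floor_rates``, since the decoder is defined for any
    reals); ``po_jitter`` evaluates each tuning curve at theta + sigma_i with
    per-neuron offsets sigma_i ~ N(0, jitter_sd) drawn once per run, with no
    further trial noise; ``none`` passes the rates through.
    """

    kind: str = "poisson"
    gaussian_sd: float = 5.0
    jitter_sd: float = np.pi / 50
    floor_rates: bool = False

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")


def draw_jitter_offsets(population: InputPopulation, noise: NoiseModel, rng):
    """Per-neuron PO jitter offsets, fixed across the trials of a run."""
    return rng.normal(0.0, noise.jitter_sd, population.size)


def sample_response(
    rates,
    noise: NoiseModel = NoiseModel(),
    rng=None,
    population: InputPopulation | None = None,
    theta=None,
    jitter_offsets=None,
):
    """Draw one response vector for the given per-input rates (Hz).

    ``po_jitter`` ignores ``rates`` and recomputes them from the tuning
    curves at ``theta + jitter_offsets`` (all three keyword arguments are
    then required).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("input rates must be >= 0")
    if noise.kind == "none":
        return rates.copy()
    if noise.kind == "po_jitter":
        if population is None or theta is None or jitter_offsets is None:
            raise ConfigurationError("po_jitter needs population, theta and jitter_offsets")
        return tuning_rate(
            theta + np.asarray(jitter_offsets),
            population.preferred_orientation,
            population.kappa,
            population.reference_rate,
        )
    rng = np.random.default_rng(rng)
    if noise.kind == "poisson":
        return rng.poisson(rates).astype(float)
    # gaussian_rate
    out = rates + rng.normal(0.0, noise.gaussian_sd, rates.shape)
    return np.maximum(out, 0.0) if noise.floor_rates else out


def weighted_decode(responses, weights, preferred_orientations):
    """Resultant-vector orientation estimate, wrapped to [-pi/2, pi/2).

    ``responses`` may carry leading batch dimensions; the input axis is the
    last one.  A scalar decode whose resultant vanishes raises
    :class:`UndefinedEstimateError`; batched decodes return NaN there.
    """
    p = np.asarray(responses, dtype=float)
    w = np.asarray(weights, dtype=float)
    po = np.asarray(preferred_orientations, dtype=float)
    if w.shape != po.shape or w.ndim != 1 or p.shape[-1] != w.size:
        raise ValueError("responses, weights, preferred_orientations mismatch")
    mass = p * w
    num = mass @ np.sin(2.0 * po)
    den = mass @ np.cos(2.0 * po)
    scale = np.abs(mass).sum(axis=-1)
    undefined = np.hypot(num, den) <= 1e-12 * np.maximum(scale, 1e-300)
    est = wrap_orientation(0.5 * np.arctan2(num, den))
    if np.ndim(est) == 0:
        if undefined:
            raise UndefinedEstimateError("zero resultant; orientation estimate undefined")
        return float(est)
    est = np.where(undefined, np.nan, est)
    return est


@dataclass(frozen=True)
class DecoderSpec:
    """A decoding scheme plus the ingredients needed to resolve its weights."""

    scheme: str = "ml"
    shuffle_seed: int = 0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"unknown scheme {self.scheme!r}; one of {SCHEMES}")


def weights_from_record(record) -> np.ndarray:
    """Per-neuron decoder weights from a plasticity run (contacts summed)."""
    return np.bincount(
        record.population.synapse_neuron,
        weights=record.final_weights,
        minlength=record.population.size,
    )


def resolve_weights(
    spec: DecoderSpec,
    population: InputPopulation,
    variance_weights=None,
    covariance_weights=None,
):
    """Weight vector for a scheme: simulation weights, kappa, ones, or a
    seeded permutation of the variance weights."""
    if spec.scheme == "ml":
        return population.kappa.copy()
    if spec.scheme == "uniform":
        return np.ones(population.size)
    if spec.scheme == "variance":
        if variance_weights is None:
            raise ConfigurationError("variance scheme needs variance_weights")
        return np.asarray(variance_weights, dtype=float).copy()
    if spec.scheme == "shuffled":
        if variance_weights is None:
            raise ConfigurationError("shuffled scheme needs variance_weights")
        rng = np.random.default_rng(spec.shuffle_seed)
        return rng.permutation(np.asarray(variance_weights, dtype=float))
    if covariance_weights is None:
        raise ConfigurationError("covariance scheme needs covariance_weights")
    return np.asarray(covariance_weights, dtype=float).copy()


@dataclass(frozen=True)
class DecoderPerformance:
    """Bias/variance/error per test orientation plus run-level averages.

    Per orientation: bias = <wrapped(theta_hat - theta)> across trials,
    variance = trial variance of the wrapped estimates, error = variance +
    bias^2 (exact identity).  Run-level scalars average |bias|, variance and
    error over the orientation grid.  Trials with undefined estimates are
    excluded and counted in ``n_undefined``.
    """

    orientations: np.ndarray
    bias: np.ndarray
    variance: np.ndarray
    error: np.ndarray
    mean_abs_bias: float
    mean_variance: float
    mean_error: float
    n_undefined: int = 0


def orientation_grid(n_orientations=20):
    """Equally spaced test orientations covering the period once
    (-pi/2 inclusive, pi/2 exclusive: the endpoints are the same stimulus)."""
    return -np.pi / 2 + np.pi * np.arange(n_orientations) / n_orientations


def decoder_responses(
    population: InputPopulation,
    orientations,
    n_trials,
    noise: NoiseModel = NoiseModel(),
    rng=None,
):
    """Noisy response array of shape (n_orientations, n_trials, size).

    Responses depend only on the stimulus and the noise model, never on the
    decoder weights, so the same array can score several schemes under
    matched noise.
    """
    rng = np.random.default_rng(rng)
    orientations = np.asarray(orientations, dtype=float)
    n_orient = orientations.size
    rates = population.rates(orientations)  # (n_orient, size)
    shape = (n_orient, n_trials, population.size)
    if noise.kind == "poisson":
        return rng.poisson(np.broadcast_to(rates[:, None, :], shape)).astype(float)
    if noise.kind == "gaussian_rate":
        out = rates[:, None, :] + rng.normal(0.0, noise.gaussian_sd, shape)
        return np.maximum(out, 0.0) if noise.floor_rates else out
    if noise.kind == "po_jitter":
        offsets = draw_jitter_offsets(population, noise, rng)
        jittered = tuning_rate(
            orientations[:, None] + offsets[None, :],
            population.preferred_orientation[None, :],
            population.kappa[None, :],
            population.reference_rate,
        )
        return np.broadcast_to(jittered[:, None, :], shape).copy()
    return np.broadcast_to(rates[:, None, :], shape).copy()


def performance_from_responses(responses, orientations, weights, preferred_orientations):
    """Score one weight vector on a precomputed response array.

    The bias is the circular mean (period pi) of the wrapped deviations
    theta_hat - theta across trials; the variance averages the squared
    deviations from that mean, re-wrapped so a trial cloud straddling the
    +-pi/2 boundary is not torn apart.
    """
    est = weighted_decode(responses, weights, preferred_orientations)
    orientations = np.asarray(orientations, dtype=float)
    dev = wrap_orientation(est - orientations[:, None])
    n_undefined = int(np.isnan(dev).sum())
    with np.errstate(invalid="ignore"):
        z = np.nanmean(np.exp(2j * dev), axis=1)
    bias = wrap_orientation(0.5 * np.angle(z))
    variance = np.nanmean(wrap_orientation(dev - bias[:, None]) ** 2, axis=1)
    error = variance + bias**2
    return DecoderPerformance(
        orientations=orientations,
        bias=bias,
        variance=variance,
        error=error,
        mean_abs_bias=float(np.mean(np.abs(bias))),
        mean_variance=float(np.mean(variance)),
        mean_error=float(np.mean(error)),
        n_undefined=n_undefined,
    )


def evaluate_decoder(
    weights,
    population: InputPopulation,
    noise: NoiseModel = NoiseModel(),
    n_orientations=20,
    n_trials=100,
    rng=None,
):
    """Evaluate one decoder: 20 equally spaced orientations x 100 trials each
    by default, returning a :class:`DecoderPerformance`."""
    if n_trials < 2:
        raise ConfigurationError("n_trials must be >= 2")
    orientations = orientation_grid(n_orientations)
    responses = decoder_responses(population, orientations, n_trials, noise, rng)
    return performance_from_responses(
        responses, orientations, weights, population.preferred_orientation
    )


def compare_decoders(
    n_populations=20,
    noise: NoiseModel = NoiseModel(),
    base_seed=0,
    schemes=SCHEMES,
    population_size=50,
    n_orientations=20,
    n_trials=100,
    plasticity_variance: PlasticityParams = PlasticityParams("variance"),
    plasticity_covariance: PlasticityParams = PlasticityParams("covariance"),
    neuron: OutputNeuronParams = OutputNeuronParams(),
    protocol: ProtocolParams = ProtocolParams(),
) -> pd.DataFrame:
    """Benchmark the decoder schemes over an ensemble of input populations.

    For each population, a variance-rule and (if needed) a covariance-rule
    plasticity run supply the learned weights; all schemes are then scored on
    the *same* noisy responses.  Returns a tidy frame with one row per
    (run, scheme) and columns abs_bias, variance, error (rad or rad^2).
    """
    rows = []
    need_var = any(s in ("variance", "shuffled") for s in schemes)
    need_cov = "covariance" in schemes
    for k in range(n_populations):
        seed_k = derive_seed(base_seed, k)
        rng = np.random.default_rng(seed_k)
        pop = sample_population(population_size, seed=rng)
        var_w = cov_w = None
        if need_var:
            var_w = weights_from_record(
                run_simulation(pop, plasticity_variance, neuron, protocol, seed=rng)
            )
        if need_cov:
            cov_w = weights_from_record(
                run_simulation(pop, plasticity_covariance, neuron, protocol, seed=rng)
            )
        orientations = orientation_grid(n_orientations)
        responses = decoder_responses(pop, orientations, n_trials, noise, rng)
        for scheme in schemes:
            w = resolve_weights(DecoderSpec(scheme, shuffle_seed=seed_k), pop, var_w, cov_w)
            perf = performance_from_responses(
                responses, orientations, w, pop.preferred_orientation
            )
            rows.append(
                {
                    "run": k,
                    "scheme": scheme,
                    "abs_bias": perf.mean_abs_bias,
                    "variance": perf.mean_variance,
                    "error": perf.mean_error,
                    "n_undefined": perf.n_undefined,
                }
            )
    return pd.DataFrame(rows)


def summarize_performance(frame: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of abs_bias/variance/error per scheme."""
    grouped = frame.groupby("scheme")[["abs_bias", "variance", "error"]]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()
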