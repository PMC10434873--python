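"""Stimulation protocol driving the plasticity simulations.

A run proceeds in two phases:

1. **Warm-up** — every input fires at a fixed rate (20 Hz for 200 s by
   default) with plasticity active, so weights settle to the warm-up fixed
   point regardless of their initial value.
2. **Stimulation** — a new orientation is drawn uniformly from [-pi/2, pi/2)
   every ``T`` (200 ms) and shown to the whole population for 1000 stimuli;
   input rates follow the tuning curves, the output neuron integrates the
   weighted drive, and weights evolve under the selected plasticity rule.

Two integration modes are provided and must agree:

* ``"fast"`` — exploits tau_y << T: per stimulus the output rate is the
  steady-state drive, and the (linear-in-w) weight ODE is relaxed *exactly*
  over the stimulus interval toward its per-stimulus fixed point.
* ``"euler"`` — forward-Euler steps of both the output rate and the weights
  at resolution ``dt`` (1 ms default).

Weights are recorded once per stimulus (at stimulus end) to bound memory.
Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import OutputNeuronParams, steady_state_rate, step_rate
from .exceptions import ConfigurationError
from .plasticity import PlasticityParams
from .population import InputPopulation, sample_population

#: Modulus keeping derived seeds in 32-bit int range.
_SEED_MOD = 2**31


def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic per-run seed from (base_seed, run index).

    A fixed affine map modulo 2^31; documented so ensembles are reproducible
    under any execution order.
    """
    return (int(base_seed) * 1_000_003 + int(index)) % _SEED_MOD


@dataclass(frozen=True)
class ProtocolParams:
    """Timing and initialization of one plasticity run (times in seconds).

    ``initial_weight`` is either a scalar (applied to every contact; default
    0, which the warm-up makes irrelevant) or a (low, high) pair for uniform
    random initialization.
    """

    warmup_duration: float = 200.0
    warmup_rate: float = 20.0
    stimulus_duration: float = 0.2
    n_stimuli: int = 1000
    dt: float = 1e-3
    initial_weight: float | tuple = 0.0
    mode: str = "fast"

    def __post_init__(self):
        if self.warmup_duration < 0 or self.stimulus_duration <= 0 or self.dt <= 0:
            raise ConfigurationError("durations must be positive (warmup may be 0)")
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli must be >= 1")
        if self.mode not in ("fast", "euler"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        m = self.stimulus_duration / self.dt
        if abs(m - round(m)) > 1e-9 or round(m) < 1:
            raise ConfigurationError("stimulus_duration must be an integer multiple of dt")

    @property
    def steps_per_stimulus(self) -> int:
        return int(round(self.stimulus_duration / self.dt))


@dataclass(eq=False)  # array fields: identity comparison only
class SimulationRecord:
    """Full trace of one plasticity run.

    Weight arrays have one entry per synaptic contact; rate arrays one per
    neuron (they coincide except in multi-contact populations).
    """

    population: InputPopulation
    stimulus_sequence: np.ndarray  # (n_stimuli,)
    weight_trajectory: np.ndarray  # (n_stimuli, n_synapses), at stimulus ends
    per_stimulus_input_rates: np.ndarray  # (n_stimuli, size)
    per_stimulus_output_rate: np.ndarray  # (n_stimuli,)
    initial_weights: np.ndarray
    warmup_final_weights: np.ndarray
    seed: object
    mode: str
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    neuron: OutputNeuronParams = field(default_factory=OutputNeuronParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)

    @property
    def final_weights(self) -> np.ndarray:
        return self.weight_trajectory[-1]

    @property
    def n_stimuli(self) -> int:
        return self.stimulus_sequence.size

    # -- serialization -----------------------------------------------------

    def save(self, directory, include_rates=True):
        """Write the record as plain-text files (JSON metadata + CSV tables)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "seed": self.seed if isinstance(self.seed, (int, type(None))) else repr(self.seed),
            "mode": self.mode,
            "reference_rate": self.population.reference_rate,
            "plasticity": asdict(self.plasticity),
            "neuron": asdict(self.neuron),
            "protocol": {**asdict(self.protocol)},
            "include_rates": bool(include_rates),
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2, default=list))
        self.population.to_frame().to_csv(directory / "population.csv", index=False)
        pd.DataFrame(
            {
                "stimulus": np.arange(self.n_stimuli),
                "theta": self.stimulus_sequence,
                "output_rate": self.per_stimulus_output_rate,
            }
        ).to_csv(directory / "stimuli.csv", index=False)
        cols = [f"w{i}" for i in range(self.weight_trajectory.shape[1])]
        wt = pd.DataFrame(self.weight_trajectory, columns=cols)
        wt.insert(0, "stimulus", np.arange(self.n_stimuli))
        wt.to_csv(directory / "weights.csv", index=False)
        pd.DataFrame(
            [self.initial_weights, self.warmup_final_weights],
            columns=cols,
            index=["initial", "warmup_end"],
        ).to_csv(directory / "boundary_weights.csv", index_label="phase")
        if include_rates:
            rates = pd.DataFrame(
                self.per_stimulus_input_rates,
                columns=[f"r{i}" for i in range(self.population.size)],
            )
            rates.insert(0, "stimulus", np.arange(self.n_stimuli))
            rates.to_csv(directory / "input_rates.csv", index=False)

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        pop = InputPopulation.from_frame(
            pd.read_csv(directory / "population.csv"), reference_rate=meta["reference_rate"]
        )
        stim = pd.read_csv(directory / "stimuli.csv")
        wt = pd.read_csv(directory / "weights.csv").drop(columns="stimulus").to_numpy(float)
        boundary = pd.read_csv(directory / "boundary_weights.csv", index_col="phase")
        proto = meta["protocol"]
        if isinstance(proto.get("initial_weight"), list):
            proto["initial_weight"] = tuple(proto["initial_weight"])
        if meta["include_rates"]:
            rates = (
                pd.read_csv(directory / "input_rates.csv")
                .drop(columns="stimulus")
                .to_numpy(float)
            )
        else:
            rates = np.full((len(stim), pop.size), np.nan)
        return cls(
            population=pop,
            stimulus_sequence=stim["theta"].to_numpy(float),
            weight_trajectory=wt,
            per_stimulus_input_rates=rates,
            per_stimulus_output_rate=stim["output_rate"].to_numpy(float),
            initial_weights=boundary.loc["initial"].to_numpy(float),
            warmup_final_weights=boundary.loc["warmup_end"].to_numpy(float),
            seed=meta["seed"],
            mode=meta["mode"],
            plasticity=PlasticityParams(**meta["plasticity"]),
            neuron=OutputNeuronParams(**meta["neuron"]),
            protocol=ProtocolParams(**proto),
        )


def _initial_weights(protocol: ProtocolParams, n_synapses: int, rng) -> np.ndarray:
    iw = protocol.initial_weight
    if isinstance(iw, (tuple, list)):
        low, high = iw
        return rng.uniform(low, high, n_synapses)
    return np.full(n_synapses, float(iw))


def _fast_period(w, r_syn, duration, plasticity, neuron):
    """Advance weights exactly over one constant-rate period; return (w, y).

    The output rate is the steady-state drive given the weights at period
    start; the weight ODE, linear in w with constant coefficients over the
    period, is relaxed exactly toward its per-stimulus fixed point.
    """
    y = steady_state_rate(w, r_syn, neuron)
    if plasticity.rule == "frozen":
        return w, y
    eta1, eta0, rref = plasticity.eta1, plasticity.eta0, plasticity.reference_rate
    if plasticity.rule == "variance":
        w_star = (eta1 / eta0) * (r_syn / rref - plasticity.mu) ** 2
    else:  # covariance
        w_star = (eta1 / eta0) * (r_syn / rref - plasticity.gamma) * (y / rref - plasticity.gamma)
    w = w_star + (w - w_star) * np.exp(-eta0 * duration)
    if plasticity.rule == "covariance":
        w = np.maximum(w, 0.0)
    return w, y


def _euler_period(w, y, r_syn, n_steps, dt, plasticity, neuron):
    """Forward-Euler steps over one constant-rate period; return (w, y)."""
    eta1, eta0, rref = plasticity.eta1, plasticity.eta0, plasticity.reference_rate
    if plasticity.rule == "variance":
        pot = eta1 * (r_syn / rref - plasticity.mu) ** 2
    for _ in range(n_steps):
        target = steady_state_rate(w, r_syn, neuron)
        y = step_rate(y, target, dt, neuron)
        if plasticity.rule == "variance":
            w = w + dt * (pot - eta0 * w)
        elif plasticity.rule == "covariance":
            pre = r_syn / rref - plasticity.gamma
            post = y / rref - plasticity.gamma
            w = np.maximum(w + dt * (eta1 * pre * post - eta0 * w), 0.0)
    return w, y


def run_simulation(
    population: InputPopulation,
    plasticity: PlasticityParams = PlasticityParams(),
    neuron: OutputNeuronParams = OutputNeuronParams(),
    protocol: ProtocolParams = ProtocolParams(),
    seed=None,
) -> SimulationRecord:
    """Run one warm-up + stimulation protocol and record the full trace.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Randomness is
    consumed in a fixed order (initial weights, then the stimulus sequence),
    so the two integration modes see identical stimulus streams for the same
    seed and a repeated call is bit-identical.
    """
    rng = np.random.default_rng(seed)
    n_syn = population.n_synapses
    syn_map = population.synapse_neuron
    w = _initial_weights(protocol, n_syn, rng)
    initial_weights = w.copy()
    thetas = rng.uniform(-np.pi / 2, np.pi / 2, protocol.n_stimuli)

    # --- warm-up: constant untuned input rate, plasticity active ----------
    r_warm = np.full(n_syn, protocol.warmup_rate)
    y = 0.0
    if protocol.warmup_duration > 0:
        if protocol.mode == "fast":
            T = protocol.stimulus_duration
            n_full, rem = divmod(protocol.warmup_duration, T)
            for _ in range(int(round(n_full))):
                w, y = _fast_period(w, r_warm, T, plasticity, neuron)
            if rem > 1e-12:
                w, y = _fast_period(w, r_warm, rem, plasticity, neuron)
        else:
            n_steps = int(round(protocol.warmup_duration / protocol.dt))
            w, y = _euler_period(w, y, r_warm, n_steps, protocol.dt, plasticity, neuron)
    warmup_final = w.copy()

    # --- stimulation ------------------------------------------------------
    traj = np.empty((protocol.n_stimuli, n_syn))
    out_rates = np.empty(protocol.n_stimuli)
    in_rates = population.rates(thetas)  # (n_stimuli, size)
    m = protocol.steps_per_stimulus
    for j, theta in enumerate(thetas):
        r_syn = in_rates[j][syn_map]
        if protocol.mode == "fast":
            w, y = _fast_period(w, r_syn, protocol.stimulus_duration, plasticity, neuron)
        else:
            w, y = _euler_period(w, y, r_syn, m, protocol.dt, plasticity, neuron)
        traj[j] = w
        out_rates[j] = y

    return SimulationRecord(
        population=population,
        stimulus_sequence=thetas,
        weight_trajectory=traj,
        per_stimulus_input_rates=in_rates,
        per_stimulus_output_rate=out_rates,
        initial_weights=initial_weights,
        warmup_final_weights=warmup_final,
        seed=seed if isinstance(seed, int) else None,
        mode=protocol.mode,
        plasticity=plasticity,
        neuron=neuron,
        protocol=protocol,
    )


def run_ensemble(
    plasticity: PlasticityParams = PlasticityParams(),
    neuron: OutputNeuronParams = OutputNeuronParams(),
    protocol: ProtocolParams = ProtocolParams(),
    n_runs: int = 100,
    base_seed: int = 0,
    population_size: int = 50,
    po_dist: str = "uniform",
    po_sd: float = np.pi / 8,
    reference_rate: float = 125.0,
    population_builder=None,
) -> list[SimulationRecord]:
    """Run ``n_runs`` independent simulations, each with a freshly sampled
    population and a seed derived deterministically from (base_seed, run).

    ``population_builder(rng) -> InputPopulation``, when given, replaces the
    default sampling (used e.g. by the multi-contact experiment).  Runs are
    order-independent: run k depends only on ``derive_seed(base_seed, k)``.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    records = []
    for k in range(n_runs):
        seed_k = derive_seed(base_seed, k)
        rng = np.random.default_rng(seed_k)
        if population_builder is not None:
            pop = population_builder(rng)
        else:
            pop = sample_population(
                population_size,
                po_dist=po_dist,
                po_sd=po_sd,
                seed=rng,
                reference_rate=reference_rate,
            )
        record = run_simulation(pop, plasticity, neuron, protocol, seed=rng)
        record.seed = seed_k
        records.append(record)
    return records
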