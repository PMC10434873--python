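"""Experiment configuration: validated parameter blocks and presets.

A config file (YAML) selects an experiment id and optionally overrides any
parameter.  Resolution order is: package defaults < experiment preset <
user file.  Unknown keys are rejected with the offending key path.

Experiment ids map the main simulation and its supplementary variants to
runnable configs; ids covering a family of variants (population size,
activity threshold, decoder noise) resolve to one representative member,
with the siblings reachable by overriding the corresponding field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .dynamics import OutputNeuronParams
from .exceptions import ConfigurationError
from .plasticity import PlasticityParams
from .protocol import ProtocolParams

EXPERIMENT_IDS = (
    "fig1_3_main",
    "fig2_covariance",
    "fig4_decoding",
    "s1_weak_inhibition",
    "s4_s6_population_size",
    "s7_uniform_init",
    "s8_s9_normal_po",
    "s10_s11_thresholds",
    "s12_s13_decoder_noise",
    "s14_multicontact",
)

#: Experiments whose pipeline is decoder benchmarking rather than plasticity.
DECODING_EXPERIMENTS = frozenset({"fig4_decoding", "s12_s13_decoder_noise"})


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationConfig(_Block):
    size: int = Field(50, ge=1)
    po_dist: Literal["uniform", "normal"] = "uniform"
    po_sd: float = Field(np.pi / 8, gt=0)
    kappa_dist: Literal["uniform"] = "uniform"
    reference_rate: float = Field(125.0, gt=0)


class NeuronConfig(_Block):
    tau_y: float = Field(1e-3, gt=0)
    alpha: float = Field(0.1, gt=0)
    w_ref: float = Field(16.0, gt=0)
    w_inh: float = Field(-1.7, le=0)
    r_inh: float = Field(100.0, ge=0)

    def to_params(self) -> OutputNeuronParams:
        return OutputNeuronParams(**self.model_dump())


class PlasticityConfig(_Block):
    rule: Literal["variance", "covariance", "frozen"] = "variance"
    eta1: float = Field(0.1, gt=0)
    eta0: float = Field(0.03, gt=0)
    mu: float = Field(1.0 / (2.0 * np.pi), gt=0, lt=1)
    gamma: float = Field(0.24, gt=0, lt=1)
    reference_rate: float = Field(125.0, gt=0)

    def to_params(self) -> PlasticityParams:
        return PlasticityParams(**self.model_dump())


class ProtocolConfig(_Block):
    warmup_duration: float = Field(200.0, ge=0)
    warmup_rate: float = Field(20.0, ge=0)
    stimulus_duration: float = Field(0.2, gt=0)
    n_stimuli: int = Field(1000, ge=1)
    dt: float = Field(1e-3, gt=0)
    initial_weight: float | tuple[float, float] = 0.0
    mode: Literal["fast", "euler"] = "fast"

    def to_params(self) -> ProtocolParams:
        return ProtocolParams(**self.model_dump())


class AnalysisConfig(_Block):
    n_bins: int = Field(20, ge=2)
    last_k: int = Field(500, ge=1)
    threshold_multiplier: float = Field(1.0, gt=0)


class DecoderConfig(_Block):
    schemes: list[Literal["variance", "ml", "uniform", "shuffled", "covariance"]] = Field(
        default_factory=lambda: ["variance", "ml", "uniform", "shuffled", "covariance"]
    )
    noise: Literal["poisson", "gaussian_rate", "po_jitter", "none"] = "poisson"
    gaussian_sd: float = Field(5.0, gt=0)
    jitter_sd: float = Field(np.pi / 50, gt=0)
    n_orientations: int = Field(20, ge=2)
    n_trials: int = Field(100, ge=2)


class ExperimentConfig(_Block):
    experiment: Literal[EXPERIMENT_IDS] = "fig1_3_main"
    base_seed: int = 1
    n_runs: int = Field(100, ge=1)
    multicontact: bool = False
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    neuron: NeuronConfig = Field(default_factory=NeuronConfig)
    plasticity: PlasticityConfig = Field(default_factory=PlasticityConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    decoder: DecoderConfig = Field(default_factory=DecoderConfig)

    @property
    def is_decoding(self) -> bool:
        return self.experiment in DECODING_EXPERIMENTS


#: Per-experiment overrides layered on top of the package defaults.
PRESETS: dict[str, dict] = {
    "fig1_3_main": {},
    "fig2_covariance": {"plasticity": {"rule": "covariance"}},
    "fig4_decoding": {},
    "s1_weak_inhibition": {"neuron": {"w_inh": -1.7 / 5}},
    "s4_s6_population_size": {"population": {"size": 10}, "neuron": {"r_inh": 15.0}},
    "s7_uniform_init": {"protocol": {"initial_weight": (0.0, 0.05)}},
    "s8_s9_normal_po": {"population": {"po_dist": "normal"}},
    "s10_s11_thresholds": {"analysis": {"threshold_multiplier": 1.5}},
    "s12_s13_decoder_noise": {"decoder": {"noise": "gaussian_rate"}},
    "s14_multicontact": {"population": {"po_dist": "normal"}, "multicontact": True},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def build_config(data: dict | None = None, experiment: str | None = None) -> ExperimentConfig:
    """Resolve a raw mapping into a validated :class:`ExperimentConfig`."""
    data = dict(data or {})
    exp = experiment or data.get("experiment", "fig1_3_main")
    if exp not in PRESETS:
        raise ConfigurationError(f"unknown experiment id {exp!r}")
    merged = _deep_merge(PRESETS[exp], data)
    merged["experiment"] = exp
    try:
        return ExperimentConfig(**merged)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ConfigurationError(f"invalid configuration ({paths})") from exc


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return build_config(raw)


def dump_config(config: ExperimentConfig, path=None) -> str:
    """Serialize a config to YAML; round-trips through :func:`load_config`."""
    data = json.loads(config.model_dump_json())
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
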