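"""Rate dynamics of the postsynaptic (output) neuron.

The output neuron is a rectified-linear rate unit,

    tau_y * dy/dt = -y + alpha * [ w_ref * sum_i w_i r_i + w_inh * r_inh ]_+ ,

driven by the weighted excitatory inputs and a fixed untuned inhibitory
source.  With tau_y = 1 ms and stimuli held for 200 ms, y tracks the drive
essentially instantaneously, which is what :func:`steady_state_rate` exploits.

Unit bookkeeping: alpha is 1/nA, w_ref and w_inh are in nA (the inhibitory
weight of -1700 pA is stored as -1.7 nA), rates are Hz, and the bracket's
nA*Hz product times alpha is read as Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class OutputNeuronParams:
    """Parameters of the rectified-linear output unit.

    tau_y : rate time constant, seconds (default 1 ms).
    alpha : transfer-function slope, 1/nA.
    w_ref : reference weight scaling the excitatory inputs, nA.
    w_inh : inhibitory weight, nA (<= 0).
    r_inh : inhibitory source rate, Hz.
    """

    tau_y: float = 1e-3
    alpha: float = 0.1
    w_ref: float = 16.0
    w_inh: float = -1.7
    r_inh: float = 100.0

    def __post_init__(self):
        if self.tau_y <= 0 or self.alpha <= 0 or self.w_ref <= 0:
            raise ConfigurationError("tau_y, alpha, w_ref must be > 0")
        if self.w_inh > 0:
            raise ConfigurationError("w_inh must be <= 0")
        if self.r_inh < 0:
            raise ConfigurationError("r_inh must be >= 0")


def drive(weights, rates, params: OutputNeuronParams = OutputNeuronParams()):
    """Rectified input drive alpha*[w_ref * sum w_i r_i + w_inh * r_inh]_+ in Hz.

    ``weights`` and ``rates`` are per-synapse vectors of equal length.
    """
    weights = np.asarray(weights, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if weights.shape != rates.shape or weights.ndim != 1 or weights.size < 1:
        raise ConfigurationError("weights and rates must be equal-length 1-d vectors")
    bracket = params.w_ref * float(weights @ rates) + params.w_inh * params.r_inh
    return params.alpha * max(0.0, bracket)


def step_rate(y, target, dt, params: OutputNeuronParams = OutputNeuronParams()):
    """One forward-Euler step of y toward ``target`` with time constant tau_y.

    ``dt`` in seconds.  The result is clamped at 0 (defensive; the drive is
    already rectified).
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    return max(0.0, y + (dt / params.tau_y) * (target - y))


def steady_state_rate(weights, rates, params: OutputNeuronParams = OutputNeuronParams()):
    """Fixed point of the rate equation: equals :func:`drive` directly.

    Valid as the output rate whenever the stimulus duration greatly exceeds
    tau_y (the default regime, 200 ms vs 1 ms); used by the fast simulation
    mode.
    """
    return drive(weights, rates, params)
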