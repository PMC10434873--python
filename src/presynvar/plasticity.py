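"""Synaptic plasticity rules and the equilibrium-weight theory.

Two rules are implemented:

* variance rule — potentiation driven purely by the squared deviation of the
  *presynaptic* normalized rate from its ensemble mean mu = 1/(2*pi), with a
  linear weight decay:

      dw_i/dt = eta1 * (r_i/r_ref - mu)^2 - eta0 * w_i .

  The drift is independent of postsynaptic activity, so the converged weight
  of input i depends only on the statistics of r_i, i.e. on its tuning width
  kappa_i.  Averaging the per-stimulus fixed point over uniformly distributed
  stimuli gives the closed-form equilibrium

      E[W_i] = (eta1/eta0) * [ (I0(2*kappa_i)/I0(kappa_i)^2 - 1) / (4*pi^2) ],

  which :func:`equilibrium_weight` evaluates and the simulations are tested
  against.

* covariance rule — a classic Hebbian-style product of pre- and postsynaptic
  deviations from an offset gamma:

      dw_i/dt = eta1 * (r_i/r_ref - gamma) * (y/r_ref - gamma) - eta0 * w_i .

  Unlike the variance rule it can drive weights negative; simulations floor
  such weights at 0 since the inputs are excitatory.

A third "frozen" rule (zero drift) is available for control simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0

from .exceptions import ConfigurationError

RULES = ("variance", "covariance", "frozen")


@dataclass(frozen=True)
class PlasticityParams:
    """Learning-rule selection and rate constants.

    eta1, eta0 : potentiation and decay rates, per second.
    mu : mean normalized presynaptic activity (1/(2*pi) for the von Mises
         population under uniform stimuli).
    gamma : pre/post offset of the covariance rule.
    reference_rate : r_ref used to normalize rates, Hz.
    """

    rule: str = "variance"
    eta1: float = 0.1
    eta0: float = 0.03
    mu: float = 1.0 / (2.0 * np.pi)
    gamma: float = 0.24
    reference_rate: float = 125.0

    def __post_init__(self):
        if self.rule not in RULES:
            raise ConfigurationError(f"unknown rule {self.rule!r}; expected one of {RULES}")
        if self.eta1 <= 0 or self.eta0 <= 0:
            raise ConfigurationError("eta1 and eta0 must be > 0")
        if not 0 < self.mu < 1:
            raise ConfigurationError("mu must be in (0, 1)")
        if not 0 < self.gamma < 1:
            raise ConfigurationError("gamma must be in (0, 1)")
        if self.reference_rate <= 0:
            raise ConfigurationError("reference_rate must be > 0")


def variance_drift(w, r, params: PlasticityParams = PlasticityParams()):
    """dw/dt (per second) under the variance rule, for presynaptic rate r (Hz)."""
    w = np.asarray(w, dtype=float)
    r = np.asarray(r, dtype=float)
    out = params.eta1 * (r / params.reference_rate - params.mu) ** 2 - params.eta0 * w
    return float(out) if out.ndim == 0 else out


def covariance_drift(w, r_pre, y_post, params: PlasticityParams = PlasticityParams()):
    """dw/dt (per second) under the covariance rule.

    Positive when pre- and postsynaptic normalized rates sit on the same side
    of gamma, negative when they straddle it.
    """
    w = np.asarray(w, dtype=float)
    pre = np.asarray(r_pre, dtype=float) / params.reference_rate - params.gamma
    post = np.asarray(y_post, dtype=float) / params.reference_rate - params.gamma
    out = params.eta1 * pre * post - params.eta0 * w
    return float(out) if out.ndim == 0 else out


def stationary_weight_for_rate(r, params: PlasticityParams = PlasticityParams()):
    """Per-stimulus fixed point of the variance rule at constant rate r (Hz):
    w* = (eta1/eta0) * (r/r_ref - mu)^2."""
    r = np.asarray(r, dtype=float)
    out = (params.eta1 / params.eta0) * (r / params.reference_rate - params.mu) ** 2
    return float(out) if out.ndim == 0 else out


def equilibrium_weight(kappa, params: PlasticityParams = PlasticityParams()):
    """Expected converged weight of a von Mises input with width kappa.

    Closed form of the stimulus-averaged variance-rule fixed point (uniform
    stimulus ensemble):

        E[W] = (eta1/eta0) * (I0(2*kappa)/I0(kappa)^2 - 1) / (4*pi^2).

    Strictly increasing in kappa and 0 at kappa = 0 (a flat input carries no
    stimulus variance, so its weight decays away).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    out = (params.eta1 / params.eta0) * (i0(2.0 * kappa) / i0(kappa) ** 2 - 1.0) / (
        4.0 * np.pi**2
    )
    return float(out) if out.ndim == 0 else out
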