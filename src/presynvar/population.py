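"""Presynaptic input populations with von Mises orientation tuning.

Each input neuron fires at a rate

    r_i(theta) = r_ref * exp(kappa_i * cos(2*(theta - po_i))) / (2*pi*I0(kappa_i)),

a pi-periodic "bump" centred on the neuron's preferred orientation ``po_i``
whose sharpness is set by the concentration ``kappa_i`` (kappa = 0 is a flat
curve at r_ref/(2*pi)).  The normalisation by the Bessel function I0 makes the
mean rate over a uniform stimulus ensemble equal to r_ref/(2*pi) for every
kappa, so selectivity varies across the population while mean drive does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0

from .exceptions import ConfigurationError
from .orientation import wrap_orientation

DEFAULT_REFERENCE_RATE = 125.0  # Hz


def tuning_rate(theta, preferred_orientation, kappa, reference_rate=DEFAULT_REFERENCE_RATE):
    """von Mises tuning curve (period pi) evaluated at stimulus ``theta``.

    Parameters
    ----------
    theta : float or array
        Stimulus orientation(s), radians.
    preferred_orientation : float or array
        Orientation of peak response, radians.
    kappa : float or array
        Concentration (width) parameter, >= 0; 0 gives a flat curve.
    reference_rate : float
        Rate scale r_ref in Hz (the mean rate is reference_rate/(2*pi)).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    theta = np.asarray(theta, dtype=float)
    po = np.asarray(preferred_orientation, dtype=float)
    out = reference_rate * np.exp(kappa * np.cos(2.0 * (theta - po))) / (2.0 * np.pi * i0(kappa))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TuningCurve:
    """A single neuron's von Mises tuning curve."""

    preferred_orientation: float
    kappa: float
    reference_rate: float = DEFAULT_REFERENCE_RATE

    def __post_init__(self):
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.reference_rate <= 0:
            raise ConfigurationError("reference_rate must be > 0")
        object.__setattr__(
            self, "preferred_orientation", wrap_orientation(self.preferred_orientation)
        )

    def rate(self, theta):
        """Firing rate (Hz) at stimulus orientation ``theta``."""
        return tuning_rate(theta, self.preferred_orientation, self.kappa, self.reference_rate)


@dataclass(frozen=True)
class InputPopulation:
    """A population of von Mises-tuned input neurons.

    ``contact_counts`` gives the number of independent synaptic contacts each
    neuron makes onto the output neuron (default 1 everywhere; used by the
    multi-contact experiment).  Plasticity acts per contact, so simulation
    weight vectors have ``n_synapses = sum(contact_counts)`` entries; the
    ``synapse_neuron`` index maps contacts back to neurons.
    """

    preferred_orientation: np.ndarray
    kappa: np.ndarray
    reference_rate: float = DEFAULT_REFERENCE_RATE
    contact_counts: np.ndarray = field(default=None)

    def __post_init__(self):
        po = wrap_orientation(np.atleast_1d(np.asarray(self.preferred_orientation, dtype=float)))
        kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        if po.shape != kappa.shape or po.ndim != 1 or po.size < 1:
            raise ConfigurationError("preferred_orientation and kappa must be equal-length 1-d")
        if np.any(kappa < 0):
            raise ConfigurationError("kappa must be >= 0")
        if self.reference_rate <= 0:
            raise ConfigurationError("reference_rate must be > 0")
        contacts = self.contact_counts
        if contacts is None:
            contacts = np.ones(po.size, dtype=int)
        contacts = np.atleast_1d(np.asarray(contacts, dtype=int))
        if contacts.shape != po.shape or np.any(contacts < 1):
            raise ConfigurationError("contact_counts must be positive ints, one per neuron")
        object.__setattr__(self, "preferred_orientation", po)
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "contact_counts", contacts)

    @property
    def size(self) -> int:
        """Number of input neurons."""
        return self.preferred_orientation.size

    @property
    def n_synapses(self) -> int:
        """Total number of synaptic contacts (== size unless multi-contact)."""
        return int(self.contact_counts.sum())

    @property
    def synapse_neuron(self) -> np.ndarray:
        """Neuron index of each synaptic contact, length ``n_synapses``."""
        return np.repeat(np.arange(self.size), self.contact_counts)

    def curves(self):
        """The population as a list of :class:`TuningCurve`."""
        return [
            TuningCurve(po, k, self.reference_rate)
            for po, k in zip(self.preferred_orientation, self.kappa)
        ]

    def rates(self, theta):
        """Per-neuron rates (Hz) for stimulus ``theta``.

        Scalar ``theta`` gives shape (size,); an array of stimuli gives
        shape (len(theta), size).
        """
        theta = np.asarray(theta, dtype=float)
        if theta.ndim == 0:
            return tuning_rate(theta, self.preferred_orientation, self.kappa, self.reference_rate)
        return tuning_rate(
            theta[:, None],
            self.preferred_orientation[None, :],
            self.kappa[None, :],
            self.reference_rate,
        )

    def with_overrides(self, index, preferred_orientation=None, kappa=None, contacts=None):
        """Return a copy with one neuron's parameters replaced."""
        po = self.preferred_orientation.copy()
        kap = self.kappa.copy()
        cc = self.contact_counts.copy()
        if preferred_orientation is not None:
            po[index] = preferred_orientation
        if kappa is not None:
            kap[index] = kappa
        if contacts is not None:
            cc[index] = contacts
        return replace(self, preferred_orientation=po, kappa=kap, contact_counts=cc)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per neuron: index, preferred orientation, kappa, contacts."""
        return pd.DataFrame(
            {
                "neuron": np.arange(self.size),
                "preferred_orientation": self.preferred_orientation,
                "kappa": self.kappa,
                "contact_count": self.contact_counts,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference_rate=DEFAULT_REFERENCE_RATE):
        frame = frame.sort_values("neuron")
        return cls(
            preferred_orientation=frame["preferred_orientation"].to_numpy(float),
            kappa=frame["kappa"].to_numpy(float),
            reference_rate=reference_rate,
            contact_counts=frame["contact_count"].to_numpy(int)
            if "contact_count" in frame
            else None,
        )


def sample_population(
    n,
    po_dist="uniform",
    kappa_dist="uniform",
    seed=None,
    po_sd=np.pi / 8,
    reference_rate=DEFAULT_REFERENCE_RATE,
):
    """Draw an :class:`InputPopulation` of ``n`` neurons.

    Preferred orientations are drawn either uniformly on [-pi/2, pi/2) or,
    for the biased-population variant, from a normal distribution with mean 0
    and sd ``po_sd`` wrapped onto the orientation circle.  Widths kappa are
    drawn uniformly on the half-open interval ]0, 1] (flat kappa = 0 curves
    are permitted by :func:`tuning_rate` but never sampled).

    ``seed`` may be an int, None, or a ``numpy.random.Generator``; the same
    seed always reproduces the same population bit-exactly.
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    if po_dist == "uniform":
        po = rng.uniform(-np.pi / 2, np.pi / 2, n)
    elif po_dist == "normal":
        po = wrap_orientation(rng.normal(0.0, po_sd, n))
    else:
        raise ConfigurationError(f"unknown po_dist {po_dist!r}")
    if kappa_dist == "uniform":
        # ]0, 1]: uniform() is [0, 1) so reflect to make 0 impossible.
        kappa = 1.0 - rng.uniform(0.0, 1.0, n)
    else:
        raise ConfigurationError(f"unknown kappa_dist {kappa_dist!r}")
    return InputPopulation(po, kappa, reference_rate)
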