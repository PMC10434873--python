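"""Circular statistics and tuning/weight analyses of simulation records.

Preferred orientation (PO) and selectivity of a tuning curve c(theta) are
read off the doubled-angle circular resultant

    R = sum_theta c(theta) * exp(2i*theta) / sum_theta c(theta),

whose angle (halved) is the PO and whose length |R| in [0, 1] is the
selectivity (0 = untuned, 1 = all response in one bin).  Tuning curves are
estimated from the last 500 stimuli of a run, binned into 20 orientation
bins.  On top of that this module provides the delta-PO correlation
analyses, the per-input pre/post activity correlations, the active-input
decomposition of the total input current, and the weighted-sum estimate of
the postsynaptic PO.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError
from .orientation import circular_mean_orientation, delta_po, wrap_orientation
from .population import InputPopulation, tuning_rate
from .protocol import SimulationRecord

__all__ = [
    "TuningEstimate",
    "ActiveInputSummary",
    "circular_resultant",
    "estimate_tuning",
    "delta_po",
    "weight_vs_dpo_correlation",
    "pre_post_activity_correlation",
    "active_input_decomposition",
    "ensemble_active_curves",
    "estimate_po_from_weighted_sum",
]

_SEL_EPS = 1e-12


def circular_resultant(curve_values, bin_centers):
    """PO and selectivity of a non-negative tuning curve.

    Returns ``(preferred_orientation, selectivity)``; the PO is NaN when the
    resultant vanishes (perfectly symmetric curve), never silently 0.
    """
    c = np.asarray(curve_values, dtype=float)
    theta = np.asarray(bin_centers, dtype=float)
    if c.shape != theta.shape or c.ndim != 1:
        raise ValueError("curve_values and bin_centers must be equal-length 1-d")
    if np.any(c < 0):
        raise ValueError("curve values must be non-negative")
    total = c.sum()
    if total <= 0:
        raise UndefinedStatisticError("all-zero tuning curve has no resultant")
    z = np.sum(c * np.exp(2j * theta)) / total
    selectivity = float(abs(z))
    po = wrap_orientation(0.5 * np.angle(z)) if selectivity > _SEL_EPS else float("nan")
    return po, selectivity


@dataclass(frozen=True)
class TuningEstimate:
    """Binned tuning curve with its circular-resultant summary.

    ``mean_rate_per_bin`` is NaN for bins no stimulus fell into; those bins
    are excluded from the resultant sums.
    """

    bin_centers: np.ndarray
    mean_rate_per_bin: np.ndarray
    preferred_orientation: float
    selectivity: float


def estimate_tuning(record: SimulationRecord, target="output", n_bins=20, last_k=500):
    """Estimate a neuron's tuning curve from the tail of a simulation.

    ``target`` is ``"output"`` for the postsynaptic neuron or an input-neuron
    index.  The last ``last_k`` (stimulus, rate) pairs are binned into
    ``n_bins`` orientation bins and averaged within bins.
    """
    if record.n_stimuli < last_k:
        raise ValueError(f"record has {record.n_stimuli} stimuli, fewer than last_k={last_k}")
    thetas = record.stimulus_sequence[-last_k:]
    if target == "output":
        rates = record.per_stimulus_output_rate[-last_k:]
    else:
        rates = record.per_stimulus_input_rates[-last_k:, int(target)]
    edges = np.linspace(-np.pi / 2, np.pi / 2, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(thetas, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=rates, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mean_rate = np.full(n_bins, np.nan)
    occupied = counts > 0
    mean_rate[occupied] = sums[occupied] / counts[occupied]
    if mean_rate[occupied].sum() <= 0:  # silent neuron: no resultant
        return TuningEstimate(centers, mean_rate, float("nan"), float("nan"))
    po, sel = circular_resultant(mean_rate[occupied], centers[occupied])
    return TuningEstimate(centers, mean_rate, po, sel)


def _pair_weights(record: SimulationRecord, weights=None) -> np.ndarray:
    """Per-neuron weights: synapse weights summed over each neuron's contacts."""
    w = record.final_weights if weights is None else np.asarray(weights, dtype=float)
    return np.bincount(record.population.synapse_neuron, weights=w,
                       minlength=record.population.size)


def weight_vs_dpo_correlation(records, use_pair_weights=False):
    """Pearson correlation between final weights and |delta PO| pooled over runs.

    Each run's postsynaptic PO comes from its estimated output tuning curve;
    runs whose output neuron is unselective (undefined PO) are skipped.
    Under the variance rule this correlation is ~0 (weights depend on kappa
    only); under the covariance rule it is negative.
    """
    ws, dpos = [], []
    for rec in records:
        post_po = estimate_tuning(rec).preferred_orientation
        if np.isnan(post_po):
            continue
        pre_po = rec.population.preferred_orientation
        if use_pair_weights:
            ws.append(_pair_weights(rec))
            dpos.append(np.abs(delta_po(pre_po, post_po)))
        else:
            syn = rec.population.synapse_neuron
            ws.append(rec.final_weights)
            dpos.append(np.abs(delta_po(pre_po[syn], post_po)))
    w = np.concatenate(ws)
    d = np.concatenate(dpos)
    if w.size < 2 or np.std(w) == 0 or np.std(d) == 0:
        raise UndefinedStatisticError("degenerate variance; correlation undefined")
    return float(stats.pearsonr(w, d).statistic)


def pre_post_activity_correlation(record: SimulationRecord, last_k=500):
    """Per-input Pearson correlation between input and output rates over stimuli.

    Returns an array of length ``population.size``; inputs (or an output)
    with constant rate series get NaN.
    """
    r = record.per_stimulus_input_rates[-last_k:]
    y = record.per_stimulus_output_rate[-last_k:]
    r_c = r - r.mean(axis=0)
    y_c = y - y.mean()
    denom = np.sqrt((r_c**2).sum(axis=0) * (y_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (r_c * y_c[:, None]).sum(axis=0) / denom
    # constant series (to within float rounding of the mean) have no correlation
    constant = np.ptp(r, axis=0) == 0
    corr[constant | ~np.isfinite(corr)] = np.nan
    if np.ptp(y) == 0:
        corr[:] = np.nan
    return corr


@dataclass(frozen=True)
class ActiveInputSummary:
    """Active-input decomposition of the drive, per stimulus and binned.

    An input counts as active for a stimulus when its rate strictly exceeds
    ``threshold = multiplier * r_ref/(2*pi)`` (so a flat kappa=0 input, whose
    rate equals the base threshold exactly, is never active at multiplier 1).
    ``delta`` is the wrapped difference between each stimulus and the run's
    estimated postsynaptic PO; ``curve`` holds bin means of the three
    quantities against delta.
    """

    threshold: float
    delta: np.ndarray
    n_active: np.ndarray
    mean_active_weight: np.ndarray
    total_input_current: np.ndarray
    curve: pd.DataFrame
    postsynaptic_po: float


def active_input_decomposition(
    record: SimulationRecord,
    threshold_multiplier=1.0,
    last_k=500,
    n_bins=20,
    include_inhibition=False,
):
    """Split the per-stimulus drive into active-input count and mean weight.

    ``total_input_current`` is the excitatory sum w_ref * sum_i w_i r_i (nA*Hz
    under the model's unit convention); ``include_inhibition`` adds the
    constant inhibitory term w_inh * r_inh.
    """
    pop = record.population
    beta = pop.reference_rate / (2 * np.pi)
    threshold = threshold_multiplier * beta
    thetas = record.stimulus_sequence[-last_k:]
    rates = record.per_stimulus_input_rates[-last_k:]  # (k, size)
    weights = record.weight_trajectory[-last_k:]  # (k, n_syn)
    syn = pop.synapse_neuron

    active = rates > threshold  # strict: at-threshold inputs are inactive
    n_active = active.sum(axis=1)
    active_syn = active[:, syn]
    with np.errstate(invalid="ignore"):
        mean_active_weight = np.where(
            active_syn.any(axis=1),
            (weights * active_syn).sum(axis=1) / active_syn.sum(axis=1),
            np.nan,
        )
    current = record.neuron.w_ref * (weights * rates[:, syn]).sum(axis=1)
    if include_inhibition:
        current = current + record.neuron.w_inh * record.neuron.r_inh

    post_po = estimate_tuning(record, n_bins=n_bins, last_k=last_k).preferred_orientation
    delta = wrap_orientation(thetas - post_po)

    edges = np.linspace(-np.pi / 2, np.pi / 2, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(delta, edges) - 1, 0, n_bins - 1)
    frame = pd.DataFrame(
        {
            "bin": idx,
            "n_active": n_active,
            "mean_active_weight": mean_active_weight,
            "total_input_current": current,
        }
    )
    binned = frame.groupby("bin").mean().reindex(range(n_bins))
    curve = pd.DataFrame(
        {
            "delta": centers,
            "n_active": binned["n_active"].to_numpy(),
            "mean_active_weight": binned["mean_active_weight"].to_numpy(),
            "total_input_current": binned["total_input_current"].to_numpy(),
        }
    )
    return ActiveInputSummary(
        threshold=threshold,
        delta=delta,
        n_active=n_active,
        mean_active_weight=mean_active_weight,
        total_input_current=current,
        curve=curve,
        postsynaptic_po=post_po,
    )


def ensemble_active_curves(records, threshold_multiplier=1.0, last_k=500, n_bins=20):
    """Average the per-run active-input curves across an ensemble.

    Each run's curve is already expressed against the wrapped distance to its
    own postsynaptic PO, so runs with heterogeneous POs can be pooled
    directly; the ensemble curves peak at delta = 0 when activity is biased
    toward the postsynaptic preference.
    """
    curves = []
    for rec in records:
        summary = active_input_decomposition(rec, threshold_multiplier, last_k, n_bins)
        if np.isnan(summary.postsynaptic_po):  # silent output neuron: no alignment
            continue
        curves.append(summary.curve)
    if not curves:
        raise UndefinedStatisticError("no record has a defined postsynaptic PO")
    stacked = pd.concat(curves).groupby("delta", as_index=False).mean()
    return stacked


def estimate_po_from_weighted_sum(
    population: InputPopulation, weights, override="none", n_grid=720
):
    """Postsynaptic PO predicted from the weighted sum of input tuning curves.

    Builds sum_i w_i r_i(theta) on a dense grid and takes its circular
    resultant.  ``override`` replaces the weights by 1 (``"unit_weights"``),
    the widths by 1 (``"unit_kappa"``), or both (``"both"``), to separate the
    contributions of weights, selectivity and PO layout.  Multi-contact
    weights are first summed per neuron.
    """
    if override not in ("none", "unit_weights", "unit_kappa", "both"):
        raise ValueError(f"unknown override {override!r}")
    w = np.asarray(weights, dtype=float)
    if w.size == population.n_synapses and population.n_synapses != population.size:
        w = np.bincount(population.synapse_neuron, weights=w, minlength=population.size)
    if w.size != population.size:
        raise ValueError("weights length must match population (neurons or contacts)")
    kappa = population.kappa
    if override in ("unit_weights", "both"):
        w = np.ones(population.size)
    if override in ("unit_kappa", "both"):
        kappa = np.ones(population.size)
    if not np.any(w > 0):
        raise UndefinedStatisticError("all-zero weights; weighted-sum PO undefined")
    grid = np.linspace(-np.pi / 2, np.pi / 2, n_grid, endpoint=False)
    curve = (
        w[None, :]
        * tuning_rate(
            grid[:, None],
            population.preferred_orientation[None, :],
            kappa[None, :],
            population.reference_rate,
        )
    ).sum(axis=1)
    po, _ = circular_resultant(curve, grid)
    return po
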