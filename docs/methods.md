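# Methods

## Model

One rate-based output neuron receives N excitatory inputs and a constant
untuned inhibitory drive. The output rate y follows

    tau_y dy/dt = -y + alpha [ w_ref sum_i w_i r_i(theta) + w_I r_I ]_+

with rectification inside the bracket, and each input fires according to a
von Mises tuning curve of period pi,

    r_i(theta) = r_ref exp(kappa_i cos 2(theta - theta_i^P)) / (2 pi I0(kappa_i)).

The I0 normalization makes every input's stimulus-averaged rate equal to
r_ref/(2 pi) regardless of kappa, so the population is heterogeneous in
selectivity but homogeneous in mean drive. Orientations are represented in
the half-open interval [-pi/2, pi/2), which gives every orientation exactly
one representative (the closed interval would double-count +-pi/2); signed
orientation differences are wrapped to (-pi/2, pi/2] with the boundary
reported as +pi/2.

### Plasticity

* **Variance rule** (default): dw_i/dt = eta1 (r_i/r_ref - mu)^2 - eta0 w_i.
  The drift depends on presynaptic activity only. Because it is linear in w
  with stimulus-dependent forcing, its stimulus-averaged fixed point has the
  closed form E[W_i] = (eta1/eta0)(I0(2 kappa_i)/I0(kappa_i)^2 - 1)/(4 pi^2),
  strictly increasing in kappa_i and zero at kappa_i = 0. This closed form
  is the package's primary oracle: simulations must collapse onto it.
  Starting from non-negative weights the rule cannot cross zero (the drift
  at w = 0 is non-negative), so no clipping is applied.
* **Covariance rule** (control): dw_i/dt = eta1 (r_i/r_ref - gamma)
  (y/r_ref - gamma) - eta0 w_i. This Hebbian-style product can drive weights
  negative; since the inputs are excitatory, weights are floored at 0 after
  each update. Whether the original formulation floors is not documented;
  this is our choice and is confined to the covariance control.
* **Frozen rule**: zero drift, for no-plasticity controls.

### Parameters (defaults)

| parameter | value | units | meaning |
|---|---|---|---|
| N | 50 | – | input population size |
| r_ref | 125 | Hz | tuning-curve rate scale (mean rate r_ref/2pi ≈ 19.9 Hz) |
| kappa | U]0, 1] | – | tuning width, drawn per neuron |
| theta^P | U[-pi/2, pi/2) | rad | preferred orientation, drawn per neuron |
| tau_y | 1e-3 | s | output rate time constant |
| alpha | 0.1 | 1/nA | transfer-function slope |
| w_ref | 16 | nA | excitatory reference weight |
| w_I | -1.7 | nA | inhibitory weight (stored in nA for uniform units) |
| r_I | 100 | Hz | inhibitory rate |
| eta1, eta0 | 0.1, 0.03 | 1/s | potentiation and decay rates |
| mu | 1/(2 pi) | – | mean normalized presynaptic rate |
| gamma | 0.24 | – | covariance-rule offset |
| T | 0.2 | s | stimulus duration |
| n_stimuli | 1000 | – | stimuli per run |
| warm-up | 200 s at 20 Hz | | untuned pre-stimulation phase |

All times are stored in seconds. eta1 and eta0 are interpreted as
per-second rates: with eta0 = 0.03/s the weight relaxation time constant is
~33 s, so weights converge within the 200 s warm-up and the 200 s protocol,
consistent with the trajectories the model is meant to produce. The
interpretation matters only through this time scale.

## Protocol and integration

A run is: warm-up (all inputs at 20 Hz, plasticity active), then 1000
stimuli, each drawn uniformly from [-pi/2, pi/2) and held for T = 200 ms.
Two integration modes must agree (tested to 2% per synapse):

* **fast** (default): because tau_y << T, the output rate within a stimulus
  is taken as the steady-state drive given the weights at stimulus onset,
  and the weight ODE — linear in w with constant coefficients over the
  stimulus — is relaxed *exactly* toward its per-stimulus fixed point
  (exp(-eta0 T) decay factor). For the variance rule this is exact; for the
  covariance rule it freezes y within each stimulus, a good approximation
  since weights move on a ~33 s time scale.
* **euler**: forward-Euler steps of y and w at dt = 1 ms.

Initial weights default to 0: the warm-up drives every weight to the
analytic fixed point (eta1/eta0)(20/125 - 1/2pi)^2 ≈ 2.38e-6 regardless of
initialization (a uniform U(0, 0.05) initialization variant is provided and
converges to the same state). The output rate is integrated continuously
across stimulus boundaries in euler mode; in fast mode the question does not
arise. Weights are recorded once per stimulus (at stimulus end) to bound
memory.

Ensembles derive per-run seeds as (base_seed * 1000003 + run) mod 2^31, so
runs are order-independent and individually reproducible; each run samples a
fresh population and stimulus stream.

## Analyses

* **Tuning estimate**: mean response in 20 orientation bins over the last
  500 stimuli; PO and selectivity are the angle (halved) and length of the
  doubled-angle circular resultant. Empty bins are excluded from the
  resultant sums rather than zero-filled (zero-filling would bias the
  resultant); with 500 stimuli over 20 bins empties are rare. A curve with
  vanishing resultant has no PO: it is reported as NaN, never silently 0.
  A fully silent neuron likewise yields NaN (this occurs in a minority of
  variance-rule runs — the strong-inhibition regime can leave the output
  below threshold everywhere — and such runs are excluded from analyses
  that align by postsynaptic PO).
* **Active-input decomposition**: an input is active for a stimulus when its
  rate strictly exceeds beta = r_ref/(2 pi) (times an optional multiplier
  0.5 or 1.5). The strict inequality matters only for the flat kappa = 0
  curve, which sits exactly at beta and counts as inactive. The total input
  current is the excitatory sum w_ref sum_i w_i r_i; including the constant
  inhibitory term is available via a flag but off by default since it only
  shifts the curve. Per-run curves are expressed against the wrapped
  distance between the stimulus and that run's estimated postsynaptic PO,
  then averaged across runs, which pools runs with heterogeneous POs.
* **Weighted-sum PO estimate**: the postsynaptic PO predicted from
  sum_i w_i r_i(theta) on a dense grid, with overrides that replace weights
  and/or widths by 1 to separate their contributions.

## Decoding

Responses are Poisson draws with mean r_i(theta) by default; variants add
Gaussian rate noise (sd 5 Hz; negative values are used as-is, since the
resultant estimator is defined for any reals — a flooring option exists) or
evaluate each tuning curve at theta + sigma_i with per-neuron offsets
sigma_i ~ N(0, pi/50) fixed across trials and no further trial noise.

The estimator is theta_hat = 1/2 atan2(sum p_i w_i sin 2 theta_i^P,
sum p_i w_i cos 2 theta_i^P) — the two-argument arctangent resolves the
quadrant ambiguity of the printed arctan-of-ratio form. Test orientations
are 20 points covering the period once (-pi/2 inclusive, pi/2 exclusive;
duplicating the endpoint would double-weight one stimulus). Per
orientation, bias is the circular (period-pi) mean of the wrapped
deviations theta_hat - theta across 100 trials, variance averages the
squared re-wrapped deviations from that mean, and error = variance +
bias^2 exactly; without wrapping, estimates near +-pi/2 would register
spurious ~pi errors. Run-level scores average |bias|, variance and error
over the orientation grid. Trials with a vanishing resultant (possible
only in contrived symmetric cases) are excluded and counted.

The five schemes share the same noisy responses within a population
(matched noise), which removes trial noise from scheme comparisons.

## What the generator emulates — and does not

The sampled populations and stimulus streams *are* the study conditions:
independently drawn POs and widths, uniform (or normal, sd pi/8) PO
distributions, uniform stimuli, Poisson spiking variability. They do not
emulate contrast or spatial structure, correlated noise between neurons,
direction (as opposed to orientation) selectivity, spiking dynamics, or
plastic inhibition. Passing tests therefore validate the model's internal
consistency and its closed-form theory, not fidelity to any particular
biological dataset.

## Problem sizes

The test suite and acceptance script run 10-run plasticity ensembles
(500 synapses pooled), 20-population decoder benchmarks (20 orientations x
100 trials each), and 3-run multi-contact ensembles — sizes at which the
qualitative results are stable while the whole suite runs in seconds on one
CPU. Two caveats at these sizes, documented because they reflect the model
rather than sampling error:

* Under the variance rule the pooled weight-vs-|dPO| correlation is weakly
  *negative*, not zero. Weights depend only on kappa, but the postsynaptic
  PO is itself pulled toward the high-kappa (hence high-weight) inputs —
  the same coupling the weighted-sum PO analysis demonstrates — so strong
  synapses sit at systematically smaller |dPO|. The effect is small but
  does not vanish with more runs.
* Per-population decoder error is heavy-tailed: occasional populations with
  clustered high-kappa POs produce large systematic bias for every scheme,
  and they dominate ensemble means. Mean-error comparisons between the
  variance-rule and ML decoders are therefore noisy at small ensemble
  sizes, with the variance-rule decoder's mean error hovering around 10%
  above the ML decoder's; the orderings against the uniform, shuffled and
  covariance decoders are robust.

## Known limitations

* The covariance-rule floor at zero weight is a modeling choice; alternate
  treatments (soft bounds, no bound) are not implemented.
* The fast mode's frozen-y approximation within a stimulus is specific to
  tau_y << T; protocols violating that should use euler mode.
* The dimensional bookkeeping of the output equation (alpha in 1/nA acting
  on nA·Hz yielding Hz) is taken as a convention, not resolved.
* Selectivity of the output neuron depends strongly on the inhibition
  level; the provided population-size variants rescale r_I (1000 Hz, 200 Hz
  and 15 Hz for N = 1000, 100 and 10) and a weak-inhibition variant scales
  w_I by 1/5.
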