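# presynvar

A simulation and analysis toolkit for a feedforward model of primary visual
cortex in which synaptic weights track **presynaptic selectivity** rather
than pre/post activity covariance, and for the population decoders that such
weights support.

## The scientific question

Classic Hebbian plasticity predicts that synapses between neurons with
similar preferred orientation (PO) should be strong. Some experiments
instead suggest that a postsynaptic neuron's orientation preference is set
by *how many* inputs a stimulus activates, while individual synaptic
strengths correlate with how *sharply tuned* the presynaptic neuron is —
independent of pre/post tuning similarity. This package implements a rate
model that realizes that regime and asks what it costs, or buys, for
decoding.

## The model

A single rectified-linear output neuron receives N = 50 von Mises-tuned
inputs plus fixed untuned inhibition:

    tau_y dy/dt = -y + alpha [ w_ref * sum_i w_i r_i(theta) + w_I r_I ]_+
    r_i(theta)  = r_ref exp(kappa_i cos 2(theta - theta_i^P)) / (2 pi I0(kappa_i))

Weights follow the **variance rule** — potentiation driven only by the
squared deviation of the presynaptic normalized rate from its mean
mu = 1/(2 pi), plus decay:

    dw_i/dt = eta_1 (r_i/r_ref - mu)^2 - eta_0 w_i

Averaging the per-stimulus fixed point over uniform stimuli gives the
closed-form equilibrium, used throughout as an analytic oracle:

    E[W_i] = (eta_1/eta_0) [ I0(2 kappa_i)/I0(kappa_i)^2 - 1 ] / (4 pi^2)

— a strictly increasing function of the tuning width kappa_i alone. A
classic covariance (Hebbian) rule is included as a control, as is the
maximum-likelihood orientation decoder for Poisson responses,

    theta_hat = 1/2 atan2( sum_i p_i w_i sin 2 theta_i^P,
                           sum_i p_i w_i cos 2 theta_i^P ),   w_i = kappa_i,

and its arbitrary-weight generalization (variance-rule / uniform / shuffled
/ covariance weights), scored by wrapped bias, trial variance and error
(= variance + bias^2) over a grid of test orientations.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from presynvar import (PlasticityParams, sample_population, run_simulation,
                       equilibrium_weight)

pop = sample_population(50, seed=1)                  # POs ~ U[-pi/2, pi/2), kappa ~ U]0, 1]
record = run_simulation(pop, PlasticityParams("variance"), seed=2)

print(f"warm-up weight      : {record.warmup_final_weights[0]:.3e}")
rho = spearmanr(record.final_weights, pop.kappa).statistic
print(f"weight~kappa Spearman: {rho:.4f}")
for k in (0.25, 0.5, 1.0):
    print(f"equilibrium w(kappa={k}): {equilibrium_weight(k):.5f}")
```

prints

```
warm-up weight      : 2.375e-06
weight~kappa Spearman: 0.9988
equilibrium w(kappa=0.25): 0.00261
equilibrium w(kappa=0.5): 0.01008
equilibrium w(kappa=1.0): 0.03564
```

The warm-up (200 s of untuned 20 Hz input) parks every weight at the
analytic fixed point (eta1/eta0)(20/125 - 1/2pi)^2 ≈ 2.38e-6; after 1000
stimuli the weights have converged onto the equilibrium curve — rank
correlation with kappa ≈ 0.999 — so synaptic strength encodes presynaptic
selectivity, not pre/post similarity.

## Command line

```sh
presynvar theory -o theory.csv                   # closed-form w(kappa) curve
presynvar reproduce fig1_3_main -o out/main      # plasticity ensemble + analyses
presynvar reproduce fig4_decoding -o out/dec     # 5-decoder benchmark
presynvar simulate -c my_config.yml -o out/run   # custom configuration
```

Experiment ids cover the main simulation and its variants (covariance rule,
weak inhibition, population-size scaling, uniform weight initialization,
normal PO distribution, activity-threshold multipliers, decoder-noise
variants, multi-contact pairs). Every output directory contains a
`manifest.json` tracing all CSVs to the (config, seed) pair; re-running
reproduces them bit-identically.

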