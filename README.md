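# autovi

Automated black-box variational inference with robust stochastic
optimization. The library fits a variational approximation (mean-field
Gaussian by default) to an unnormalized target density by running
fixed-learning-rate stochastic optimization in epochs:

1. **Optimize** at a fixed learning rate with an averaged adaptive method
   (`avg_adam` by default), treating the iterates as a Markov chain.
2. **Detect stationarity** with an adaptively windowed worst-coordinate
   split-R-hat criterion.
3. **Average iterates** until a Monte-Carlo-standard-error gate certifies
   the average is accurate relative to the posterior scale, with gate
   checks scheduled geometrically by the measured optimization/check cost
   ratio.
4. **Estimate accuracy**: the closed-form symmetrized KL divergence between
   successive epoch averages feeds a small weighted Bayesian regression
   that predicts the divergence to the (unreachable) optimum.
5. **Terminate** when the predicted accuracy gain from halving the learning
   rate is no longer worth the predicted extra iterations (inefficiency
   index exceeding a user threshold), leaving the user a single intuitive
   accuracy knob `xi`.

A suite of synthetic Gaussian targets with structured covariances
(identity, diagonal, uniform/banded correlation, spiked variants) is built
in for validation, along with closed-form oracles (optimal mean-field
approximation, exponential tail-control scale) and accuracy metrics.

## Library usage

```python
import numpy as np
from autovi import RABVIConfig, run_rabvi, make_gaussian_target, \
    optimal_mean_field, skl

target = make_gaussian_target("diag", d=100)
result = run_rabvi(target, RABVIConfig(xi=0.1, seed=1))
print(result.status, result.total_iters)
print(np.sqrt(skl(result.final_params(), optimal_mean_field(target))))
```

Custom targets implement the `TargetDistribution` contract: a dimension, a
vectorized unnormalized log-density, and (ideally) its gradient.

## Command line

```sh
# run the optimizer on a built-in target
autovi fit --target gaussian:diag:d=100 --xi 0.1 --seed 1 --out result.json

# recompute chain diagnostics from a saved trace (CSV, iterations x params)
autovi diagnose --trace trace.csv --wmin 200

# summarize a results file
autovi report result.json
```

`fit` accepts a flat YAML config file via `--config`; explicit flags
override file values. Targets can also be loaded from plugins with
`--target my_module:my_target`.

## Tests and acceptance report

```sh
python -m pytest tests/            # full suite (~6-8 minutes)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities from scratch
(tail-control constant, scheduling constants, worst-case gate error
factors, and the accuracy of the full pipeline at termination on the
d=100 diagonal Gaussian target over 5 seeds) and writes them as JSON.

## Package layout

- `autovi.targets` — target contract, synthetic Gaussian suite, oracles,
  accuracy metrics
- `autovi.families` — mean-field and full-rank Gaussian families with
  closed-form symmetrized KL
- `autovi.gradients` — reparameterization gradient of the KL objective
- `autovi.optimizers` — SGD / RMSProp / Adam and averaged variants
- `autovi.diagnostics` — split-R-hat, adaptive window search, ESS, MCSE
- `autovi.epoch` — one fixed-learning-rate epoch (detection, gate,
  check scheduling)
- `autovi.regression` — SKL-gap regression, iteration model, termination
  rule
- `autovi.driver` — outer loop, configuration, results serialization
- `autovi.cli` — `autovi` console entry point
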