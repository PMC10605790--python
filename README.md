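# bpsurv — Bayesian parametric survival models

`bpsurv` fits Bayesian parametric survival models for medical
time-to-event data: predicting, with uncertainty, how long until an event
(death, recurrence, device failure) for an individual subject, from
right-censored cohorts of a few hundred patients. It is aimed at
biostatisticians and ML practitioners who need three things conventional
survival models do not give them together: built-in regularization for
small cohorts, a full posterior (hence honest uncertainty bands on every
survival curve), and the ability to update a deployed model at a new
institution **without the original training data**.

## The model

Survival times follow an Exponential or Weibull distribution in the rate
parameterization,

    S(t) = exp(-λt)           (Exponential)
    S(t) = exp(-(λt)^κ)       (Weibull; κ=1 recovers the Exponential)

where 1/λ is the time by which 63.2% of subjects have had the event and κ
says whether the hazard rises (κ>1) or falls (κ<1). The distribution
parameters come from a predictor function of the covariates x,

    λ = exp(θ₀ + θ₁x₁ + … + θₙxₙ)            (linear)
    λ = exp(W^L a^{L-1} + b^L),  a^l = tanh(W^l a^{l-1} + b^l)   (neural network)

with independent Normal(0, σ) priors on all coefficients (σ = 1 by
default, acting as regularization). The censored likelihood uses the log
density for observed events and log S(t) for censored subjects. Posteriors
are sampled by ensemble MCMC (emcee's affine-invariant sampler with
differential-evolution moves), with split-R̂/ESS diagnostics via ArviZ.

**Updating by Bayes rule:** a fitted model is summarised by per-parameter
Normal(mean, SD) marginals; those become the priors of a fresh fit on new
data only. Prior widening (`widen > 1`) makes an over-confident model
movable again. The package also ships the surrounding machinery: Harrell's
C-index, train-minus-test overfitting gap, mutual-information feature
selection, cross-validated tuning, HDI/ROPE equivalence decisions, the
KDE overlap index (OVI) between posteriors, and a synthetic-cohort
generator with known ground truth.

## Worked example

```python
import numpy as np
from bpsurv import ModelSpec, fit, predict_survival, simulate_survival

data, truth = simulate_survival(
    400, [np.log(0.4), 0.8], distribution="weibull", kappa=1.5,
    censoring={"mode": "administrative", "target_frac": 0.3}, seed=1)
posterior = fit(ModelSpec("weibull", "linear"), data,
                sampler_config={"tune": 600, "draws": 400, "thin": 2, "seed": 1})
print(posterior.summary().round(3))
```

prints

```
                  mean     sd   rhat      ess
lam_intercept   -0.886  0.041  1.029  276.629
lam_x0           0.821  0.056  1.025  295.163
kappa_intercept  0.356  0.050  1.041  235.079
```

— the log-rate intercept and covariate effect (truth: −0.916 and 0.8) and
log κ (truth: log 1.5 ≈ 0.405), each with posterior SD and convergence
diagnostics. Predicting two subjects one SD below/above the covariate
mean:

```python
curves = predict_survival(posterior, np.array([[-1.0], [1.0]]), np.linspace(0, 6, 7))
```

gives `S(2) = 0.79 ± 0.02` for the low-risk subject versus
`S(2) = 0.09 ± 0.02` for the high-risk one — the ± SD band is the model's
uncertainty about each survival curve. The `examples/` directory has
narrative scripts for each capability: fitting and prediction
(`fit_and_predict.py`), the data-free cross-site update
(`update_across_sites.py`), the evaluation pipeline with feature selection
and tuning (`evaluate_pipeline.py`), and the streaming full-retrain vs
update experiment (`streaming_update_experiment.py`).

A thin CLI mirrors the workflow
(`bpsurv simulate | fit | predict | update | evaluate | tune | ovi`);
model files are versioned JSON holding the spec and per-parameter
posterior summaries, which is all an update needs.

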