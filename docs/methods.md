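# Methods

## Model

A subject's survival time T follows Exponential(λ) or Weibull(λ, κ) in the
**rate parameterization**: S(t) = exp(−λt) or S(t) = exp(−(λt)^κ). λ is an
inverse scale (higher λ = earlier events; 1/λ is the 63.2% event-probability
time) and κ the shape. Many libraries use scale = 1/λ instead; the public
API is rate-form throughout, and conversions are one reciprocal away.
κ = 1 collapses the Weibull onto the Exponential, which the test suite uses
as an exact (1e−12) consistency oracle.

Distribution parameters come from covariates through a predictor whose
output is exponentiated to guarantee positivity:

* **linear** — λ = exp(θ·[1, x]); the intercept column is prepended
  internally, callers never supply it.
* **nn** — a tanh feed-forward network; hidden layers a^l = tanh(W^l a^{l−1}
  + b^l), output layer exponentiated. The output width equals the number of
  distribution parameters being predicted.

The Weibull shape is, by default, a single shared κ = exp(θ_κ0)
(`kappa_mode="intercept_only"`); `"covariate"` runs the full predictor for
κ as well (for the nn predictor this becomes a second output head).

**Likelihood.** Right-censored subjects contribute log S(t_i) — their true
event time exceeds the observation time. Event subjects contribute the log
density of the named distribution (log hazard + log survival); the model
statement T ∼ Dist(λ) leaves no other coherent choice, and the
censored-Exponential MLE #events/Σt is recovered by a grid-search oracle in
the tests. All likelihood code works on the log scale
(log λ, log κ) so extreme coefficient proposals underflow to −∞ rather than
producing NaNs.

**Priors.** Independent Normal(0, prior_sd) on every coefficient, weight
and bias; prior_sd defaults to 1 (weakly informative, acting as
regularization on small cohorts) and is the main tuning hyperparameter
(searched over (0.1, 10) by `cv_tune`).

## Inference

Posteriors are drawn by **ensemble MCMC**: emcee's affine-invariant sampler
with a 0.8/0.2 mixture of differential-evolution and snooker moves, which
mixes markedly better than stretch moves on these correlated posteriors.
The package's models have flat parameter counts in the 2–30 range, well
inside the regime where ensemble samplers are reliable. Walkers are
reported as chains: `SamplerConfig(chains, tune, draws, thin, seed)` maps
to `max(2p+2, chains, 8)` walkers, `tune` discarded burn-in steps, and
enough retained (optionally thinned) steps to total ≈ `chains × draws`
draws. `target_accept` is accepted for interface compatibility but has no
ensemble analogue and is ignored. Defaults are 4 chains / 1000 tune / 1000
draws. Split-R̂ and ESS are computed with ArviZ; R̂ > 1.01 raises a
*warning*, never an error, so unattended replicate loops and CV runs
proceed with diagnostics attached to the Posterior. A fixed seed reproduces
draws bit-for-bit (the test suite asserts byte-identical model files).

Note the NN posterior is inherently multimodal (tanh sign-flip and
neuron-permutation symmetries), so per-weight R̂ can be large even when
predictive quantities are stable; convergence should be judged on
identified quantities (predictions, κ), which is also how the recovery
simulations score it.

**Prediction.** For each retained draw, λ (and κ) are computed for the new
subjects and S(t) is evaluated on the requested grid; curves are summarised
by the pointwise mean and SD, with a mean ± SD band clipped to [0, 1] as
the default uncertainty display (central quantile bands are available via
`band="quantile"`). Risk scores for ranking metrics are the posterior-mean
rate (Exponential) or the negative posterior-mean median survival time
(ln 2)^{1/κ}/λ generally — monotone transforms of each other in the
Exponential case, so the C-index is unaffected by the choice.

## Updating

`posterior_to_priors` summarises each scalar parameter by its marginal
posterior (mean, SD) and returns Normal priors — optionally widened by a
factor — and `update` refits on the new data alone. This deliberately
discards posterior correlations (only marginal summaries travel in the
model file); the information loss is observable through `ovi_report`, the
per-parameter KDE overlap between two fits. The same recipe applies
uniformly to NN weights. The streaming experiment
(`run_updating_experiment`) implements the two strategies being compared:
full retraining (all past partitions pooled, non-informative priors each
step) and updating (newest partition only, priors carried forward), each
step tested on the next partition by C-index. The update path never touches
earlier partitions — asserted by a recording-stub test — which is the
privacy contract that lets a model move between institutions.

## Diagnostics and decision statistics

* **HDI** — narrowest sorted-draw window holding the requested mass (exact
  for unimodal samples); requires ≥ 100 draws. Checked against Gaussian and
  Exponential closed forms and against ArviZ.
* **OVI** — ∫ min(KDE_a, KDE_b): Gaussian KDEs with Silverman bandwidth per
  sample, integrated on a 512-point grid spanning the pooled range ± 3
  pooled bandwidths. Values are reproducible only up to this bandwidth
  convention; the unit-shifted-normal closed form 2Φ(−½) ≈ 0.617 anchors it.
* **ROPE equivalence** — the HDI of a difference distribution against a
  region of practical equivalence (default [−0.01, 0.01] on the C-index
  scale, 98.33% credible level = 1 − 0.05/3): accepted iff the interval is
  fully inside, rejected iff fully outside, otherwise undecided;
  `pct_in_rope` is the fraction of interval length inside.
  `mean_difference_posterior` supplies the difference draws from replicate
  means (Student-t posterior under a Jeffreys-prior normal model),
  mirroring how replicate-level performance differences are normally
  analysed.
* **Sample size** — two-sided two-sample t-test by noncentral-t power
  inversion (statsmodels), rounded up; d = 0.02/0.025 at α = 0.0033 and
  power 0.8 gives 47 per group. Bonferroni helpers provide α/m and the
  m(m−1)/2 pairwise count.

## Evaluation pipeline

Harrell's C-index with explicit tie conventions: pairs with tied event
times are non-comparable; tied risk scores count ½; no comparable pairs
returns 0.5 with a warning. The implementation is vectorized O(n²) and is
tested against brute-force pair enumeration (n ≤ 50) and lifelines on
tie-free data. Normalization z-scores continuous columns with training
statistics only (binary/one-hot columns pass through); feature selection
ranks by nearest-neighbour mutual information (3 neighbours, seeded jitter)
between each feature and the indicator time > median(observed time) —
censoring is ignored at this ranking step, the simplest reading of
"mutual information with median survival"; a Kaplan–Meier-based median
would be a censoring-aware alternative but adds a model to the ranking
step. `cv_tune` runs seeded random search over prior_sd (log-uniform on
(0.1, 10)), k ∈ [1, n_features] and NN depth with event-balanced 5-fold CV
(folds reshuffled, with a warning, if a fold has no events); the strategy
is pluggable via a `search` callable for model-based optimisers. Pipeline
hygiene — nothing fitted on a fold sees its validation rows — is enforced
by constructing the normalizer and ranking inside the training fold and
tested by mutation of held-out rows.

## Synthetic cohorts

`simulate_survival` draws covariates (standard-normal continuous,
Bernoulli binary), sets λ_i = exp(θ·[1, x_i]) and inverts the survival
function: T = (−ln U)^{1/κ}/λ. Censoring is *administrative* (every subject
cut at a fixed time placed at the (1 − target) empirical quantile of the
drawn event times) or *uniform* (C ~ U(0, c) with c solved by root-finding
so the expected censored fraction hits the target); the achieved fraction
lands within ±0.05 of target for n ≥ 1000 and a warning reports misses.
Times of exactly zero (possible only with discretized inputs) are bumped to
half the smallest positive value. Each cohort returns a truth record
(θ, κ, censoring cutoff, seed) for recovery scoring.

What the generator emulates: cohort sizes (hundreds of subjects), ~20–40%
right-censoring, log-linear covariate effects, proportional-hazard-style
Weibull/Exponential event times. What it does not: covariate-dependent or
informative censoring, time-varying covariates, measurement error,
missingness, or model misspecification — so passing recovery tests shows
the machinery is correct and calibrated *under the model's own
assumptions*, not that the model fits any particular clinical dataset.

## Study conditions used in tests and the acceptance script

Recovery and equivalence checks use cohorts of n = 500 with coefficients
(log 0.5, 0.6, −0.4), 30% administrative censoring, 20 replicates per model
variant, scoring 94% HDI coverage of the truth (threshold 80%). For the NN
variant the individual weights are non-identified, so coverage is scored on
the baseline subject's median survival time and on κ. The updating
experiment uses n = 600 split into 6 partitions, 8 replicate streams, and
the ROPE decision at the 98.33% level on the mean C-index difference.
Sampler settings in these simulations are 600 burn-in / 400 kept steps with
thinning 2, which keep split-R̂ near 1.01 on the linear models while
allowing many replicates. The Veteran lung-cancer cohort (137 complete
cases, 8 variables, from the classic randomized trial distributed with the
R `survival` package) ships as a loader fixture.

## Known limitations

* Only right censoring; no left/interval censoring, competing risks or
  time-varying covariates; no Gompertz/log-normal/log-logistic families.
* Updating transports marginal Normal summaries, not the joint posterior;
  strongly correlated posteriors lose information (visible as low OVI after
  an update on identical data).
* Ensemble MCMC scales poorly beyond a few hundred parameters; the nn
  predictor is intended for small networks (1–2 hidden layers).
* The C-index treats tied event times as non-comparable; datasets with
  heavy time ties will score slightly differently under other conventions.
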