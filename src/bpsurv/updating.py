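"""Bayes-rule model updating: posterior -> prior -> refit on new data only.

An existing model is summarised by per-parameter Normal(mean, SD) marginals
of its posterior; those become the priors of a fresh fit on the new data.
No subject from the original training data is needed — the model file is
the only artifact exchanged. Widening the prior SDs makes an over-confident
model (trained on a very large sample) movable by a smaller update batch.
The Normal approximation discards posterior correlations; the overlap-index
diagnostic (:func:`bpsurv.diagnostics.overlap_index`) surfaces the effect.
"""

from __future__ import annotations

import numpy as np

from .data import SurvivalData
from .inference import Posterior, SamplerConfig, fit, predict_median_survival
from .models import ModelSpec
from .params import PriorSet


def posterior_to_priors(posterior, widen: float = 1.0) -> PriorSet:
    """Per-parameter Normal(posterior mean, widen * posterior SD) priors.

    ``posterior`` is anything with ``param_summaries()`` returning
    name -> (mean, sd) — a fitted :class:`Posterior` or a loaded model file.
    """
    if widen <= 0:
        raise ValueError("widen must be positive")
    summaries = posterior.param_summaries()
    names = list(summaries)
    mu = np.array([summaries[n][0] for n in names])
    sd = np.array([summaries[n][1] for n in names]) * widen
    if np.any(sd <= 0):
        bad = [n for n, s in zip(names, sd) if s <= 0]
        raise ValueError(f"degenerate posterior: zero SD for {bad[:5]}")
    return PriorSet(names=names, means=mu, sds=sd)


def update(
    old_posterior: Posterior,
    new_data: SurvivalData,
    widen: float = 1.0,
    sampler_config=None,
) -> Posterior:
    """Refit the old model's spec on new data with posterior-derived priors."""
    if new_data.n < 1:
        raise ValueError("updating requires at least one new subject")
    spec = old_posterior.spec
    if new_data.n_features != old_posterior.layout.n_features:
        raise ValueError(
            f"new data has {new_data.n_features} features, model expects "
            f"{old_posterior.layout.n_features} ({old_posterior.layout.feature_names})"
        )
    priors = posterior_to_priors(old_posterior, widen=widen)
    return fit(spec, new_data, priors=priors, sampler_config=sampler_config)


def partition_stream(
    data: SurvivalData,
    n_partitions: int,
    by: str = "random",
    seed: int | None = None,
) -> list[SurvivalData]:
    """Split a cohort into ordered partitions emulating data collected over time.

    ``by="random"`` shuffles with ``seed`` and splits into near-equal parts;
    ``by="column:<name>"`` (e.g. a year-of-enrollment variable) orders
    partitions by ascending column value, keeping input order within ties.
    """
    if n_partitions < 2 or n_partitions > data.n:
        raise ValueError("need 2 <= n_partitions <= n subjects")
    if by == "random":
        order = np.random.default_rng(seed).permutation(data.n)
    elif by.startswith("column:"):
        col = by.split(":", 1)[1]
        if col not in data.feature_names:
            raise ValueError(f"partition column {col!r} not among features {data.feature_names}")
        values = data.covariates[:, data.feature_names.index(col)]
        order = np.argsort(values, kind="stable")
    else:
        raise ValueError("by must be 'random' or 'column:<name>'")
    return [data.subset(np.sort(chunk)) if by == "random" else data.subset(chunk)
            for chunk in np.array_split(order, n_partitions)]


def run_updating_experiment(
    data_or_partitions,
    spec: ModelSpec,
    n_partitions: int | None = None,
    mode: str = "full_retrain",
    sampler_config=None,
    seed: int | None = None,
    return_models: bool = False,
):
    """Stream protocol: train on arriving partitions, test on the next one.

    At step k (1-based), the test set is partition k+1. In
    ``mode="full_retrain"`` the model is refitted from non-informative
    priors on partitions 1..k combined; in ``mode="update"`` only partition
    k is seen, with priors taken from step k-1's model (step 1 starts from
    non-informative priors, so both modes coincide there). Returns the test
    C-index per step (and the per-step models when ``return_models``).
    """
    from .evaluation import concordance_index
    from .data import SurvivalData as SD

    if mode not in ("full_retrain", "update"):
        raise ValueError("mode must be 'full_retrain' or 'update'")
    if isinstance(data_or_partitions, SD):
        if n_partitions is None or n_partitions < 3:
            raise ValueError("n_partitions >= 3 required")
        parts = partition_stream(data_or_partitions, n_partitions, seed=seed)
    else:
        parts = list(data_or_partitions)
        if len(parts) < 3:
            raise ValueError("need at least 3 partitions")

    cfg = SamplerConfig.resolve(sampler_config)
    trace: list[float] = []
    models: list[Posterior] = []
    previous: Posterior | None = None
    for k in range(1, len(parts)):
        test = parts[k]
        if mode == "full_retrain" or previous is None:
            if mode == "full_retrain":
                train = _concat(parts[:k])
            else:
                train = parts[k - 1]
            model = fit(spec, train, sampler_config=cfg)
        else:
            model = update(previous, parts[k - 1], sampler_config=cfg)
        risk = -predict_median_survival(model, test.covariates, max_draws=500).mean(axis=0)
        trace.append(concordance_index(test.times, test.events, risk))
        models.append(model)
        previous = model
    return (trace, models) if return_models else trace


def ovi_report(model_a, model_b, n_samples: int = 4000, seed: int = 0):
    """Per-parameter overlap index between two fitted models.

    Inputs are :class:`Posterior` objects or loaded model files; when only
    (mean, SD) summaries are available the marginal is sampled from its
    Normal approximation. Returns a DataFrame (parameter, ovi).
    """
    import pandas as pd

    from .diagnostics import overlap_index

    def draws_of(model, offset):
        if isinstance(model, Posterior):
            flat = model.flat(max_draws=n_samples, seed=seed + offset)
            return dict(zip(model.layout.scalar_names, flat.T))
        rng = np.random.default_rng(seed + offset)
        return {
            n: mu + sd * rng.standard_normal(n_samples)
            for n, (mu, sd) in model.param_summaries().items()
        }

    da, db = draws_of(model_a, 0), draws_of(model_b, 1)
    common = [n for n in da if n in db]
    if not common:
        raise ValueError("models share no parameters")
    return pd.DataFrame({
        "parameter": common,
        "ovi": [overlap_index(da[n], db[n]) for n in common],
    })


def _concat(parts: list[SurvivalData]) -> SurvivalData:
    return SurvivalData(
        times=np.concatenate([p.times for p in parts]),
        events=np.concatenate([p.events for p in parts]),
        covariates=np.vstack([p.covariates for p in parts]),
        feature_names=list(parts[0].feature_names),
        feature_kinds=list(parts[0].feature_kinds),
    )
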