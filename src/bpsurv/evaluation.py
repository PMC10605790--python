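"""Evaluation pipeline: concordance index, normalization, feature selection,
train/test splitting and cross-validated hyperparameter tuning.

The concordance index follows Harrell's conventions: a pair (i, j) is
comparable when t_i < t_j and subject i had the event (tied event times are
non-comparable); tied risk scores count 1/2. Any external model can be
evaluated through a risk-score callable (covariates -> scores, higher =
shorter expected survival).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalData
from .inference import Posterior, SamplerConfig, fit, posterior_params_for, predict_median_survival
from .models import EXPONENTIAL, ModelSpec


def concordance_index(times, events, risk_scores) -> float:
    """Harrell's C-index; 0.5 = random ranking, 1 = perfect.

    Returns 0.5 with a warning when no comparable pairs exist (e.g. all
    subjects censored).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    r = np.asarray(risk_scores, dtype=float)
    if not (t.shape == e.shape == r.shape):
        raise ValueError("times, events and risk_scores must have equal length")
    # comparable: t_i < t_j and the earlier subject had the event
    comp = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = int(comp.sum())
    if n_comp == 0:
        warnings.warn("no comparable pairs; returning 0.5")
        return 0.5
    greater = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    concordant = (comp & greater).sum() + 0.5 * (comp & tied).sum()
    return float(concordant / n_comp)


def risk_score(model: Posterior, X) -> np.ndarray:
    """Risk score per subject: higher = shorter predicted survival.

    For the exponential model this is the posterior-mean rate; generally it
    is the negative posterior-mean median survival time (a monotone
    transform of the rate, so C-index is unchanged for the exponential).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.spec.distribution == EXPONENTIAL:
        return posterior_params_for(model, X).lam.mean(axis=0)
    return -predict_median_survival(model, X).mean(axis=0)


def overfit_gap(train_ci: float, test_ci: float) -> float:
    """Training minus test C-index; positive values indicate overfitting."""
    for v in (train_ci, test_ci):
        if not 0.0 <= v <= 1.0:
            raise ValueError("C-indices must lie in [0, 1]")
    return train_ci - test_ci


class Normalizer:
    """Z-scores continuous columns with *training* statistics.

    Binary / one-hot columns pass through untouched. Zero-variance
    continuous columns get SD 1 with a warning. ``transform`` reuses the
    training mean/SD on any new matrix — test data never influences the
    fitted statistics.
    """

    def __init__(self, feature_kinds):
        self.feature_kinds = list(feature_kinds)
        self.continuous = np.array([k == "continuous" for k in self.feature_kinds])
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, train_X) -> "Normalizer":
        X = np.atleast_2d(np.asarray(train_X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("cannot fit a normalizer on an empty matrix")
        self.mean_ = np.where(self.continuous, X.mean(axis=0), 0.0)
        sd = np.where(self.continuous, X.std(axis=0), 1.0)
        zero = self.continuous & (sd == 0)
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance continuous column(s); using SD 1")
            sd = np.where(zero, 1.0, sd)
        self.sd_ = sd
        return self

    def transform(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) / self.sd_

    def inverse_transform(self, X) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer not fitted")
        return np.atleast_2d(np.asarray(X, dtype=float)) * self.sd_ + self.mean_

    def fit_transform(self, X) -> np.ndarray:
        return self.fit(X).transform(X)


def mi_kbest(X, times, events, k: int, seed: int | None = 0) -> np.ndarray:
    """Top-k features by mutual information with dichotomised survival.

    The label is 1 where the observed time exceeds the cohort's median
    observed time (censoring is ignored at this ranking step). MI is the
    nearest-neighbour estimator (3 neighbours) with seeded jitter; ties
    break by original column order.
    """
    from sklearn.feature_selection import mutual_info_classif

    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not 1 <= k <= X.shape[1]:
        raise ValueError(f"k must be in [1, {X.shape[1]}], got {k}")
    label = (np.asarray(times, dtype=float) > np.median(times)).astype(int)
    mi = mutual_info_classif(X, label, n_neighbors=3, random_state=seed)
    order = np.lexsort((np.arange(X.shape[1]), -mi))  # stable: ties keep column order
    return np.sort(order[:k])


def split_train_test(data: SurvivalData, test_frac: float = 0.2, seed: int | None = None):
    """Random disjoint 80/20 (by default) split, reproducible given a seed."""
    if data.n < 5:
        raise ValueError("need at least 5 subjects to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    n_test = max(1, int(round(test_frac * data.n)))
    return data.subset(np.sort(perm[n_test:])), data.subset(np.sort(perm[:n_test]))


@dataclass
class TuneResult:
    best: dict
    best_score: float
    trace: pd.DataFrame = field(repr=False)


def _sample_config(space: dict, rng: np.random.Generator) -> dict:
    """Draw one configuration: log-uniform for (lo, hi) float bounds,
    uniform integer for [lo, hi] int bounds, choice for lists."""
    cfg = {}
    for name, bound in space.items():
        if isinstance(bound, list):
            cfg[name] = bound[rng.integers(len(bound))]
        elif isinstance(bound, tuple) and all(isinstance(b, int) for b in bound):
            cfg[name] = int(rng.integers(bound[0], bound[1] + 1))
        elif isinstance(bound, tuple):
            lo, hi = bound
            cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            cfg[name] = bound
    return cfg


def cv_tune(
    data: SurvivalData,
    spec: ModelSpec,
    space: dict | None = None,
    n_folds: int = 5,
    budget: int = 10,
    seed: int | None = 0,
    sampler_config=None,
    scorer=None,
    search=None,
) -> TuneResult:
    """Seeded random-search hyperparameter tuning with k-fold CV.

    ``space`` maps hyperparameter names to bounds: ``prior_sd`` (log-uniform
    float tuple, default (0.1, 10)), ``k`` (integer tuple, default
    (1, n_features)), ``n_hidden_layers`` (list, nn predictor only). Each
    candidate is scored by mean out-of-fold C-index; normalization and MI
    ranking are fitted inside the training fold only. A custom ``search``
    callable (space, rng, budget) -> iterable of configs makes the strategy
    pluggable.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if space is None:
        space = {"prior_sd": (0.1, 10.0), "k": (1, data.n_features)}
        if spec.predictor == "nn":
            space["n_hidden_layers"] = [1, 2]
    rng = np.random.default_rng(seed)
    if search is None:
        configs = [_sample_config(space, rng) for _ in range(budget)]
    else:
        configs = list(search(space, rng, budget))
    cfg_sampler = SamplerConfig.resolve(sampler_config)
    if scorer is None:
        scorer = _cv_score_model

    folds = _event_balanced_folds(data, n_folds, rng)
    rows = []
    best, best_score = None, -np.inf
    for i, hp in enumerate(configs):
        scores = []
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(data.n), test_idx)
            scores.append(scorer(data, train_idx, test_idx, spec, hp, cfg_sampler))
        mean_score = float(np.mean(scores))
        rows.append({"config": i, **hp, "cv_c_index": mean_score})
        if mean_score > best_score:
            best, best_score = hp, mean_score
    return TuneResult(best=best, best_score=best_score, trace=pd.DataFrame(rows))


def _event_balanced_folds(data: SurvivalData, n_folds: int, rng) -> list[np.ndarray]:
    """Seeded folds; refold (reshuffle) if a fold has zero events."""
    for attempt in range(20):
        perm = rng.permutation(data.n)
        folds = np.array_split(perm, n_folds)
        if all(data.events[f].sum() > 0 for f in folds):
            return folds
        warnings.warn(f"fold with zero events on attempt {attempt + 1}; refolding")
    return folds


def _cv_score_model(data, train_idx, test_idx, spec, hp, sampler_cfg) -> float:
    """Fit the spec with one hyperparameter draw on a fold; return test C-index."""
    from dataclasses import replace

    train, test = data.subset(train_idx), data.subset(test_idx)
    norm = Normalizer(train.feature_kinds).fit(train.covariates)
    Xtr, Xte = norm.transform(train.covariates), norm.transform(test.covariates)
    k = int(hp.get("k", data.n_features))
    cols = mi_kbest(Xtr, train.times, train.events, k, seed=0)
    fit_spec = replace(
        spec,
        prior_sd=float(hp.get("prior_sd", spec.prior_sd)),
        n_hidden_layers=int(hp.get("n_hidden_layers", spec.n_hidden_layers)),
    )
    train_sel = train.select_features(cols)
    train_sel.covariates = Xtr[:, cols]
    model = fit(fit_spec, train_sel, sampler_config=sampler_cfg)
    return concordance_index(test.times, test.events, risk_score(model, Xte[:, cols]))
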