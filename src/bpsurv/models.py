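"""Parametric survival model math: predictors, distributions, censored likelihood.

The survival time is modelled as Exponential(lambda) or Weibull(lambda, kappa)
in the *rate* parameterization,

    S(t) = exp(-lambda * t)            (exponential)
    S(t) = exp(-(lambda * t)**kappa)   (weibull)

so lambda is an inverse scale (rate) — 1/lambda is the time by which the
event probability reaches 1 - 1/e ~ 63.2% — and kappa > 1 (< 1) means a
rising (falling) hazard. Many libraries use the scale form with
scale = 1/lambda; conversions are ``lambda = 1/scale``. Distribution
parameters are produced from covariates by a predictor function whose output
is exponentiated, guaranteeing positivity: a linear combination with
intercept, or a tanh feed-forward network whose last layer is exponentiated.

Everything here is pure and vectorized over posterior draws; the sampler and
the deterministic oracles in the test suite share these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EXPONENTIAL = "exponential"
WEIBULL = "weibull"
_DISTRIBUTIONS = (EXPONENTIAL, WEIBULL)


@dataclass
class ModelSpec:
    """Configuration of one Bayesian parametric survival model.

    Parameters
    ----------
    distribution : {"exponential", "weibull"}
    predictor : {"linear", "nn"}
        How covariates map to the distribution parameters. ``"nn"`` is a
        tanh feed-forward network with an exponentiated output layer.
    prior_sd : float
        Standard deviation of the independent Normal(0, prior_sd)
        coefficient priors (the ``priors_sd`` tuning hyperparameter).
    n_hidden_layers, n_hidden_units : int
        Network depth/width (nn predictor only). ``n_hidden_units=None``
        defaults to the number of input features at fit time.
    kappa_mode : {"intercept_only", "covariate"}
        Whether the Weibull shape is a single shared exp(intercept)
        (default) or itself predicted from covariates.
    """

    distribution: str = EXPONENTIAL
    predictor: str = "linear"
    prior_sd: float = 1.0
    n_hidden_layers: int = 1
    n_hidden_units: int | None = None
    kappa_mode: str = "intercept_only"

    def __post_init__(self) -> None:
        if self.distribution not in _DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.predictor not in ("linear", "nn"):
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")
        if self.kappa_mode not in ("intercept_only", "covariate"):
            raise ValueError(f"unknown kappa_mode {self.kappa_mode!r}")
        if self.predictor == "nn":
            if self.n_hidden_layers < 0:
                raise ValueError("n_hidden_layers must be >= 0")
            if self.n_hidden_units is not None and self.n_hidden_units < 1:
                raise ValueError("n_hidden_units must be >= 1")

    @property
    def n_dist_params(self) -> int:
        return 1 if self.distribution == EXPONENTIAL else 2

    def to_dict(self) -> dict:
        return {
            "distribution": self.distribution,
            "predictor": self.predictor,
            "prior_sd": self.prior_sd,
            "n_hidden_layers": self.n_hidden_layers,
            "n_hidden_units": self.n_hidden_units,
            "kappa_mode": self.kappa_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class DistParams:
    """Per-subject distribution parameters (always positive).

    ``lam`` is the rate; ``kappa`` is the Weibull shape (None for the
    exponential model). Arrays may carry leading draw dimensions.
    """

    lam: np.ndarray
    kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if self.kappa is not None:
            self.kappa = np.asarray(self.kappa, dtype=float)
        if np.any(self.lam <= 0):
            raise ValueError("lam must be strictly positive")
        if self.kappa is not None and np.any(self.kappa <= 0):
            raise ValueError("kappa must be strictly positive")


# ---------------------------------------------------------------------------
# predictor functions
# ---------------------------------------------------------------------------

def linear_predictor(x_row: np.ndarray, theta: np.ndarray) -> float:
    """exp(theta . x_row) for one subject; x_row carries the leading 1."""
    x_row = np.asarray(x_row, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if x_row.shape != theta.shape:
        raise ValueError(f"dimension mismatch: x_row {x_row.shape} vs theta {theta.shape}")
    return float(np.exp(x_row @ theta))


def nn_forward(x_row: np.ndarray, layers) -> np.ndarray:
    """Feed-forward pass for one subject.

    Hidden layers apply tanh(W @ a + b); the last layer applies
    exp(W @ a + b), one output per distribution parameter.
    """
    a = np.asarray(x_row, dtype=float)
    if not layers:
        raise ValueError("at least one layer required")
    for i, (W, b) in enumerate(layers):
        W = np.asarray(W, dtype=float)
        b = np.asarray(b, dtype=float)
        if W.shape[0] != a.shape[0] or W.shape[1] != b.shape[0]:
            raise ValueError(
                f"layer {i}: shapes do not chain (a {a.shape}, W {W.shape}, b {b.shape})"
            )
        z = a @ W + b
        a = np.exp(z) if i == len(layers) - 1 else np.tanh(z)
    return a


# ---------------------------------------------------------------------------
# survival quantities
# ---------------------------------------------------------------------------

def log_survival(t, params: DistParams, distribution: str):
    """log S(t): -lambda*t (exponential) or -(lambda*t)**kappa (weibull)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if distribution == EXPONENTIAL:
        return -params.lam * t
    if distribution == WEIBULL:
        if params.kappa is None:
            raise ValueError("weibull requires kappa")
        return -((params.lam * t) ** params.kappa)
    raise ValueError(f"unknown distribution {distribution!r}")


def survival_probability(t, params: DistParams, distribution: str):
    """S(t) = exp(log S(t)), the complement of the CDF."""
    return np.exp(log_survival(t, params, distribution))


def event_probability(t, params: DistParams, distribution: str):
    """CDF: 1 - S(t)."""
    return 1.0 - survival_probability(t, params, distribution)


def log_density(t, params: DistParams, distribution: str):
    """log f(t) of the event-time distribution (log hazard + log survival)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if distribution == EXPONENTIAL:
        return np.log(params.lam) - params.lam * t
    if distribution == WEIBULL:
        lam, kappa = params.lam, params.kappa
        if kappa is None:
            raise ValueError("weibull requires kappa")
        with np.errstate(divide="ignore"):
            logt = np.log(t)
        return np.log(kappa) + kappa * np.log(lam) + (kappa - 1.0) * logt - (lam * t) ** kappa
    raise ValueError(f"unknown distribution {distribution!r}")


def median_survival_time(params: DistParams, distribution: str):
    """Closed-form median: ln2/lambda, or (ln2)**(1/kappa)/lambda."""
    if distribution == EXPONENTIAL:
        return np.log(2.0) / params.lam
    if distribution == WEIBULL:
        return np.log(2.0) ** (1.0 / params.kappa) / params.lam
    raise ValueError(f"unknown distribution {distribution!r}")


def total_log_likelihood(data, params: DistParams, distribution: str) -> float:
    """Censored log-likelihood summed over subjects.

    Event subjects contribute log f(t_i); right-censored subjects contribute
    log S(t_i) — for them the true event time exceeds the observation time.
    ``params`` carries one lam (and kappa) per subject; leading draw
    dimensions are allowed and reduce over the last (subject) axis.
    """
    ll = _loglik_terms(data.times, data.events, params, distribution)
    total = ll.sum(axis=-1)
    if not np.all(np.isfinite(total)):
        nonfinite = ~np.isfinite(ll)
        bad = np.where(nonfinite.reshape(-1, ll.shape[-1]).any(axis=0))[0]
        raise FloatingPointError(f"non-finite likelihood terms at subject index {bad[:5].tolist()}")
    return float(total) if np.ndim(total) == 0 else total


def _loglik_terms(times, events, params: DistParams, distribution: str):
    """Per-subject log-likelihood terms; broadcasts over draw dimensions."""
    times = np.asarray(times, dtype=float)
    ev = np.asarray(events, dtype=bool)
    ls = log_survival(times, params, distribution)
    ld = log_density(times, params, distribution)
    return np.where(ev, ld, ls)
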