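"""Synthetic right-censored survival data with known ground truth.

Event times are drawn from the same generative model the package fits:
covariates x_i (standard-normal continuous and/or Bernoulli binary), rate
lambda_i = exp(theta . [1, x_i]) and T_i ~ Exponential(lambda_i) or
Weibull(lambda_i, kappa) in the rate parameterization. Censoring is either
administrative (a fixed study cutoff) or uniform, with the cutoff solved so
the expected censored fraction hits a target. The returned truth record
carries everything needed to score parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data import BINARY, CONTINUOUS, SurvivalData


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    coefficients: np.ndarray  # intercept first
    kappa: float
    distribution: str
    censoring_mode: str | None
    censoring_cutoff: float | None
    target_censor_frac: float
    achieved_censor_frac: float
    seed: int | None
    feature_kinds: list[str] = field(default_factory=list)


def _draw_covariates(n: int, covariate_spec, rng) -> tuple[np.ndarray, list[str]]:
    """covariate_spec: sequence of "continuous" | "binary" | ("binary", p)."""
    cols, kinds = [], []
    for item in covariate_spec or []:
        if item == CONTINUOUS:
            cols.append(rng.standard_normal(n))
            kinds.append(CONTINUOUS)
        else:
            p = item[1] if isinstance(item, tuple) else 0.5
            cols.append(rng.binomial(1, p, size=n).astype(float))
            kinds.append(BINARY)
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, kinds


def simulate_survival(
    n: int,
    coefficients,
    distribution: str = "exponential",
    kappa: float = 1.0,
    censoring: dict | None = None,
    covariate_spec=None,
    seed: int | None = None,
) -> tuple[SurvivalData, SimulationTruth]:
    """Simulate a right-censored cohort.

    Parameters
    ----------
    coefficients : array-like
        Log-rate coefficients, intercept first; needs len(coefficients) - 1
        covariate columns. ``covariate_spec`` defaults to that many
        standard-normal continuous features.
    censoring : dict, optional
        ``{"mode": "administrative" | "uniform", "target_frac": f}``; omit
        for a fully observed cohort. The cutoff is calibrated on the drawn
        event times so the censored fraction lands near ``target_frac``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    theta = np.asarray(coefficients, dtype=float)
    rng = np.random.default_rng(seed)
    d = theta.shape[0] - 1
    if covariate_spec is None:
        covariate_spec = [CONTINUOUS] * d
    X, kinds = _draw_covariates(n, covariate_spec, rng)
    if X.shape[1] != d:
        raise ValueError(f"coefficients imply {d} features, covariate_spec gives {X.shape[1]}")

    lam = np.exp(theta[0] + X @ theta[1:])
    # rate-parameterized Weibull: T = (-ln U)^(1/kappa) / lambda; kappa=1 is exponential
    u = rng.uniform(size=n)
    t_event = (-np.log(u)) ** (1.0 / kappa) / lam
    if distribution == "exponential" and kappa != 1.0:
        raise ValueError("exponential distribution requires kappa = 1")

    mode = cutoff = None
    target = 0.0
    if censoring:
        mode = censoring.get("mode", "administrative")
        target = float(censoring["target_frac"])
        if not 0 < target < 1:
            raise ValueError("target_frac must be in (0, 1)")
        if mode == "administrative":
            # censored iff T > cutoff, so place the cutoff at the (1-target) quantile
            cutoff = float(np.quantile(t_event, 1.0 - target))
            c_times = np.full(n, cutoff)
        elif mode == "uniform":
            def frac(c):  # P(C < T) with C ~ U(0, c): expected censored fraction
                return np.mean(np.minimum(t_event / c, 1.0)) - target
            hi = float(t_event.max()) * 2
            lo = float(t_event.min()) * 1e-6
            cutoff = brentq(frac, lo, hi) if frac(hi) < 0 < frac(lo) else hi
            c_times = rng.uniform(0, cutoff, size=n)
        else:
            raise ValueError(f"unknown censoring mode {mode!r}")
        events = (t_event <= c_times).astype(int)
        times = np.minimum(t_event, c_times)
    else:
        events = np.ones(n, dtype=int)
        times = t_event

    tiny = times <= 0
    if tiny.any():
        bump = 0.5 * times[times > 0].min()
        warnings.warn(f"bumped {int(tiny.sum())} zero times to {bump:g}")
        times = np.where(tiny, bump, times)

    achieved = 1.0 - events.mean()
    if censoring and abs(achieved - target) > 0.05:
        warnings.warn(
            f"achieved censoring fraction {achieved:.3f} misses target {target:.3f}"
        )
    data = SurvivalData(
        times=times, events=events, covariates=X,
        feature_names=[f"x{i}" for i in range(X.shape[1])],
        feature_kinds=kinds,
    )
    truth = SimulationTruth(
        coefficients=theta, kappa=float(kappa), distribution=distribution,
        censoring_mode=mode, censoring_cutoff=cutoff,
        target_censor_frac=target, achieved_censor_frac=float(achieved),
        seed=seed, feature_kinds=kinds,
    )
    return data, truth
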