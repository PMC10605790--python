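"""MCMC fitting and posterior-predictive survival prediction.

Models are fitted by ensemble MCMC (emcee's affine-invariant sampler) on
the flat coefficient vector, with independent Normal priors and the
censored parametric log-likelihood evaluated fully vectorized across
walkers. Walkers double as chains for split-R-hat / effective-sample-size
diagnostics (computed with ArviZ). Fixing the seed reproduces draws
bit-for-bit on the same platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .data import SurvivalData
from .models import EXPONENTIAL, WEIBULL, DistParams, ModelSpec
from .params import ParameterLayout, PriorSet, default_priors

__all__ = [
    "SamplerConfig", "Posterior", "SurvivalCurves", "default_priors",
    "fit", "posterior_params_for", "predict_survival", "predict_median_survival",
]


@dataclass
class SamplerConfig:
    """Sampler settings.

    ``chains`` sets the minimum number of walkers (walkers are reported as
    chains), ``tune`` the discarded burn-in steps and ``draws`` the target
    total number of retained draws divided over walkers. ``target_accept``
    is accepted for interface compatibility; the affine-invariant ensemble
    sampler has no step-size acceptance target, so it is ignored.
    """

    chains: int = 4
    tune: int = 1000
    draws: int = 1000
    seed: int | None = None
    target_accept: float = 0.9
    thin: int = 1

    @classmethod
    def resolve(cls, cfg) -> "SamplerConfig":
        if cfg is None:
            return cls()
        if isinstance(cfg, cls):
            return cfg
        return cls(**cfg)


@dataclass
class SurvivalCurves:
    """Per-subject survival curves over a time grid with uncertainty.

    ``mean``/``sd`` have shape (subjects, len(time_grid)); ``lower``/``upper``
    are the mean +/- SD band clipped to [0, 1] (or posterior quantiles when
    requested at prediction time).
    """

    time_grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_posterior_samples: int

    def to_frame(self) -> pd.DataFrame:
        n, T = self.mean.shape
        return pd.DataFrame({
            "subject": np.repeat(np.arange(n), T),
            "time": np.tile(self.time_grid, n),
            "mean": self.mean.ravel(),
            "sd": self.sd.ravel(),
            "lower": self.lower.ravel(),
            "upper": self.upper.ravel(),
        })


@dataclass
class Posterior:
    """Named posterior draws plus convergence diagnostics.

    ``samples`` is the flat draw array of shape (chains, draws, n_params)
    in layout order; ``draws`` exposes the per-parameter view.
    """

    samples: np.ndarray
    layout: ParameterLayout
    priors: PriorSet
    seed: int | None
    diagnostics: pd.DataFrame = field(default=None)
    acceptance_fraction: float = float("nan")

    @property
    def spec(self) -> ModelSpec:
        return self.layout.spec

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_draws(self) -> int:
        return self.samples.shape[1]

    @property
    def draws(self) -> dict[str, np.ndarray]:
        return {
            name: self.samples[:, :, i]
            for i, name in enumerate(self.layout.scalar_names)
        }

    def flat(self, max_draws: int | None = None, seed: int = 0) -> np.ndarray:
        """Draws as (total, n_params); optionally an evenly-seeded subsample."""
        out = self.samples.reshape(-1, self.samples.shape[-1])
        if max_draws is not None and max_draws < out.shape[0]:
            idx = np.random.default_rng(seed).choice(out.shape[0], max_draws, replace=False)
            out = out[np.sort(idx)]
        return out

    def param_summaries(self) -> dict[str, tuple[float, float]]:
        """Posterior (mean, SD) per scalar parameter — the updating currency."""
        flat = self.flat()
        mu = flat.mean(axis=0)
        sd = flat.std(axis=0, ddof=1)
        return {n: (float(m), float(s)) for n, m, s in zip(self.layout.scalar_names, mu, sd)}

    def summary(self) -> pd.DataFrame:
        flat = self.flat()
        df = pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
        }, index=self.layout.scalar_names)
        if self.diagnostics is not None:
            df = df.join(self.diagnostics)
        return df


def _log_likelihood_matrix(times, events, log_lam, log_kappa, distribution):
    """Total censored log-likelihood per draw, stable on the log scale."""
    t = times
    ev = events
    with np.errstate(over="ignore", invalid="ignore"):
        if distribution == EXPONENTIAL:
            lam_t = np.exp(log_lam) * t
            ll = np.where(ev, log_lam - lam_t, -lam_t)
        else:
            kappa = np.exp(log_kappa)
            z = np.exp(kappa * (log_lam + np.log(t)))  # (lam*t)**kappa
            ll = np.where(
                ev,
                log_kappa + kappa * log_lam + (kappa - 1.0) * np.log(t) - z,
                -z,
            )
        total = ll.sum(axis=-1)
    return np.where(np.isfinite(total), total, -np.inf)


def fit(
    spec: ModelSpec,
    data: SurvivalData,
    priors: PriorSet | None = None,
    sampler_config=None,
) -> Posterior:
    """Fit a Bayesian parametric survival model by ensemble MCMC.

    Parameters
    ----------
    spec : ModelSpec
    data : SurvivalData
    priors : PriorSet, optional
        Defaults to Normal(0, spec.prior_sd) on every parameter; pass the
        output of :func:`bpsurv.updating.posterior_to_priors` to update an
        existing model on new data.
    sampler_config : SamplerConfig or dict, optional

    Returns
    -------
    Posterior with split-R-hat / ESS diagnostics. A warning is emitted when
    any R-hat exceeds 1.01 (increase ``tune``/``draws``) — fitting never
    hard-fails on convergence so unattended replicate loops can proceed.
    """
    if data.n == 0:
        raise ValueError("cannot fit on zero subjects")
    if data.n_events == 0:
        warnings.warn("no events in the data: only censoring information available")
    cfg = SamplerConfig.resolve(sampler_config)
    layout = ParameterLayout(spec, data.n_features, data.feature_names)
    if priors is None:
        priors = default_priors(spec, data.n_features, data.feature_names)
    if list(priors.names) != list(layout.scalar_names):
        raise ValueError(
            "prior parameter names do not match the model layout; "
            f"expected {layout.scalar_names[:4]}..., got {list(priors.names)[:4]}..."
        )

    p = layout.size
    nwalkers = max(2 * p + 2, cfg.chains, 8)
    nwalkers += nwalkers % 2
    keep_steps = max(1, int(np.ceil(cfg.chains * cfg.draws / nwalkers)))

    times, events = data.times, data.events.astype(bool)
    X = data.covariates
    mu, sd = priors.means, priors.sds
    dist = spec.distribution

    def log_prob(theta):
        lp = -0.5 * (((theta - mu) / sd) ** 2).sum(axis=-1)
        llam, lkap = layout.log_params(theta, X)
        return lp + _log_likelihood_matrix(times, events, llam, lkap, dist)

    seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)
    p0 = mu + 0.1 * sd * rng.standard_normal((nwalkers, p))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, p, log_prob, vectorize=True, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed).get_state())
    state = sampler.run_mcmc(state, cfg.tune + keep_steps * cfg.thin, progress=False)

    chain = sampler.get_chain(discard=cfg.tune, thin=cfg.thin)  # (steps, walkers, p)
    samples = np.ascontiguousarray(np.moveaxis(chain, 0, 1))  # (walkers, steps, p)
    accept = float(np.mean(sampler.acceptance_fraction))
    if accept < 0.05:
        warnings.warn(f"low ensemble acceptance fraction ({accept:.3f}); check the model")

    diagnostics = _convergence_table(samples, layout.scalar_names)
    bad = diagnostics["rhat"] > 1.01
    if bad.any():
        worst = diagnostics["rhat"].max()
        warnings.warn(
            f"{int(bad.sum())} parameter(s) with split-R-hat > 1.01 (max {worst:.3f}); "
            "consider more tuning steps or draws"
        )
    return Posterior(
        samples=samples,
        layout=layout,
        priors=priors,
        seed=cfg.seed,
        diagnostics=diagnostics,
        acceptance_fraction=accept,
    )


def _convergence_table(samples: np.ndarray, names) -> pd.DataFrame:
    import arviz as az

    idata = az.from_dict({n: samples[:, :, i] for i, n in enumerate(names)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    return pd.DataFrame({
        "rhat": [float(rhat[n].values) for n in names],
        "ess": [float(ess[n].values) for n in names],
    }, index=list(names))


def posterior_params_for(
    posterior: Posterior,
    X_new: np.ndarray,
    max_draws: int | None = None,
    seed: int = 0,
) -> DistParams:
    """Distribution parameters for new subjects under every retained draw.

    Returns a :class:`DistParams` whose arrays have shape
    (draws_total, n_subjects); ``kappa`` is None for the exponential model.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    theta = posterior.flat(max_draws=max_draws, seed=seed)
    llam, lkap = posterior.layout.log_params(theta, X_new)
    return DistParams(
        lam=np.exp(llam),
        kappa=None if lkap is None else np.exp(lkap),
    )


def predict_survival(
    posterior: Posterior,
    X_new: np.ndarray,
    time_grid: np.ndarray,
    max_draws: int | None = 1000,
    band: str = "sd",
    band_prob: float = 0.94,
    seed: int = 0,
) -> SurvivalCurves:
    """Posterior-predictive survival curves with uncertainty.

    For every retained draw, S(t) is evaluated from the drawn distribution
    parameters on the time grid; the curve is summarised by its pointwise
    mean and SD, with a mean +/- SD band clipped to [0, 1] by default
    (``band="quantile"`` gives central ``band_prob`` quantile bands).
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or np.any(np.diff(time_grid) < 0):
        raise ValueError("time_grid must be 1-D and sorted ascending")
    if np.any(time_grid < 0):
        raise ValueError("time_grid must start at or after 0")
    params = posterior_params_for(posterior, X_new, max_draws=max_draws, seed=seed)
    lam = params.lam[:, :, None]  # (m, n, 1)
    t = time_grid[None, None, :]
    if posterior.spec.distribution == WEIBULL:
        kap = params.kappa[:, :, None]
        S = np.exp(-((lam * t) ** kap))
    else:
        S = np.exp(-lam * t)
    mean = S.mean(axis=0)
    sd = S.std(axis=0)
    if band == "sd":
        lower = np.clip(mean - sd, 0.0, 1.0)
        upper = np.clip(mean + sd, 0.0, 1.0)
    elif band == "quantile":
        alpha = (1.0 - band_prob) / 2.0
        lower = np.quantile(S, alpha, axis=0)
        upper = np.quantile(S, 1.0 - alpha, axis=0)
    else:
        raise ValueError("band must be 'sd' or 'quantile'")
    return SurvivalCurves(
        time_grid=time_grid, mean=mean, sd=sd, lower=lower, upper=upper,
        n_posterior_samples=params.lam.shape[0],
    )


def predict_median_survival(
    posterior: Posterior,
    X_new: np.ndarray,
    max_draws: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Posterior draws of each subject's median survival time.

    (ln 2)^(1/kappa) / lambda for the Weibull model, ln 2 / lambda for the
    exponential; shape (draws_total, n_subjects).
    """
    params = posterior_params_for(posterior, X_new, max_draws=max_draws, seed=seed)
    if posterior.spec.distribution == WEIBULL:
        return np.log(2.0) ** (1.0 / params.kappa) / params.lam
    return np.log(2.0) / params.lam
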