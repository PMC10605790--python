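"""Flat parameter layout and Normal prior sets.

The sampler works on a flat coefficient vector; this module owns the
mapping between that vector, named scalar parameters (used in priors,
summaries and model files) and the predictor functions that turn
covariates into distribution parameters on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import EXPONENTIAL, WEIBULL, ModelSpec


@dataclass
class PriorSet:
    """Independent Normal(mu, sigma) priors, one per scalar parameter."""

    names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (len(self.names) == self.means.shape[0] == self.sds.shape[0]):
            raise ValueError("names, means and sds must have equal length")
        if np.any(self.sds <= 0):
            raise ValueError("all prior standard deviations must be positive")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: (float(m), float(s)) for n, m, s in zip(self.names, self.means, self.sds)}

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "PriorSet":
        names = list(d)
        mu = np.array([d[n][0] for n in names], dtype=float)
        sd = np.array([d[n][1] for n in names], dtype=float)
        return cls(names, mu, sd)


class ParameterLayout:
    """Ordered blocks of model parameters for a spec and feature set.

    Blocks are (name, shape) pairs; scalars get readable names like
    ``lam_intercept`` / ``lam_age`` / ``kappa_intercept`` / ``nn_W1[0,2]``.
    """

    def __init__(self, spec: ModelSpec, n_features: int, feature_names=None):
        self.spec = spec
        self.n_features = int(n_features)
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(n_features)]
        if len(feature_names) != n_features:
            raise ValueError("feature_names length mismatch")
        self.feature_names = list(feature_names)

        d = self.n_features
        self.n_heads = 2 if (spec.distribution == WEIBULL and spec.kappa_mode == "covariate"
                             and spec.predictor == "nn") else 1
        self.blocks: list[tuple[str, tuple[int, ...]]] = []
        if spec.predictor == "linear":
            self.blocks.append(("lam_coef", (d + 1,)))
            if spec.distribution == WEIBULL:
                if spec.kappa_mode == "covariate":
                    self.blocks.append(("kappa_coef", (d + 1,)))
                else:
                    self.blocks.append(("kappa_intercept", ()))
        else:
            units = spec.n_hidden_units or max(d, 1)
            width_in = d
            for layer in range(1, spec.n_hidden_layers + 1):
                self.blocks.append((f"nn_W{layer}", (width_in, units)))
                self.blocks.append((f"nn_b{layer}", (units,)))
                width_in = units
            self.blocks.append(("nn_W_out", (width_in, self.n_heads)))
            self.blocks.append(("nn_b_out", (self.n_heads,)))
            if spec.distribution == WEIBULL and spec.kappa_mode == "intercept_only":
                self.blocks.append(("kappa_intercept", ()))

        self._slices: dict[str, tuple[slice, tuple[int, ...]]] = {}
        offset = 0
        names: list[str] = []
        for name, shape in self.blocks:
            size = int(np.prod(shape)) if shape else 1
            self._slices[name] = (slice(offset, offset + size), shape)
            names.extend(self._scalar_names(name, shape))
            offset += size
        self.size = offset
        self.scalar_names = names

    def _scalar_names(self, block: str, shape: tuple[int, ...]) -> list[str]:
        if block == "lam_coef":
            return ["lam_intercept"] + [f"lam_{f}" for f in self.feature_names]
        if block == "kappa_coef":
            return ["kappa_intercept"] + [f"kappa_{f}" for f in self.feature_names]
        if not shape:
            return [block]
        if len(shape) == 1:
            return [f"{block}[{i}]" for i in range(shape[0])]
        return [f"{block}[{i},{j}]" for i in range(shape[0]) for j in range(shape[1])]

    def block(self, theta: np.ndarray, name: str) -> np.ndarray:
        """Slice one block out of flat draws; leading draw dims preserved."""
        sl, shape = self._slices[name]
        part = theta[..., sl]
        return part.reshape(part.shape[:-1] + shape) if shape else part[..., 0]

    def log_params(self, theta: np.ndarray, X: np.ndarray):
        """log lambda and log kappa per subject for each draw.

        Parameters
        ----------
        theta : array (..., size) of flat coefficient draws.
        X : array (n, d) covariates without intercept column.

        Returns
        -------
        (log_lam, log_kappa) with shape (..., n); log_kappa is None for the
        exponential model.
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"covariate matrix has {X.shape[1]} columns, model expects "
                f"{self.n_features} ({self.feature_names})"
            )
        spec = self.spec
        if spec.predictor == "linear":
            coef = self.block(theta, "lam_coef")
            log_lam = coef[..., :1] + coef[..., 1:] @ X.T
        else:
            a = None
            for layer in range(1, spec.n_hidden_layers + 1):
                W = self.block(theta, f"nn_W{layer}")
                b = self.block(theta, f"nn_b{layer}")
                z = (np.einsum("nd,mdo->mno", X, W) if a is None
                     else np.einsum("mni,mio->mno", a, W)) + b[:, None, :]
                a = np.tanh(z)
            W = self.block(theta, "nn_W_out")
            b = self.block(theta, "nn_b_out")
            z = (np.einsum("nd,mdo->mno", X, W) if a is None
                 else np.einsum("mni,mio->mno", a, W)) + b[:, None, :]
            log_lam = z[..., 0]
            if self.n_heads == 2:
                return log_lam, z[..., 1]

        if spec.distribution == EXPONENTIAL:
            return log_lam, None
        if spec.kappa_mode == "intercept_only":
            log_kap = np.broadcast_to(
                self.block(theta, "kappa_intercept")[..., None], log_lam.shape
            )
        else:
            coef = self.block(theta, "kappa_coef")
            log_kap = coef[..., :1] + coef[..., 1:] @ X.T
        return log_lam, log_kap


def default_priors(spec: ModelSpec, n_features: int, feature_names=None) -> PriorSet:
    """Normal(0, spec.prior_sd) on every coefficient, weight and bias.

    With the default ``prior_sd=1`` these are the non-informative priors
    that act as regularization during initial training.
    """
    layout = ParameterLayout(spec, n_features, feature_names)
    return PriorSet(
        names=list(layout.scalar_names),
        means=np.zeros(layout.size),
        sds=np.full(layout.size, float(spec.prior_sd)),
    )
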