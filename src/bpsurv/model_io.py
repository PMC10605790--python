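"""Versioned model files: the artifact exchanged between institutions.

A model file is a JSON document holding the model spec, training seed,
feature metadata and per-parameter posterior (mean, SD) summaries — all
the updating recipe needs. Full draws can optionally be embedded so
predictions reload exactly; without them prediction falls back to an
independent-Normal approximation of the posterior (with a warning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .inference import Posterior
from .models import ModelSpec
from .params import ParameterLayout, PriorSet

FORMAT_VERSION = "1"


def save_model(posterior: Posterior, path, include_draws: bool = False) -> None:
    """Write a fitted model to a versioned JSON file."""
    layout = posterior.layout
    doc = {
        "format_version": FORMAT_VERSION,
        "spec": posterior.spec.to_dict(),
        "seed": posterior.seed,
        "n_features": layout.n_features,
        "feature_names": layout.feature_names,
        "summaries": {n: list(ms) for n, ms in posterior.param_summaries().items()},
        "diagnostics": {
            "max_rhat": float(posterior.diagnostics["rhat"].max())
            if posterior.diagnostics is not None else None,
        },
    }
    if include_draws:
        doc["draws_shape"] = list(posterior.samples.shape)
        doc["draws"] = np.round(posterior.samples, 12).ravel().tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)


@dataclass
class LoadedModel:
    """A model file read back: summaries always, full posterior if stored."""

    spec: ModelSpec
    layout: ParameterLayout
    summaries: dict[str, tuple[float, float]]
    seed: int | None
    posterior: Posterior | None = None

    def param_summaries(self) -> dict[str, tuple[float, float]]:
        return self.summaries

    def as_posterior(self, n_draws: int = 1000, seed: int = 0) -> Posterior:
        """Exact posterior when draws were stored; otherwise an
        independent-Normal approximation sampled from the summaries."""
        if self.posterior is not None:
            return self.posterior
        warnings.warn(
            "model file has no draws: predictions use a Normal approximation "
            "of the posterior"
        )
        rng = np.random.default_rng(seed)
        mu = np.array([self.summaries[n][0] for n in self.layout.scalar_names])
        sd = np.array([self.summaries[n][1] for n in self.layout.scalar_names])
        samples = mu + sd * rng.standard_normal((2, n_draws, self.layout.size))
        priors = PriorSet(list(self.layout.scalar_names), mu, sd)
        return Posterior(samples=samples, layout=self.layout, priors=priors, seed=self.seed)


def load_model(path) -> LoadedModel:
    """Read a model file; raises on version mismatch or corruption."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"model file version {version!r} not supported (expected {FORMAT_VERSION!r})"
        )
    spec = ModelSpec.from_dict(doc["spec"])
    layout = ParameterLayout(spec, doc["n_features"], doc["feature_names"])
    summaries = {n: tuple(v) for n, v in doc["summaries"].items()}
    posterior = None
    if "draws" in doc:
        samples = np.asarray(doc["draws"], dtype=float).reshape(doc["draws_shape"])
        mu = np.array([summaries[n][0] for n in layout.scalar_names])
        sd = np.array([summaries[n][1] for n in layout.scalar_names])
        posterior = Posterior(
            samples=samples, layout=layout,
            priors=PriorSet(list(layout.scalar_names), mu, np.maximum(sd, 1e-300)),
            seed=doc.get("seed"),
        )
    return LoadedModel(
        spec=spec, layout=layout, summaries=summaries,
        seed=doc.get("seed"), posterior=posterior,
    )
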