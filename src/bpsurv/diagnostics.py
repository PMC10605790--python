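"""Posterior-comparison and decision statistics.

Highest-density intervals, the kernel-density overlap index (OVI) between
two sets of draws, ROPE equivalence decisions on a difference distribution,
Bonferroni arithmetic and the superiority-design sample size. These are the
statistics used to decide whether two trainings of a model are practically
equivalent and how many experiment replicates such a comparison needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ROPE = (-0.01, 0.01)


def hdi(samples, level: float = 0.94) -> tuple[float, float]:
    """Highest-density interval: the narrowest interval holding ``level`` mass.

    Implemented as the minimum-width window over the sorted draws
    (exact for unimodal posteriors, the standard empirical HDI).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ValueError(f"need >= 100 samples for a stable HDI, got {samples.size}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(samples)
    n = x.size
    k = max(1, math.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def overlap_index(samples_a, samples_b, grid_size: int = 512) -> float:
    """OVI: integral of the pointwise minimum of two KDE densities, in [0, 1].

    Each sample gets a Gaussian KDE with Silverman bandwidth; the minimum
    density is integrated on a shared grid spanning the pooled range plus
    three pooled bandwidths on each side. 1 = identical, 0 = disjoint.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    for name, s in (("samples_a", a), ("samples_b", b)):
        if s.size < 100:
            raise ValueError(f"{name}: need >= 100 draws, got {s.size}")
        if np.std(s) == 0:
            raise ValueError(f"{name}: zero variance, KDE undefined")
    kde_a = stats.gaussian_kde(a, bw_method="silverman")
    kde_b = stats.gaussian_kde(b, bw_method="silverman")
    bw = max(kde_a.factor * a.std(ddof=1), kde_b.factor * b.std(ddof=1))
    lo = min(a.min(), b.min()) - 3.0 * bw
    hi = max(a.max(), b.max()) + 3.0 * bw
    grid = np.linspace(lo, hi, grid_size)
    ovi = np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid)
    return float(min(ovi, 1.0))


@dataclass
class RopeDecision:
    decision: str  # "accepted" | "rejected" | "undecided"
    pct_in_rope: float
    hdi: tuple[float, float]


def rope_equivalence(
    diff_samples,
    rope: tuple[float, float] = DEFAULT_ROPE,
    hdi_level: float = 0.9833,
) -> RopeDecision:
    """Equivalence decision for a difference distribution against a ROPE.

    The credible interval (HDI at ``hdi_level``) is compared with the
    region of practical equivalence: fully inside -> accepted, fully
    outside -> rejected, otherwise undecided. ``pct_in_rope`` is the
    percentage of the interval's length inside the ROPE.
    """
    lo_r, hi_r = rope
    if lo_r >= hi_r:
        raise ValueError("invalid ROPE: lower bound must be below upper bound")
    diff_samples = np.asarray(diff_samples, dtype=float).ravel()
    if diff_samples.size == 0:
        raise ValueError("diff_samples is empty")
    if np.ptp(diff_samples) == 0:
        lo = hi = float(diff_samples[0])
    else:
        lo, hi = hdi(diff_samples, hdi_level)
    if hi == lo:
        pct = 100.0 if lo_r <= lo <= hi_r else 0.0
    else:
        inside = max(0.0, min(hi, hi_r) - max(lo, lo_r))
        pct = 100.0 * inside / (hi - lo)
    if lo >= lo_r and hi <= hi_r:
        decision = "accepted"
    elif hi < lo_r or lo > hi_r:
        decision = "rejected"
    else:
        decision = "undecided"
    return RopeDecision(decision=decision, pct_in_rope=pct, hdi=(lo, hi))


def superiority_sample_size(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.8
) -> int:
    """Per-group n for a two-sided two-sample t-test detecting ``delta``.

    Inverts noncentral-t power at effect size d = delta / sd and rounds up.
    """
    if delta == 0:
        raise ValueError("delta must be non-zero (no finite n detects a zero difference)")
    if delta < 0 or sd <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("delta, sd must be positive; alpha, power in (0, 1)")
    from statsmodels.stats.power import TTestIndPower

    n = TTestIndPower().solve_power(
        effect_size=delta / sd, alpha=alpha, power=power, alternative="two-sided"
    )
    return int(math.ceil(n))


def bonferroni(alpha_family: float, n_comparisons: int) -> float:
    """Per-test significance level alpha / n."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha_family / n_comparisons


def pairwise_count(n_models: int) -> int:
    """Number of unordered model pairs: n(n-1)/2."""
    return n_models * (n_models - 1) // 2


def mean_difference_posterior(
    diffs, n_draws: int = 20000, seed: int | None = None
) -> np.ndarray:
    """Posterior draws of the mean of replicate-level differences.

    Under a normal model with Jeffreys prior, the posterior of the mean is
    mean(d) + sd(d)/sqrt(R) * t_{R-1}; these draws feed
    :func:`rope_equivalence` when deciding whether two training strategies
    are practically equivalent across experiment replicates.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    if d.size < 3:
        raise ValueError("need at least 3 replicate differences")
    rng = np.random.default_rng(seed)
    se = d.std(ddof=1) / math.sqrt(d.size)
    return d.mean() + se * rng.standard_t(df=d.size - 1, size=n_draws)
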