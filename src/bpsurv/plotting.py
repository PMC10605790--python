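"""Basic survival-curve figure helper."""

from __future__ import annotations

from .inference import SurvivalCurves


def plot_survival_curves(curves: SurvivalCurves, subjects=None, ax=None, labels=None):
    """Plot mean survival curves with their uncertainty bands.

    Parameters
    ----------
    curves : SurvivalCurves
    subjects : iterable of int, optional
        Row indices to draw (default: all).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    idx = range(curves.mean.shape[0]) if subjects is None else subjects
    for j, i in enumerate(idx):
        label = labels[j] if labels else f"subject {i}"
        line, = ax.plot(curves.time_grid, curves.mean[i], label=label)
        ax.fill_between(
            curves.time_grid, curves.lower[i], curves.upper[i],
            alpha=0.2, color=line.get_color(),
        )
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
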