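"""Optional matplotlib rendering of traces and fits."""

from __future__ import annotations

import numpy as np

from .core import PerturbationProfile, Trace

__all__ = ["plot_group_fit"]


def plot_group_fit(
    mean: Trace,
    sem: np.ndarray | None = None,
    model: Trace | None = None,
    pert: PerturbationProfile | None = None,
    ax=None,
):
    """Group mean ± SEM with an optional model overlay.

    When the perturbation profile is given, the full-compensation
    reference (the inverse of the applied shift, i.e. the deviation
    that would exactly cancel the heard change) is drawn as well.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t_ms = mean.grid.times * 1000.0
    ax.plot(t_ms, mean.values, color="tab:blue", label="group mean")
    if sem is not None:
        ax.fill_between(t_ms, mean.values - sem, mean.values + sem,
                        color="tab:blue", alpha=0.25, linewidth=0)
    if model is not None:
        ax.plot(t_ms, model.values, color="tab:red", label="model fit")
    if pert is not None:
        full_comp = 1.0 / (1.0 + pert.values) - 1.0
        ax.plot(t_ms, full_comp, color="tab:green", linestyle="--",
                label="full compensation")
    ax.axvline(0.0, color="0.6", linewidth=0.8)
    ax.set_xlabel("time re perturbation onset (ms)")
    ax.set_ylabel("normalized $f_o$ deviation")
    ax.legend(frameon=False)
    return ax
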