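"""Plots for fitted models and validation output (matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .jlcm import JLCMResults
from .validation import CalibrationGroups, _labeled


def plot_trajectories(fitted: JLCMResults, t_max: float = 104.0, ax=None):
    """Mean DAS28 trajectory of each latent class over follow-up."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, t_max, 200)
    T = np.vander(t, fitted.params.beta.shape[1], increasing=True)
    for g in range(fitted.spec.n_classes):
        ax.plot(t, T @ fitted.params.beta[g],
                label=f"class {g + 1} (pi={fitted.params.pi[g]:.2f})")
    ax.axhline(3.2, ls=":", color="grey", lw=0.8)
    ax.set_xlabel("weeks from baseline")
    ax.set_ylabel("DAS28")
    ax.legend()
    return ax


def plot_roc(preds: Sequence, ax=None):
    """Empirical ROC curve of pooled landmark predictions."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    risks, y, _ = _labeled(preds)
    order = np.argsort(-risks)
    y = y[order]
    tpr = np.concatenate([[0], np.cumsum(y) / max(y.sum(), 1)])
    fpr = np.concatenate([[0], np.cumsum(1 - y) / max((1 - y).sum(), 1)])
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    return ax


def plot_calibration(groups: CalibrationGroups, ax=None):
    """Mean predicted risk vs observed flare frequency per quartile group."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(groups.mean_predicted, groups.observed_frequency, "o-")
    lim = max(0.05, groups.mean_predicted.max(), groups.observed_frequency.max()) * 1.1
    ax.plot([0, lim], [0, lim], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("mean predicted 3-month flare risk")
    ax.set_ylabel("observed flare frequency")
    return ax
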