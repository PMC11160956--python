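"""Convenience plots.  Figures are illustrations only; every asserted
number in the pipeline comes from the result tables, never from a plot."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .individual import LambdaResult
from .population import BlandAltman
from .quality import SweepRow, logit


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_lambda_box(groups: Mapping[str, Sequence[LambdaResult]], ax=None):
    """Boxplots of λ per group (cohort or cohort×method)."""
    ax = _get_ax(ax)
    labels = list(groups)
    data = [[r.lambda_pct for r in groups[k]] for k in labels]
    ax.boxplot(data, tick_labels=labels)
    ax.axhline(25.0, ls="--", lw=0.8, color="grey")
    ax.set_ylabel("lambda (%)")
    return ax


def plot_sweep(rows: Sequence[SweepRow], ax=None):
    """Max / median / min λ versus exclusion fraction."""
    ax = _get_ax(ax)
    f = [r.exclusion_fraction for r in rows]
    for attr, style in (("lambda_max", "--o"), ("lambda_median", "-s"), ("lambda_min", ":v")):
        ax.plot(f, [getattr(r, attr) for r in rows], style, label=attr.replace("lambda_", ""))
    ax.set_xlabel("fraction of images excluded by quality")
    ax.set_ylabel("lambda (%)")
    ax.legend()
    return ax


def plot_lambda_vs_quality(lambdas: Sequence[LambdaResult], scale: str = "probability", ax=None):
    """Scatter of λ against worst P(bad) per eye."""
    ax = _get_ax(ax)
    x = np.asarray([r.worst_pbad for r in lambdas])
    if scale == "logit":
        x = logit(x)
        ax.set_xlabel("logit(worst P(bad) per eye)")
    else:
        ax.set_xlabel("worst P(bad) per eye")
    y = [r.lambda_pct for r in lambdas]
    ax.scatter(x, y, s=12)
    ax.axhline(25.0, ls="--", lw=0.8, color="grey")
    ax.set_ylabel("lambda (%)")
    return ax


def plot_bland_altman(value_a, value_b, ba: BlandAltman, ax=None):
    """Bland–Altman plot: difference vs mean with limits of agreement."""
    ax = _get_ax(ax)
    a = np.asarray(value_a, dtype=float)
    b = np.asarray(value_b, dtype=float)
    ax.scatter((a + b) / 2.0, a - b, s=12)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, ls=style[0] if style == "-" else "--", lw=0.8, color="grey")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    return ax
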