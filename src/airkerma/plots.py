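"""Optional diagnostics: regression scatter and error histogram.

Matplotlib is imported lazily so the core package works without it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["regression_plot", "error_histogram"]


def _axis(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def regression_plot(expected, predicted, ax=None):
    """Predicted vs reference kerma with the identity line."""
    expected = np.asarray(expected, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ax = _axis(ax)
    ax.scatter(expected, predicted, s=12, facecolors="none", edgecolors="green")
    lo, hi = expected.min(), expected.max()
    ax.plot([lo, hi], [lo, hi], color="gold", lw=1.5)
    ax.set_xlabel("reference air kerma")
    ax.set_ylabel("predicted air kerma")
    return ax


def error_histogram(expected, predicted, bins=30, ax=None):
    """Histogram of prediction residuals (reference minus predicted)."""
    expected = np.asarray(expected, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ax = _axis(ax)
    ax.hist(expected - predicted, bins=bins, color="steelblue")
    ax.set_xlabel("residual (reference - predicted)")
    ax.set_ylabel("count")
    return ax
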