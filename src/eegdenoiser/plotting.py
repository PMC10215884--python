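"""Overlay plots of ground-truth, noisy and predicted segments."""

from __future__ import annotations

import numpy as np


def overlay_segments(x_hat, y_hat=None, z_hat=None, fs=256, ax=None):
    """Plot x̂ (and optionally ŷ, ẑ) on a shared time axis.

    Returns the matplotlib Axes.  Matplotlib is imported lazily so the rest
    of the package has no hard plotting dependency.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    x_hat = np.asarray(x_hat)
    t = np.arange(x_hat.size) / fs
    if y_hat is not None:
        ax.plot(t, y_hat, color="0.7", lw=0.8, label="noisy")
    ax.plot(t, x_hat, color="C0", lw=1.0, label="ground truth")
    if z_hat is not None:
        ax.plot(t, z_hat, color="C3", lw=1.0, ls="--", label="predicted")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized amplitude")
    ax.legend(frameon=False, ncol=3)
    return ax
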