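"""Optional diagnostic figures (best-effort, matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def plot_correction_panels(
    m, cs, times: Sequence[int], path=None, channel_range=None
):
    """Stacked panels of original vs background-corrected spectra at selected
    time points (0-based).  Returns the figure; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axis = m.axis
    lo, hi = (0, m.W) if channel_range is None else channel_range
    fig, axes = plt.subplots(
        len(times), 2, figsize=(9, 2.2 * len(times)), squeeze=False, sharex=True
    )
    for row, t in enumerate(times):
        axes[row][0].plot(axis[lo:hi], m.intensities[t, lo:hi], lw=0.7, color="k")
        axes[row][0].set_ylabel(f"t={t + 1}")
        axes[row][1].plot(axis[lo:hi], cs.values[t, lo:hi], lw=0.7, color="k")
        axes[row][1].axhline(0.0, lw=0.5, color="r")
    axes[0][0].set_title("original")
    axes[0][1].set_title("background-corrected")
    axes[-1][0].set_xlabel("wavenumber / channel")
    axes[-1][1].set_xlabel("wavenumber / channel")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_signature_overlay(signatures, path=None, labels=None):
    """Overlay signature spectra restricted to the union of their supports."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    for k, s in enumerate(signatures):
        label = labels[k] if labels else f"t={s.time_index + 1}"
        ax.plot(np.arange(1, s.spectrum.size + 1), s.spectrum, lw=0.8, label=label)
    ax.set_xlabel("frequency channel")
    ax.set_ylabel("corrected intensity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
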