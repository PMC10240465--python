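"""Plotting helpers for p-value heat maps and group spectra."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_pvalue_grid", "plot_group_psd"]


def plot_pvalue_grid(grid, ax=None, alpha=None):
    """Heat map of a p-value grid; significant cells are outlined.

    Mirrors the convention of clinical-EEG feature heat maps: colour encodes
    the p-value (warm = small), cells below the significance threshold get a
    box.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.6 * len(grid.col_labels), 1 + 0.45 * len(grid.row_labels))
        )
    alpha = alpha if alpha is not None else grid.alpha
    im = ax.imshow(grid.p, cmap="RdYlBu", vmin=0.0, vmax=1.0, aspect="auto")
    ax.set_xticks(range(len(grid.col_labels)), grid.col_labels, rotation=90)
    ax.set_yticks(range(len(grid.row_labels)), grid.row_labels)
    ax.set_title(f"{grid.family} (p < {alpha:g} outlined)")
    for i in range(len(grid.row_labels)):
        for j in range(len(grid.col_labels)):
            if grid.p[i, j] < alpha:
                ax.add_patch(
                    __import__("matplotlib.patches", fromlist=["Rectangle"]).Rectangle(
                        (j - 0.5, i - 0.5), 1, 1, fill=False, lw=1.5, ec="black"
                    )
                )
    ax.figure.colorbar(im, ax=ax, label="p")
    return ax


def plot_group_psd(band_power, labels, ax=None):
    """Group-mean relative band power with between-subject SD bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    bands = list(band_power.columns)
    x = np.arange(len(bands))
    width = 0.38
    for k, group in enumerate(("high", "low")):
        sub = band_power[labels == group]
        ax.bar(
            x + (k - 0.5) * width,
            sub.mean(),
            width,
            yerr=sub.std(),
            capsize=3,
            label=f"{group} ESS (n={len(sub)})",
        )
    ax.set_xticks(x, bands)
    ax.set_ylabel("relative band power")
    ax.legend()
    return ax
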