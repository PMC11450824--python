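"""Figure exports: oscillation heatmaps and rose plots of contraction
directionality."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_oscillation_map(osc_map: pd.DataFrame, path, *, f0: float | None = 0.008) -> None:
    """Heatmap of FFT amplitude over (depth offset, frequency).

    Rows of ``osc_map`` are depth offsets from the nuclear midplane (µm,
    positive apical), columns are frequencies (Hz); the colour scale is
    the FFT amplitude.  A dotted line marks ``f0`` when given.
    """
    offs = osc_map.index.to_numpy(dtype=float)
    freqs = osc_map.columns.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(freqs, offs, osc_map.to_numpy(), shading="nearest", cmap="magma")
    if f0 is not None:
        ax.axvline(f0, color="w", ls=":", lw=1)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("depth offset from nuclear midplane (µm)")
    fig.colorbar(im, ax=ax, label="FFT amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rose(histogram: pd.DataFrame, path) -> None:
    """Polar histogram of contracting-interface angles.

    0° (DV-aligned vertical interfaces) points up; the histogram is
    mirrored so each angle bin appears on both sides, as conventional for
    interface-orientation rose plots.
    """
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    centers = np.deg2rad(
        (histogram["bin_left_deg"].to_numpy() + histogram["bin_right_deg"].to_numpy()) / 2.0
    )
    widths = np.deg2rad(histogram["bin_right_deg"].to_numpy() - histogram["bin_left_deg"].to_numpy())
    counts = histogram["count"].to_numpy()
    ax.bar(centers, counts, width=widths, alpha=0.8)
    ax.bar(centers + np.pi, counts, width=widths, alpha=0.8, color="C0")
    ax.set_yticklabels([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
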