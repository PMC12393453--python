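"""Figure outputs: raster heatmap, frequency bars, flux trend, permeability."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["raster_heatmap", "frequency_bars", "flux_trend_plot", "permeability_plot"]


def raster_heatmap(raster: np.ndarray, frame_interval: float, path=None, cell_ids=None):
    """Binary on/off signaling heatmap, time axis in seconds."""
    n_cells, n_frames = raster.shape
    fig, ax = plt.subplots(figsize=(8, max(2, n_cells * 0.12)))
    ax.imshow(
        raster,
        aspect="auto",
        interpolation="nearest",
        cmap="Greys",
        extent=(0, n_frames * frame_interval, n_cells - 0.5, -0.5),
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cell")
    if cell_ids is not None and n_cells <= 40:
        ax.set_yticks(range(n_cells))
        ax.set_yticklabels(cell_ids)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def frequency_bars(bars, path=None):
    """Per-cell event frequency bar plot (events/minute)."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(bars["cell_id"].astype(str), bars["frequency"], color="0.3")
    ax.set_xlabel("cell")
    ax.set_ylabel("frequency (events/min)")
    if len(bars) > 30:
        ax.set_xticks([])
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def flux_trend_plot(flux, trend, labels=None, block_duration=2.0, path=None):
    """Per-block flux with the 5-point smoothed trend, during-blocks shaded."""
    t = np.arange(len(flux)) * block_duration
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, flux, color="0.7", label="flux")
    ax.plot(t, trend, color="k", label="trend")
    if labels is not None:
        for i, lab in enumerate(labels):
            if lab == "during":
                ax.axvspan(t[i], t[i] + block_duration, color="g", alpha=0.15, lw=0)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("flux (cells/s)")
    ax.legend(loc="upper right", frameon=False)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def permeability_plot(series, path=None):
    """Normalized extravascular MFI over minutes post-injection."""
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(series.times_min, series.normalized, color="m")
    ax.set_xlabel("time post-injection (min)")
    ax.set_ylabel("extravascular MFI (norm.)")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
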