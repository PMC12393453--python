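"""Mean-fluorescence trace extraction from movies.

Per-cell traces come from a labeled nuclear mask (the nuclear signal is the
proxy for the cell body; the ROI is the nuclear mask itself, without
dilation).  Per-grid traces come from tiling the vessel mask into
0.0076 x 0.0076 mm^2 squares anchored at the image origin; a grid is kept
iff it overlaps the vessel mask, and its trace averages over its vessel
pixels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "CellTrace",
    "GridGeometry",
    "extract_traces",
    "traces_to_frame",
    "extract_grid_traces",
]

DEFAULT_GRID_MM = 0.0076


@dataclass
class Recording:
    """A fixed-interval fluorescence timelapse.

    ``frames``: (time, y, x) intensity array; ``pixel_size_mm`` is needed
    only for grid tiling.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size_mm: float | None = None
    bit_depth: int = 8

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, y, x)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def minutes(self) -> float:
        return self.n_frames * self.frame_interval / 60.0


@dataclass
class CellTrace:
    cell_id: int
    mfi: np.ndarray
    n_pixels: int


@dataclass
class GridGeometry:
    """One retained grid of the vessel-surface tiling."""

    grid_id: int
    row: int
    col: int
    y_bounds: tuple[float, float]  # half-open [y0, y1) in pixels
    x_bounds: tuple[float, float]
    n_vessel_pixels: int


def extract_traces(recording: Recording, labels: np.ndarray) -> list[CellTrace]:
    """One mean-fluorescence trace per nonzero label, sorted by label.

    ``mfi[t]`` is the arithmetic mean of frame ``t`` over the ROI's pixels.
    Labels with zero pixels are skipped with a warning; a spatial shape
    mismatch is a hard error.
    """
    labels = np.asarray(labels)
    if labels.shape != recording.frames.shape[1:]:
        raise ValueError(
            f"label shape {labels.shape} != frame shape {recording.frames.shape[1:]}"
        )
    if labels.min() < 0:
        raise ValueError("labels must be nonnegative integers")
    flat = labels.ravel()
    n_lab = int(flat.max())
    counts = np.bincount(flat, minlength=n_lab + 1)
    movie_flat = recording.frames.reshape(recording.n_frames, -1)
    sums = np.empty((recording.n_frames, n_lab + 1))
    for t in range(recording.n_frames):
        sums[t] = np.bincount(flat, weights=movie_flat[t], minlength=n_lab + 1)
    traces = []
    for lab in range(1, n_lab + 1):
        if counts[lab] == 0:
            warnings.warn(f"label {lab} has no pixels; skipped", stacklevel=2)
            continue
        traces.append(CellTrace(lab, sums[:, lab] / counts[lab], int(counts[lab])))
    return traces


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Wide table: one column per cell id, one row per frame."""
    return pd.DataFrame({t.cell_id: t.mfi for t in traces})


def extract_grid_traces(
    recording: Recording,
    vessel_mask: np.ndarray,
    grid_size_mm: float = DEFAULT_GRID_MM,
    pixel_size_mm: float | None = None,
) -> tuple[pd.DataFrame, list[GridGeometry]]:
    """Per-grid mean traces over the vessel surface.

    The tiling is anchored at pixel (0, 0); pixel (y, x) belongs to grid
    ``(floor(y*ps/g), floor(x*ps/g))``, which handles non-integer grid
    widths exactly.  Edge grids may be partial.  A grid is retained iff it
    contains >= 1 vessel-mask pixel, and its trace averages over those
    vessel pixels only.  An empty vessel mask yields an empty result.
    """
    ps = pixel_size_mm if pixel_size_mm is not None else recording.pixel_size_mm
    if ps is None:
        raise ValueError("pixel_size_mm is required for grid tiling")
    if grid_size_mm <= 0:
        raise ValueError("grid_size_mm must be positive")
    vessel_mask = np.asarray(vessel_mask).astype(bool)
    if vessel_mask.shape != recording.frames.shape[1:]:
        raise ValueError("vessel mask shape mismatch")

    g_px = grid_size_mm / ps
    ys, xs = np.nonzero(vessel_mask)
    if ys.size == 0:
        return pd.DataFrame(), []
    rows = np.floor(ys * ps / grid_size_mm).astype(int)
    cols = np.floor(xs * ps / grid_size_mm).astype(int)
    keys = sorted(set(zip(rows.tolist(), cols.tolist())))
    gid_of = {rc: i for i, rc in enumerate(keys)}
    gid = np.array([gid_of[rc] for rc in zip(rows.tolist(), cols.tolist())])

    movie_flat = recording.frames.reshape(recording.n_frames, -1)
    pix = ys * vessel_mask.shape[1] + xs
    n_grids = len(keys)
    counts = np.bincount(gid, minlength=n_grids)
    data = np.empty((recording.n_frames, n_grids))
    for t in range(recording.n_frames):
        data[t] = np.bincount(gid, weights=movie_flat[t][pix], minlength=n_grids) / counts

    geometry = [
        GridGeometry(
            grid_id=i,
            row=r,
            col=c,
            y_bounds=(r * g_px, (r + 1) * g_px),
            x_bounds=(c * g_px, (c + 1) * g_px),
            n_vessel_pixels=int(counts[i]),
        )
        for i, (r, c) in enumerate(keys)
    ]
    return pd.DataFrame(data, columns=range(n_grids)), geometry
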