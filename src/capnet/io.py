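"""Reading and writing the pipeline's file formats.

Movies are multi-page TIFF; label and binary masks are single-page TIFF or
PNG; traces are wide CSV (one column per cell, one row per frame) with a
metadata comment header carrying the frame interval; event tables,
dynamics, clusters and revisit pairs are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio.v3 import imread as _imread

from .traces import GridGeometry, Recording

__all__ = [
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "read_traces",
    "write_traces",
    "read_events",
    "write_events",
    "write_grid_geometry",
    "read_grid_geometry",
]


def write_movie(path, movie: np.ndarray, as_uint8: bool = True) -> None:
    """Write a (time, y, x) stack as multi-page TIFF.

    With ``as_uint8`` the 0-255 float movie is rounded to 8-bit; otherwise a
    16-bit export is written with the scale factor recorded in the TIFF
    description so persistence detection can rescale to 0-255.
    """
    movie = np.asarray(movie)
    if as_uint8:
        tifffile.imwrite(
            path,
            np.clip(np.rint(movie), 0, 255).astype(np.uint8),
            photometric="minisblack",
        )
    else:
        scale = 65535.0 / 255.0
        tifffile.imwrite(
            path,
            np.clip(np.rint(movie * scale), 0, 65535).astype(np.uint16),
            photometric="minisblack",
            description=json.dumps({"scale_factor": scale}),
        )


def read_movie(path, frame_interval: float, pixel_size_mm: float | None = None) -> Recording:
    """Read a multi-page TIFF movie into a :class:`Recording` on the 0-255 scale."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].description
    frames = np.atleast_3d(frames)
    bit_depth = 8
    if frames.dtype == np.uint16:
        bit_depth = 16
        scale = 65535.0 / 255.0
        if desc:
            try:
                scale = float(json.loads(desc).get("scale_factor", scale))
            except (ValueError, json.JSONDecodeError):
                pass
        frames = frames.astype(np.float32) / scale
    return Recording(
        frames=frames,
        frame_interval=frame_interval,
        pixel_size_mm=pixel_size_mm,
        bit_depth=bit_depth,
    )


def write_mask(path, mask: np.ndarray) -> None:
    """Write a label mask (uint16 TIFF) or binary mask (uint8)."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        tifffile.imwrite(path, mask.astype(np.uint8) * 255)
    else:
        tifffile.imwrite(path, mask.astype(np.uint16))


def read_mask(path, binary: bool = False) -> np.ndarray:
    """Read a TIFF/PNG mask; ``binary=True`` thresholds nonzero pixels."""
    arr = _imread(path)
    if arr.ndim == 3:  # drop a color axis if present
        arr = arr[..., 0]
    return arr > 0 if binary else arr.astype(np.int64)


def write_traces(path, traces: pd.DataFrame, frame_interval: float) -> None:
    """Wide trace CSV with a ``# frame_interval=<s>`` metadata header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_interval={frame_interval}\n")
        traces.to_csv(fh, index=False)


def read_traces(path) -> tuple[pd.DataFrame, float]:
    """Read a trace CSV written by :func:`write_traces`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    frame_interval = None
    skip = 0
    if first.startswith("#"):
        skip = 1
        for part in first.lstrip("#").split(","):
            key, _, val = part.strip().partition("=")
            if key == "frame_interval":
                frame_interval = float(val)
    if frame_interval is None:
        raise ValueError("trace CSV lacks a frame_interval header")
    df = pd.read_csv(path, skiprows=skip)
    df.columns = [int(c) for c in df.columns]
    return df, frame_interval


def write_events(path, events: pd.DataFrame) -> None:
    events.to_csv(path, index=False)


def read_events(path, frame_interval: float | None = None) -> pd.DataFrame:
    """Read an event-interval table.

    Accepts either frame columns (``cell_id,start_frame,end_frame``) or
    second columns (``cell_id,start_s,end_s`` plus ``frame_interval`` to
    convert); XLSX is accepted alongside CSV.
    """
    path = Path(path)
    df = pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(path)
    if {"start_frame", "end_frame"}.issubset(df.columns):
        out = df.copy()
        if "duration_s" not in out.columns:
            if frame_interval is None:
                raise ValueError("frame_interval needed to compute duration_s")
            out["duration_s"] = (
                out["end_frame"] - out["start_frame"] + 1
            ) * frame_interval
    elif {"start_s", "end_s"}.issubset(df.columns):
        if frame_interval is None:
            raise ValueError("frame_interval needed to convert seconds to frames")
        out = pd.DataFrame(
            {
                "cell_id": df["cell_id"],
                "start_frame": np.rint(df["start_s"] / frame_interval).astype(int),
                "end_frame": np.rint(df["end_s"] / frame_interval).astype(int),
            }
        )
        out["duration_s"] = (out["end_frame"] - out["start_frame"] + 1) * frame_interval
    else:
        raise ValueError("event table needs start_frame/end_frame or start_s/end_s columns")
    if "censored" not in out.columns:
        out["censored"] = False
    return out


def write_grid_geometry(path, geometry: list[GridGeometry]) -> None:
    data = [
        {
            "grid_id": g.grid_id,
            "row": g.row,
            "col": g.col,
            "y_bounds": list(g.y_bounds),
            "x_bounds": list(g.x_bounds),
            "n_vessel_pixels": g.n_vessel_pixels,
        }
        for g in geometry
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def read_grid_geometry(path) -> list[GridGeometry]:
    data = json.loads(Path(path).read_text())
    return [
        GridGeometry(
            grid_id=d["grid_id"],
            row=d["row"],
            col=d["col"],
            y_bounds=tuple(d["y_bounds"]),
            x_bounds=tuple(d["x_bounds"]),
            n_vessel_pixels=d["n_vessel_pixels"],
        )
        for d in data
    ]
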