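"""Per-cell Ca2+ event calling from fluorescence traces.

A Ca2+ event is a maximal run of frames in which a trace exceeds 1.5x its
windowed minimum fluorescence (a 50% increase above the minimum over each
100-frame normalization window).  Persistent signaling, for which the 50%
rule fails because the minimum itself stays high, is detected separately as
time spent above an absolute intensity of 170 on the 0-255 scale.

The per-cell summary statistics follow the field's conventions: frequency in
events per minute, average duration in seconds per event (total signaling
time divided by the event count), and a ">1 SD" classification of high
frequency / high average duration cells against a reference population of
active cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "window_minima",
    "call_events",
    "events_to_table",
    "call_events_table",
    "compute_dynamics",
    "detect_persistent",
    "classify_dynamics",
    "build_raster",
    "raster_to_events",
]

EVENT_COLUMNS = ["cell_id", "start_frame", "end_frame", "duration_s", "censored"]


@dataclass(frozen=True)
class Event:
    """One detected Ca2+ event: inclusive frame interval of one cell.

    ``censored`` marks events touching the first or last frame of the
    recording; their observed duration is a lower bound.
    """

    start_frame: int
    end_frame: int
    censored: bool = False

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise ValueError("event start after end")

    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def window_minima(values: np.ndarray, window: int = 100) -> np.ndarray:
    """Per-frame minimum-fluorescence reference series.

    Frames are partitioned into consecutive non-overlapping windows
    ``[0, w), [w, 2w), ...`` (the last window may be shorter); every frame's
    reference is the minimum of its window.  ``window`` larger than the
    trace yields a single global-minimum window.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("trace must be a nonempty 1-D array")
    if window < 1:
        raise ValueError("window must be >= 1")
    reference = np.empty_like(values)
    for start in range(0, values.size, window):
        block = slice(start, min(start + window, values.size))
        reference[block] = values[block].min()
    return reference


def call_events(
    values: np.ndarray,
    window: int = 100,
    threshold_ratio: float = 0.5,
    gap_tolerance: int = 0,
) -> list[Event]:
    """Detect Ca2+ events in one trace.

    Frame ``t`` is supra-threshold iff
    ``values[t] > (1 + threshold_ratio) * reference[t]`` (strict), with the
    reference from :func:`window_minima`.  Maximal supra-threshold runs are
    events; runs crossing a window seam merge naturally into one event.
    ``gap_tolerance`` > 0 additionally merges events separated by at most
    that many sub-threshold frames (default 0: no gap merging).
    """
    values = np.asarray(values, dtype=float)
    reference = window_minima(values, window=window)
    supra = values > (1.0 + threshold_ratio) * reference
    runs = _runs(supra)
    if gap_tolerance > 0:
        runs = _merge_gaps(runs, gap_tolerance)
    last = values.size - 1
    return [
        Event(int(s), int(e), censored=(s == 0 or e == last)) for s, e in runs
    ]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) indices of maximal True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e - 1)) for s, e in zip(idx[::2], idx[1::2])]


def _merge_gaps(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def events_to_table(
    events_by_cell: dict[int, list[Event]], frame_interval: float
) -> pd.DataFrame:
    """Flatten per-cell event lists into an event table.

    Columns: ``cell_id, start_frame, end_frame, duration_s, censored`` with
    ``duration_s = (end - start + 1) * frame_interval`` (inclusive frames).
    """
    rows = [
        (cid, ev.start_frame, ev.end_frame, ev.n_frames() * frame_interval, ev.censored)
        for cid in sorted(events_by_cell)
        for ev in sorted(events_by_cell[cid], key=lambda e: e.start_frame)
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS).astype(
        {"cell_id": int, "start_frame": int, "end_frame": int, "censored": bool}
    )


def call_events_table(
    traces: pd.DataFrame,
    frame_interval: float,
    window: int = 100,
    threshold_ratio: float = 0.5,
    gap_tolerance: int = 0,
) -> pd.DataFrame:
    """Run :func:`call_events` on every column of a wide trace table.

    ``traces`` has one column per cell (column name = cell id) and one row
    per frame, as written by :mod:`capnet.traces`.
    """
    events = {
        int(col): call_events(
            traces[col].to_numpy(), window, threshold_ratio, gap_tolerance
        )
        for col in traces.columns
    }
    return events_to_table(events, frame_interval)


def compute_dynamics(
    event_table: pd.DataFrame,
    n_frames: int,
    frame_interval: float,
    cell_ids=None,
) -> pd.DataFrame:
    """Per-cell activity summary from an event table.

    recording_minutes = n_frames * frame_interval / 60; a cell is ``active``
    iff it has >= 1 event; frequency = n_events / recording_minutes
    (events/minute); avg_duration = total signaling seconds / n_events,
    absent (NaN) for inactive cells.  ``cell_ids`` lists the full population
    including event-free cells (defaults to the ids present in the table).
    """
    minutes = n_frames * frame_interval / 60.0
    if cell_ids is None:
        cell_ids = sorted(event_table["cell_id"].unique())
    grouped = event_table.groupby("cell_id")["duration_s"].agg(["count", "sum"])
    rows = []
    for cid in cell_ids:
        if cid in grouped.index:
            n_ev = int(grouped.loc[cid, "count"])
            total_s = float(grouped.loc[cid, "sum"])
        else:
            n_ev, total_s = 0, 0.0
        rows.append(
            {
                "cell_id": cid,
                "status": "active" if n_ev >= 1 else "inactive",
                "n_events": n_ev,
                "frequency": n_ev / minutes,
                "avg_duration": total_s / n_ev if n_ev else np.nan,
                "total_signaling_s": total_s,
            }
        )
    return pd.DataFrame(rows)


def detect_persistent(
    values: np.ndarray,
    frame_interval: float,
    mfi_threshold: float = 170.0,
    scale_max: float = 255.0,
    min_persistent_duration_s: float = 120.0,
) -> tuple[bool, float]:
    """Persistent-signaling call for one trace on the 0-255 scale.

    Time spent strictly above ``mfi_threshold`` (170 out of 255) counts as
    persistent signaling; the cell is flagged persistent iff that time
    reaches ``min_persistent_duration_s`` (default 120 s — persistent events
    run minutes, from ~2 minutes up to the full recording, so a brief bright
    transient alone does not qualify).  Returns (persistent, supra-threshold
    seconds).  Traces on a larger scale must be rescaled first; intensities
    above ``scale_max`` are a hard error.
    """
    values = np.asarray(values, dtype=float)
    if values.max(initial=0.0) > scale_max:
        raise ValueError(
            f"trace exceeds scale_max={scale_max}; rescale 16-bit input to 0-255 first"
        )
    duration_s = float(np.count_nonzero(values > mfi_threshold) * frame_interval)
    return duration_s >= min_persistent_duration_s, duration_s


def classify_dynamics(
    dynamics: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    ddof: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Flag high-frequency / high-average-duration cells (>1 SD rule).

    Thresholds are mean + 1 sample SD of frequency and of avg_duration over
    the *active* cells of the reference population (default: ``dynamics``
    itself; for revisits pass the Day-0 table, for knockouts the control
    table).  A cell is high_frequency if its frequency is strictly above the
    frequency threshold, high_avg_duration likewise; the flags are not
    mutually exclusive and both are kept.  Returns the annotated copy and
    the thresholds used.
    """
    ref = reference if reference is not None else dynamics
    ref_active = ref[ref["status"] == "active"]
    if len(ref_active) < 2:
        raise ValueError("classification needs >= 2 active cells in the reference")
    thresholds = {
        "frequency": float(
            ref_active["frequency"].mean() + ref_active["frequency"].std(ddof=ddof)
        ),
        "avg_duration": float(
            ref_active["avg_duration"].mean()
            + ref_active["avg_duration"].std(ddof=ddof)
        ),
        "ddof": ddof,
    }
    out = dynamics.copy()
    active = out["status"] == "active"
    out["high_frequency"] = active & (out["frequency"] > thresholds["frequency"])
    out["high_avg_duration"] = active & (
        out["avg_duration"] > thresholds["avg_duration"]
    )

    def label(row):
        if row["status"] != "active":
            return "inactive"
        tags = [
            t
            for t, flag in [
                ("high_frequency", row["high_frequency"]),
                ("high_avg_duration", row["high_avg_duration"]),
            ]
            if flag
        ]
        return "+".join(tags) if tags else "normal"

    out["dynamics_class"] = out.apply(label, axis=1)
    return out, thresholds


def build_raster(
    event_table: pd.DataFrame,
    n_frames: int,
    frame_interval: float,
    cell_ids=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary cell x time activity raster plus per-cell frequency bar data.

    ``raster[c, t] = 1`` iff frame ``t`` lies inside an event of cell ``c``
    (rows ordered by ``cell_ids``).  Overlapping events for one cell violate
    the event-table invariant and raise.  The second return value holds the
    frequency-bar data (cell_id, n_events, frequency).
    """
    if cell_ids is None:
        cell_ids = sorted(event_table["cell_id"].unique())
    row_of = {cid: i for i, cid in enumerate(cell_ids)}
    raster = np.zeros((len(cell_ids), n_frames), dtype=np.uint8)
    for rec in event_table.itertuples(index=False):
        r = row_of[rec.cell_id]
        if not (0 <= rec.start_frame <= rec.end_frame < n_frames):
            raise ValueError("event outside the recording")
        if raster[r, rec.start_frame : rec.end_frame + 1].any():
            raise ValueError(f"overlapping events for cell {rec.cell_id}")
        raster[r, rec.start_frame : rec.end_frame + 1] = 1
    minutes = n_frames * frame_interval / 60.0
    counts = event_table.groupby("cell_id").size()
    bars = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "n_events": [int(counts.get(c, 0)) for c in cell_ids],
        }
    )
    bars["frequency"] = bars["n_events"] / minutes
    return raster, bars


def raster_to_events(
    raster: np.ndarray, frame_interval: float, cell_ids=None
) -> pd.DataFrame:
    """Inverse of :func:`build_raster` (round-trip check helper)."""
    if cell_ids is None:
        cell_ids = list(range(raster.shape[0]))
    events = {
        int(cid): [Event(s, e) for s, e in _runs(raster[i].astype(bool))]
        for i, cid in enumerate(cell_ids)
    }
    table = events_to_table(events, frame_interval)
    # censoring flags are not recoverable from a raster alone
    return table.drop(columns="censored")
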