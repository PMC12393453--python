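"""Synthetic intravital-imaging data with planted ground truth.

Every input the quantification pipeline consumes can be generated here:
timelapse movies with labeled nuclear masks and planted Ca2+ events,
line-scan intensity profiles with cell-transit valleys, vessel masks with
enclosed loops, skeletons with nuclei at known distances, and paired
revisit status tables.  Planted truth is returned alongside so downstream
detectors can be scored against it.

Defaults emulate the study conditions of the homeostatic skin capillary
plexus: 300-frame recordings at 3.44 s/frame, ~50% active cells, event
rate 0.45 events/min per active cell, mean event duration 8.4 s, line scans
at 300 lines/s in 600-sample (2 s) blocks.  Intensities are on a 0-255
(8-bit) scale because the persistence threshold (170/255) is defined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import Event

__all__ = [
    "RecordingSpec",
    "LineScanSpec",
    "GroundTruth",
    "PlacementError",
    "generate_recording",
    "generate_linescan",
    "generate_vessel_geometry",
    "generate_revisit_pair",
]


class PlacementError(RuntimeError):
    """Raised when disjoint ROI placement fails within the retry budget."""


@dataclass
class RecordingSpec:
    """Parameters of a synthetic Ca2+ timelapse recording.

    ``event_rate`` is the expected number of events per minute for each
    ordinary active cell (censored Poisson process: events truncated at the
    recording boundaries are kept and flagged).  ``event_amplitude`` is the
    multiplicative gain over baseline during an event and must exceed the
    detector's 1.5x rule for events to be recoverable.  Persistent cells
    hold a constant ``persistent_mfi`` (> 170) for the whole recording.
    """

    n_frames: int = 300
    frame_interval: float = 3.44
    n_cells: int = 50
    active_fraction: float = 0.5
    event_rate: float = 0.45          # events/minute per ordinary active cell
    duration_mean: float = 8.4        # seconds
    persistent_fraction: float = 0.0  # of active cells
    baseline_mfi: float = 100.0
    event_amplitude: float = 1.6
    persistent_mfi: float = 200.0
    noise_sd: float = 0.0
    bleach_rate: float = 0.0          # fractional decay per frame
    rng_seed: int = 0
    image_shape: tuple[int, int] = (160, 160)

    def validate(self) -> None:
        if not (0.0 <= self.active_fraction <= 1.0):
            raise ValueError("active_fraction must be in [0, 1]")
        if not (0.0 <= self.persistent_fraction <= 1.0):
            raise ValueError("persistent_fraction must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.event_amplitude <= 1.5:
            raise ValueError("event_amplitude must exceed 1.5 (the detector rule)")


@dataclass
class LineScanSpec:
    """Parameters of a synthetic line-scan pair (red dextran, green Ca2+).

    ``flux_true`` is cells/second per block; the planted transit count per
    block is ``round(flux_true * block_duration)`` (rounded to the nearest
    integer, documented rounding rule).  Valleys are smooth dips of exact
    support ``valley_width`` samples.  Green block means sit at
    ``green_baseline`` except on ``green_event_blocks`` where they are
    raised above 1.5x the minimum block mean.
    """

    n_blocks: int = 150
    block_width: int = 600
    lines_per_second: float = 300.0
    flux_true: float = 1.5            # cells/second, or per-block sequence
    valley_depth: float = 120.0
    valley_width: int = 20
    min_separation: int | None = None   # default 2 x valley_width (no collisions)
    baseline: float = 200.0
    noise_sd: float = 0.0
    green_baseline: float = 10.0
    green_event_level: float = 40.0
    green_event_blocks: frozenset = field(default_factory=frozenset)
    rng_seed: int = 0

    @property
    def block_duration(self) -> float:
        return self.block_width / self.lines_per_second

    def counts_per_block(self) -> np.ndarray:
        flux = np.broadcast_to(
            np.asarray(self.flux_true, dtype=float), (self.n_blocks,)
        )
        return np.rint(flux * self.block_duration).astype(int)


@dataclass
class GroundTruth:
    """Planted truth for scoring downstream detectors.

    Only the fields relevant to the generator that produced it are filled.
    """

    events: pd.DataFrame | None = None          # cell_id, start_frame, end_frame, censored
    active_cells: set = field(default_factory=set)
    persistent_cells: set = field(default_factory=set)
    roi_traces: np.ndarray | None = None        # noise-free per-cell mean traces
    transits: list | None = None                # per-block planted valley counts
    valley_centers: list | None = None          # per-block sample positions
    green_event_blocks: set = field(default_factory=set)
    loops: list | None = None                   # dicts: area_px, centroid, bbox
    segments: list | None = None                # dicts: path (list of (r, c)), length_um
    nuclei_true_segment: dict = field(default_factory=dict)
    nuclei_distances_um: dict = field(default_factory=dict)


def _place_ellipses(shape, n, rng, a=(2.5, 4.0), b=(1.5, 2.8), margin=2, retries=5000):
    """Disjoint elliptical ROIs with >= ``margin`` px separation.

    Returns a uint16 label mask (labels 1..n).  Separation is enforced by
    keeping an exclusion footprint dilated by ``margin``.
    """
    labels = np.zeros(shape, dtype=np.uint16)
    occupied = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    placed = 0
    for _ in range(retries):
        if placed == n:
            break
        ra = rng.uniform(*a)
        rb = rng.uniform(*b)
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(ra + margin, shape[0] - ra - margin)
        cx = rng.uniform(ra + margin, shape[1] - ra - margin)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
        guard = (u / (ra + margin)) ** 2 + (v / (rb + margin)) ** 2 <= 1.0
        if not inside.any() or (occupied & guard).any():
            continue
        placed += 1
        labels[inside] = placed
        occupied |= guard
    if placed < n:
        raise PlacementError(f"placed only {placed}/{n} ROIs within retry budget")
    return labels


def _plant_cell_events(rng, spec: RecordingSpec) -> list[Event]:
    """Censored-Poisson event placement for one ordinary active cell.

    Event count ~ Poisson(rate x recording minutes); starts uniform over the
    recording; durations exponential with mean ``duration_mean`` (>= 1
    frame).  Events overlapping or abutting an already-planted event are
    dropped so per-cell events stay disjoint with >= 1 quiet frame between
    them (maximal-run detection would otherwise merge them).
    """
    minutes = spec.n_frames * spec.frame_interval / 60.0
    n_ev = rng.poisson(spec.event_rate * minutes)
    taken = np.zeros(spec.n_frames + 2, dtype=bool)  # +1 halo for the gap rule
    events = []
    for _ in range(n_ev):
        start = int(rng.integers(0, spec.n_frames))
        dur_frames = max(1, int(round(rng.exponential(spec.duration_mean) / spec.frame_interval)))
        end = min(spec.n_frames - 1, start + dur_frames - 1)
        if taken[start : end + 2].any() or (start > 0 and taken[start - 1]):
            continue
        taken[start : end + 2] = True
        if start > 0:
            taken[start - 1] = True
        censored = start == 0 or end == spec.n_frames - 1
        events.append(Event(start, end, censored))
    return sorted(events, key=lambda e: e.start_frame)


def _enforce_quiet_frames(events: list[Event], n_frames: int, window: int = 100) -> list[Event]:
    """Keep >= 1 baseline frame in every normalization window.

    Windowed-minimum normalization needs at least one quiet frame per
    window; if planted events fully cover a window, events in that window
    are dropped longest-first until a quiet frame exists.
    """
    events = list(events)
    changed = True
    while changed:
        changed = False
        covered = np.zeros(n_frames, dtype=bool)
        for ev in events:
            covered[ev.start_frame : ev.end_frame + 1] = True
        for w0 in range(0, n_frames, window):
            w1 = min(w0 + window, n_frames)
            if covered[w0:w1].all():
                in_win = [e for e in events if e.start_frame < w1 and e.end_frame >= w0]
                in_win.sort(key=lambda e: e.n_frames(), reverse=True)
                events.remove(in_win[0])
                changed = True
                break
    return events


def generate_recording(spec: RecordingSpec):
    """Synthesize a timelapse movie, nuclear label mask and ground truth.

    Returns ``(movie, labels, truth)``: ``movie`` is float32
    (n_frames, H, W) on the 0-255 scale, ``labels`` a uint16 mask with one
    disjoint elliptical ROI per cell, ``truth`` a :class:`GroundTruth` with
    all planted events, the active and persistent cell sets, and the exact
    noise-free per-cell traces.  Identical seeds reproduce identical output
    bit for bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    labels = _place_ellipses(spec.image_shape, spec.n_cells, rng)

    cell_ids = list(range(1, spec.n_cells + 1))
    n_active = int(round(spec.n_cells * spec.active_fraction))
    active = list(rng.choice(cell_ids, size=n_active, replace=False)) if n_active else []
    n_pers = int(round(n_active * spec.persistent_fraction))
    persistent = set(int(c) for c in active[:n_pers])
    ordinary = [int(c) for c in active[n_pers:]]

    decay = (1.0 - spec.bleach_rate) ** np.arange(spec.n_frames)
    base = spec.baseline_mfi * decay

    roi_traces = np.tile(base, (spec.n_cells, 1))
    events_by_cell: dict[int, list[Event]] = {}
    for cid in ordinary:
        evs = _enforce_quiet_frames(_plant_cell_events(rng, spec), spec.n_frames)
        if evs:
            events_by_cell[cid] = evs
        for ev in evs:
            roi_traces[cid - 1, ev.start_frame : ev.end_frame + 1] = (
                spec.event_amplitude * base[ev.start_frame : ev.end_frame + 1]
            )
    for cid in persistent:
        roi_traces[cid - 1, :] = spec.persistent_mfi

    movie = np.tile(base[:, None, None], (1,) + spec.image_shape).astype(np.float32)
    flat_idx = {cid: np.flatnonzero(labels.ravel() == cid) for cid in cell_ids}
    movie_flat = movie.reshape(spec.n_frames, -1)
    for cid in cell_ids:
        movie_flat[:, flat_idx[cid]] = roi_traces[cid - 1][:, None]
    if spec.noise_sd > 0:
        movie += rng.normal(0.0, spec.noise_sd, movie.shape).astype(np.float32)
    np.clip(movie, 0.0, 255.0, out=movie)

    rows = [
        (cid, ev.start_frame, ev.end_frame, ev.censored)
        for cid in sorted(events_by_cell)
        for ev in events_by_cell[cid]
    ]
    truth = GroundTruth(
        events=pd.DataFrame(
            rows, columns=["cell_id", "start_frame", "end_frame", "censored"]
        ),
        active_cells=set(int(c) for c in active),
        persistent_cells=persistent,
        roi_traces=roi_traces,
    )
    return movie, labels, truth


def generate_linescan(spec: LineScanSpec):
    """Synthesize a red (dextran) profile with transit valleys and a green profile.

    Cells passing the scan line appear as smooth intensity dips of exact
    support ``valley_width``; each block carries exactly its planted count of
    non-overlapping valleys (centers separated by >= 2x valley width).
    The green profile is constant within each block.  Returns
    ``(red, green, truth)`` with per-block counts and centers in ``truth``.
    """
    counts = spec.counts_per_block()
    n = spec.n_blocks * spec.block_width
    rng = np.random.default_rng(spec.rng_seed)
    red = np.full(n, spec.baseline, dtype=float)
    sep = spec.min_separation if spec.min_separation is not None else 2 * spec.valley_width
    half = spec.valley_width / 2.0
    centers_per_block: list[list[int]] = []
    for b, count in enumerate(counts):
        lo = b * spec.block_width + spec.valley_width
        hi = (b + 1) * spec.block_width - spec.valley_width
        if count * sep > spec.block_width - 2 * spec.valley_width:
            raise ValueError(f"block {b}: {count} valleys of width {spec.valley_width} overcrowd the block")
        centers: list[int] = []
        while len(centers) < count:
            c = int(rng.integers(lo, hi))
            if all(abs(c - c0) >= sep for c0 in centers):
                centers.append(c)
        centers.sort()
        centers_per_block.append(centers)
        for c in centers:
            x = np.arange(int(np.ceil(c - half)), int(np.floor(c + half)) + 1)
            x = x[(x >= 0) & (x < n)]
            red[x] -= spec.valley_depth * 0.5 * (1 + np.cos(2 * np.pi * (x - c) / spec.valley_width))
    if spec.noise_sd > 0:
        red += rng.normal(0.0, spec.noise_sd, n)

    green = np.full(n, spec.green_baseline, dtype=float)
    for b in spec.green_event_blocks:
        green[b * spec.block_width : (b + 1) * spec.block_width] = spec.green_event_level

    truth = GroundTruth(
        transits=[int(c) for c in counts],
        valley_centers=centers_per_block,
        green_event_blocks=set(spec.green_event_blocks),
    )
    return red, green, truth


def generate_vessel_geometry(
    n_loops: int,
    pixel_size_um: float = 1.0,
    nuclei_per_segment: tuple[int, ...] = (2, 2, 1),
    rng_seed: int = 0,
    hole_size_range: tuple[int, int] = (6, 14),
    ring_thickness: int = 3,
    far_nuclei_um: tuple[float, ...] = (),
):
    """Synthesize a vessel mask with enclosed loops and a skeleton with nuclei.

    The mask tiles rectangular annuli (one fully enclosed hole each) on a
    grid.  The skeleton is a star of 1-px-wide straight segments (axis
    aligned and diagonal) radiating from one branch point; nuclei are
    planted exactly on segment pixels (snap distance 0), plus optional
    off-skeleton nuclei at the stated perpendicular distances for testing
    the <10 um retention rule.  Returns ``(mask, skeleton, nuclei, truth)``
    with nuclei as an (n, 2) array of (row, col) centroids.
    """
    rng = np.random.default_rng(rng_seed)
    per_row = max(1, int(np.ceil(np.sqrt(n_loops)))) if n_loops else 1
    hole_hi = hole_size_range[1]
    cell_px = hole_hi + 2 * ring_thickness + 4
    side = max(per_row * cell_px + 4, 64)
    mask = np.zeros((side, side), dtype=bool)
    loops = []
    for i in range(n_loops):
        r0 = 2 + (i // per_row) * cell_px
        c0 = 2 + (i % per_row) * cell_px
        h = int(rng.integers(hole_size_range[0], hole_hi + 1))
        w = int(rng.integers(hole_size_range[0], hole_hi + 1))
        t = ring_thickness
        mask[r0 : r0 + h + 2 * t, c0 : c0 + w + 2 * t] = True
        mask[r0 + t : r0 + t + h, c0 + t : c0 + t + w] = False
        loops.append(
            {
                "area_px": h * w,
                "centroid": (r0 + t + (h - 1) / 2.0, c0 + t + (w - 1) / 2.0),
                "bbox": (r0 + t, c0 + t, h, w),
            }
        )

    # skeleton: disjoint 1-px segments (alternating horizontal/diagonal) in
    # separate row bands, so each connected component is one planted segment
    n_seg = len(nuclei_per_segment)
    far_margin = int(np.ceil(max(far_nuclei_um, default=0.0) / pixel_size_um)) + 6
    band = max(16, far_margin + 4)
    height = max(side, far_margin + n_seg * band + 4)
    skeleton = np.zeros((height, side), dtype=bool)
    segments = []
    nuclei: list[tuple[float, float]] = []
    nuclei_true_segment: dict[int, int] = {}
    nuclei_distances: dict[int, float] = {}
    for s in range(n_seg):
        r0 = far_margin + s * band
        c0 = 4
        diagonal = s % 2 == 1
        if diagonal:
            seg_len = min(band - 6, side - 10)
            path = [(r0 + k, c0 + k) for k in range(seg_len + 1)]
        else:
            seg_len = side - 10
            path = [(r0, c0 + k) for k in range(seg_len + 1)]
        for r, c in path:
            skeleton[r, c] = True
        step = (np.sqrt(2.0) if diagonal else 1.0) * pixel_size_um
        segments.append({"path": path, "length_um": seg_len * step})
        n_nuc = nuclei_per_segment[s]
        offsets = np.linspace(2, seg_len - 2, max(n_nuc, 1)).astype(int)
        for k in offsets[:n_nuc]:
            nid = len(nuclei)
            nuclei.append((float(path[k][0]), float(path[k][1])))
            nuclei_true_segment[nid] = s
            nuclei_distances[nid] = 0.0
    for d_um in far_nuclei_um:
        # perpendicular offset above the first (horizontal) segment; nothing
        # lies above it, so the planted distance is exact
        nid = len(nuclei)
        nuclei.append(
            (float(far_margin - d_um / pixel_size_um), float(4 + (side - 10) // 2))
        )
        nuclei_distances[nid] = float(d_um)

    truth = GroundTruth(
        loops=loops,
        segments=segments,
        nuclei_true_segment=nuclei_true_segment,
        nuclei_distances_um=nuclei_distances,
    )
    return mask, skeleton, np.array(nuclei, dtype=float).reshape(-1, 2), truth


def generate_revisit_pair(
    n_cells: int,
    p_active_day0: float,
    p_maintain: float,
    rng_seed: int = 0,
    independent: bool = False,
) -> pd.DataFrame:
    """Paired activity-status table for a revisit of the same cells.

    Day-0 status is Bernoulli(``p_active_day0``) per cell.  By default each
    cell keeps its status on the revisit day with probability
    ``p_maintain`` (and flips otherwise); with ``independent=True`` the
    revisit status is drawn afresh from Bernoulli(``p_active_day0``), the
    random-activity null.
    """
    if not (0.0 <= p_active_day0 <= 1.0 and 0.0 <= p_maintain <= 1.0):
        raise ValueError("proportions must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    day0 = rng.random(n_cells) < p_active_day0
    if independent:
        dayn = rng.random(n_cells) < p_active_day0
    else:
        keep = rng.random(n_cells) < p_maintain
        dayn = np.where(keep, day0, ~day0)
    status = np.array(["inactive", "active"])
    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "status_day0": status[day0.astype(int)],
            "status_dayN": status[dayn.astype(int)],
        }
    )
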