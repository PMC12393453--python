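"""Vessel-network morphometry and permeability.

Fully enclosed vascular loops are the connected components of the vessel
mask's complement that do not touch the image border; each is measured
(area, perimeter, centroid, equivalent diameter).  Linear endothelial cell
density is computed per skeleton segment: nuclei centroids are snapped to
the nearest skeleton pixel and retained only when the snap distance is
under 10 microns; segments run between branch points and endpoints and are
measured by geodesic length (unit steps and sqrt(2) diagonal steps).
Permeability is the extravascular mean fluorescence per frame after dextran
injection, normalized to the pre-dextran extravascular mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .traces import Recording

__all__ = [
    "Loop",
    "SkeletonSegment",
    "PermeabilitySeries",
    "detect_loops",
    "snap_nuclei",
    "segment_density",
    "extravascular_permeability",
]


@dataclass
class Loop:
    loop_id: int
    area_px: float
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    centroid: tuple[float, float]
    equivalent_diameter_px: float
    equivalent_diameter_um: float


@dataclass
class SkeletonSegment:
    segment_id: int
    path: list[tuple[int, int]]      # ordered (row, col) pixels, endpoints inclusive
    geodesic_length_um: float
    n_nuclei: int = 0
    linear_density_per_100um: float = 0.0   # cells per 100 um
    linear_density_per_um: float = 0.0


@dataclass
class PermeabilitySeries:
    normalized: np.ndarray           # per-frame extravascular MFI / pre-dextran mean
    times_min: np.ndarray            # frame timestamps, minutes post-injection
    pre_dextran_mean: float
    reported: dict                   # time (min) -> normalized value at nearest frame


def _boundary_trace_perimeter(region: np.ndarray) -> float:
    """Perimeter of a single connected region by Moore boundary tracing.

    The 8-connected boundary contour is walked pixel to pixel; axis steps
    count 1 and diagonal steps sqrt(2).  Single-pixel regions have
    perimeter 0 under this estimator (degenerate contour).
    """
    pts = np.argwhere(region)
    if len(pts) == 1:
        return 0.0
    padded = np.pad(region, 1)
    # Moore neighborhood in clockwise order starting from W
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    start = tuple(np.argwhere(padded)[0])  # row-major: top-left-most pixel
    # backtrack: the pixel visited before start; for the top-left-most pixel, W
    boundary = [start]
    prev_dir = 0  # index into nbrs of the backtrack direction (W)
    cur = start
    while True:
        found = False
        for k in range(8):
            d = (prev_dir + 1 + k) % 8
            dr, dc = nbrs[d]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                boundary.append(cand)
                # new backtrack points from cand to cur
                prev_dir = (d + 4) % 8
                cur = cand
                found = True
                break
        if not found:  # isolated pixel (handled above) — safety
            return 0.0
        if cur == start and len(boundary) > 1:
            break
    length = 0.0
    for (r0, c0), (r1, c1) in zip(boundary[:-1], boundary[1:]):
        length += np.sqrt(2.0) if (r0 != r1 and c0 != c1) else 1.0
    return float(length)


def detect_loops(
    vessel_mask: np.ndarray,
    pixel_size_um: float = 1.0,
    min_area_px: int = 4,
) -> list[Loop]:
    """Fully enclosed holes of a binary vessel mask, measured per loop.

    Holes are connected components (8-connectivity) of the mask complement
    that do not touch the image border; components smaller than
    ``min_area_px`` are dropped.  Equivalent diameter = sqrt(4 * area / pi).
    """
    vessel_mask = np.asarray(vessel_mask).astype(bool)
    holes = measure.label(~vessel_mask, connectivity=2)
    border = np.unique(
        np.concatenate([holes[0], holes[-1], holes[:, 0], holes[:, -1]])
    )
    loops = []
    loop_id = 0
    for region in measure.regionprops(holes):
        if region.label in border or region.area < min_area_px:
            continue
        area = float(region.area)
        hole = holes == region.label
        perim = _boundary_trace_perimeter(hole)
        eq_d = float(np.sqrt(4.0 * area / np.pi))
        loops.append(
            Loop(
                loop_id=loop_id,
                area_px=area,
                area_um2=area * pixel_size_um**2,
                perimeter_px=perim,
                perimeter_um=perim * pixel_size_um,
                centroid=tuple(map(float, region.centroid)),
                equivalent_diameter_px=eq_d,
                equivalent_diameter_um=eq_d * pixel_size_um,
            )
        )
        loop_id += 1
    return loops


def snap_nuclei(
    nuclei: np.ndarray,
    skeleton: np.ndarray,
    pixel_size_um: float = 1.0,
    max_snap_um: float = 10.0,
) -> tuple[dict, list]:
    """Snap nuclear centroids to the nearest skeleton pixel.

    Returns ``(assignments, exclusions)``: assignments maps nucleus index ->
    (skeleton pixel (row, col), distance in um) for nuclei within the snap
    radius (strictly under 10 um by default); exclusions lists
    (nucleus index, distance) for the rest.  Ties in distance resolve to the
    lexicographically smallest (row, col) skeleton pixel.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    sk_pts = np.argwhere(skeleton)
    if sk_pts.size == 0:
        raise ValueError("empty skeleton")
    # lexicographic order makes argmin deterministic under distance ties
    sk_pts = sk_pts[np.lexsort((sk_pts[:, 1], sk_pts[:, 0]))]
    nuclei = np.asarray(nuclei, dtype=float).reshape(-1, 2)
    assignments: dict[int, tuple[tuple[int, int], float]] = {}
    exclusions: list[tuple[int, float]] = []
    for i, (y, x) in enumerate(nuclei):
        d2 = (sk_pts[:, 0] - y) ** 2 + (sk_pts[:, 1] - x) ** 2
        j = int(np.argmin(d2))
        dist_um = float(np.sqrt(d2[j]) * pixel_size_um)
        if dist_um < max_snap_um:
            assignments[i] = (tuple(int(v) for v in sk_pts[j]), dist_um)
        else:
            exclusions.append((i, dist_um))
    return assignments, exclusions


def _skeleton_graph(skeleton: np.ndarray):
    """Neighbor map and degree for every skeleton pixel (8-connectivity)."""
    pts = [tuple(p) for p in np.argwhere(skeleton)]
    pset = set(pts)
    nbrs = {}
    for r, c in pts:
        nbrs[(r, c)] = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0) and (r + dr, c + dc) in pset
        ]
    return pts, nbrs


def segment_density(
    skeleton: np.ndarray,
    assignments: dict,
    pixel_size_um: float = 1.0,
) -> list[SkeletonSegment]:
    """Skeleton segments with geodesic length and linear EC density.

    Nodes are skeleton pixels with exactly 1 (endpoints) or more than 2
    (branch points) 8-connected skeleton neighbors; segments are the maximal
    paths between nodes through degree-2 pixels.  Geodesic length sums the
    step lengths (1 or sqrt(2), times pixel size) along the path.  Snapped
    nuclei count toward the segment containing their skeleton pixel; a
    nucleus snapped to a branch-point pixel counts toward the
    lexicographically first incident segment.  Density = 100 * n / length,
    in cells per 100 um.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    pts, nbrs = _skeleton_graph(skeleton)
    degree = {p: len(nbrs[p]) for p in pts}
    node_px = {p for p in pts if degree[p] != 2}
    # connected grouping: adjacent node pixels collapse into one junction node
    cluster_of: dict[tuple[int, int], int] = {}
    for p in sorted(node_px):
        if p in cluster_of:
            continue
        cid = len(set(cluster_of.values()))
        stack = [p]
        while stack:
            q = stack.pop()
            if q in cluster_of:
                continue
            cluster_of[q] = cid
            stack.extend(r for r in nbrs[q] if r in node_px and r not in cluster_of)

    def step(a, b):
        return (np.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0) * pixel_size_um

    segments: list[SkeletonSegment] = []
    visited_edges = set()

    def walk(start, first):
        """Follow the path from node pixel ``start`` through ``first`` until a node pixel."""
        path = [start, first]
        prev, cur = start, first
        while cur not in node_px:
            nxt = [q for q in nbrs[cur] if q != prev]
            if not nxt:
                break  # dead end (shouldn't happen on a clean skeleton)
            prev, cur = cur, nxt[0]
            path.append(cur)
        return path

    for node in sorted(node_px):
        for first in sorted(nbrs[node]):
            if first in node_px and cluster_of[first] == cluster_of[node]:
                continue  # internal junction edge, not a segment
            edge = frozenset((node, first))
            if edge in visited_edges:
                continue
            path = walk(node, first)
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add(frozenset((a, b)))
            length = sum(step(a, b) for a, b in zip(path[:-1], path[1:]))
            segments.append(
                SkeletonSegment(
                    segment_id=len(segments),
                    path=path,
                    geodesic_length_um=float(length),
                )
            )
    # isolated cycles (no node pixels) — trace each as one closed segment
    covered = {p for s in segments for p in s.path}
    for p in sorted(set(pts) - covered - node_px):
        if p in covered or degree[p] != 2:
            continue
        path = [p]
        prev, cur = p, sorted(nbrs[p])[0]
        while cur != p:
            path.append(cur)
            nxt = [q for q in nbrs[cur] if q != prev]
            prev, cur = cur, nxt[0]
        path.append(p)
        covered.update(path)
        length = sum(step(a, b) for a, b in zip(path[:-1], path[1:]))
        segments.append(SkeletonSegment(len(segments), path, float(length)))

    pixel_to_segment: dict[tuple[int, int], int] = {}
    for seg in segments:  # first (lexicographically walked) segment wins at nodes
        for p in seg.path:
            pixel_to_segment.setdefault(p, seg.segment_id)
    counts = {s.segment_id: 0 for s in segments}
    for _, (px, _dist) in sorted(assignments.items()):
        sid = pixel_to_segment.get(tuple(px))
        if sid is not None:
            counts[sid] += 1
    out = []
    for seg in segments:
        if seg.geodesic_length_um <= 0:
            continue
        n = counts[seg.segment_id]
        out.append(
            SkeletonSegment(
                segment_id=seg.segment_id,
                path=seg.path,
                geodesic_length_um=seg.geodesic_length_um,
                n_nuclei=n,
                linear_density_per_100um=100.0 * n / seg.geodesic_length_um,
                linear_density_per_um=n / seg.geodesic_length_um,
            )
        )
    return out


def extravascular_permeability(
    movie: Recording,
    vessel_mask: np.ndarray,
    pre_dextran_movie: Recording,
    report_times_min=(0.0, 0.5, 1.0, 2.0, 5.0),
    dilation_px: int = 2,
) -> PermeabilitySeries:
    """Normalized extravascular dextran intensity over time.

    The extravascular region is the complement of the vessel mask dilated by
    ``dilation_px`` (0 disables the margin; the margin guards against
    partial-volume bleed at vessel edges).  Each post-injection frame's
    extravascular mean is divided by the pre-dextran recording's average
    extravascular mean; values are also reported at the requested minutes
    (nearest frame).
    """
    vessel_mask = np.asarray(vessel_mask).astype(bool)
    if dilation_px > 0:
        vessel_mask = morphology.dilation(vessel_mask, morphology.disk(dilation_px))
    outside = ~vessel_mask
    if not outside.any():
        raise ValueError("no extravascular pixels after dilation")
    pre_mean = float(pre_dextran_movie.frames[:, outside].mean())
    if pre_mean <= 0:
        raise ValueError("pre-dextran extravascular mean must be positive")
    series = movie.frames[:, outside].mean(axis=1) / pre_mean
    times = np.arange(movie.n_frames) * movie.frame_interval / 60.0
    reported = {}
    for t in report_times_min:
        idx = int(np.argmin(np.abs(times - t)))
        reported[float(t)] = float(series[idx])
    return PermeabilitySeries(
        normalized=series,
        times_min=times,
        pre_dextran_mean=pre_mean,
        reported=reported,
    )
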