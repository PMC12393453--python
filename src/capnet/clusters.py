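"""Multicellular Ca2+ cluster detection on the vessel-surface grid.

Grid ROIs carrying Ca2+ events are linked into clusters when they are
spatially adjacent (8-connectivity over grid rows/cols by default, since
vessels run diagonally across the tiling; a 4-connectivity toggle is
provided) and active at the same frame or one frame apart.  Clusters are
the connected components of that spatiotemporal relation; the endothelial
cells involved are counted by assigning nuclear centroids to the member
grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import call_events
from .traces import GridGeometry

__all__ = [
    "GridRaster",
    "Cluster",
    "call_grid_events",
    "link_clusters",
    "count_cluster_cells",
    "cluster_size_distribution",
    "persistent_clusters",
]


@dataclass
class GridRaster:
    """Binary activity matrix (grid x time) plus the grid geometry."""

    activity: np.ndarray                      # bool, shape (n_grids, n_frames)
    geometry: list[GridGeometry]

    def __post_init__(self):
        self.activity = np.asarray(self.activity).astype(bool)
        if self.activity.shape[0] != len(self.geometry):
            raise ValueError("raster rows must match geometry entries")


@dataclass
class Cluster:
    members: frozenset            # of (grid_id, frame)
    grids: frozenset              # distinct grid ids
    frame_span: tuple[int, int]
    n_cells: int | None = None
    persistent: bool = False

    @property
    def n_grids(self) -> int:
        return len(self.grids)


def call_grid_events(
    grid_traces: pd.DataFrame,
    geometry: list[GridGeometry],
    window: int = 100,
    threshold_ratio: float = 0.5,
) -> GridRaster:
    """Threshold every grid trace with the same semantics as the per-cell detector."""
    n_frames = len(grid_traces)
    activity = np.zeros((len(geometry), n_frames), dtype=bool)
    for g in range(len(geometry)):
        for ev in call_events(grid_traces[g].to_numpy(), window, threshold_ratio):
            activity[g, ev.start_frame : ev.end_frame + 1] = True
    return GridRaster(activity, geometry)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int]]:
    if connectivity == 4:
        return [(0, 1), (1, 0), (0, -1), (-1, 0)]
    if connectivity == 8:
        return [
            (0, 1), (1, 0), (0, -1), (-1, 0),
            (1, 1), (1, -1), (-1, 1), (-1, -1),
        ]
    raise ValueError("connectivity must be 4 or 8")


def link_clusters(
    raster: GridRaster,
    connectivity: int = 8,
    temporal_tolerance: int = 1,
) -> list[Cluster]:
    """Connected components of co-active grid entries.

    Nodes are the active (grid, frame) entries; two nodes are linked iff
    their grids are identical or spatially adjacent and their frames differ
    by at most ``temporal_tolerance`` (one frame, by the same-frame-or-one-
    frame-apart rule).  Every active entry belongs to exactly one cluster.
    """
    offsets = _neighbor_offsets(connectivity)
    grid_at = {(g.row, g.col): g.grid_id for g in raster.geometry}
    entries = [
        (int(g), int(t)) for g, t in zip(*np.nonzero(raster.activity))
    ]
    index = {e: i for i, e in enumerate(entries)}
    uf = _UnionFind(len(entries))
    n_frames = raster.activity.shape[1]
    for (g, t), i in index.items():
        geo = raster.geometry[g]
        neighbor_gids = [g] + [
            grid_at[(geo.row + dr, geo.col + dc)]
            for dr, dc in offsets
            if (geo.row + dr, geo.col + dc) in grid_at
        ]
        for dt in range(0, temporal_tolerance + 1):
            if t + dt >= n_frames:
                continue
            for ng in neighbor_gids:
                j = index.get((ng, t + dt))
                if j is not None and j != i:
                    uf.union(i, j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for e, i in index.items():
        groups.setdefault(uf.find(i), []).append(e)
    clusters = []
    for members in groups.values():
        grids = frozenset(g for g, _ in members)
        frames = [t for _, t in members]
        clusters.append(
            Cluster(
                members=frozenset(members),
                grids=grids,
                frame_span=(min(frames), max(frames)),
            )
        )
    clusters.sort(key=lambda c: (c.frame_span[0], min(c.grids)))
    return clusters


def _grid_of_point(y: float, x: float, geometry: list[GridGeometry]) -> int | None:
    """Grid containing a point under half-open bounds [y0, y1) x [x0, x1)."""
    for g in geometry:
        if g.y_bounds[0] <= y < g.y_bounds[1] and g.x_bounds[0] <= x < g.x_bounds[1]:
            return g.grid_id
    return None


def count_cluster_cells(
    cluster: Cluster,
    nuclei: np.ndarray,
    geometry: list[GridGeometry],
) -> int:
    """Distinct nuclei whose centroid falls inside the cluster's member grids.

    ``nuclei`` is an (n, 2) array of (y, x) centroids in pixel coordinates.
    Half-open grid bounds guarantee a centroid on a shared grid edge is
    assigned to exactly one grid and counted once.
    """
    nuclei = np.asarray(nuclei, dtype=float).reshape(-1, 2)
    count = 0
    for y, x in nuclei:
        gid = _grid_of_point(y, x, geometry)
        if gid is not None and gid in cluster.grids:
            count += 1
    return count


def annotate_cells(
    clusters: list[Cluster], nuclei: np.ndarray, geometry: list[GridGeometry]
) -> list[Cluster]:
    """Fill ``n_cells`` on every cluster (returns new Cluster objects)."""
    return [
        Cluster(c.members, c.grids, c.frame_span,
                n_cells=count_cluster_cells(c, nuclei, geometry),
                persistent=c.persistent)
        for c in clusters
    ]


def cluster_size_distribution(sizes) -> dict:
    """Proportion of clusters by participating-cell count: {1}, {2-4}, {>=5}.

    Returns the binned proportions plus the raw size histogram.  Proportions
    sum to 1 for any nonempty input.
    """
    sizes = [int(s) for s in sizes]
    n = len(sizes)
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    bins = {
        "1": sum(1 for s in sizes if s == 1) / n if n else np.nan,
        "2-4": sum(1 for s in sizes if 2 <= s <= 4) / n if n else np.nan,
        ">=5": sum(1 for s in sizes if s >= 5) / n if n else np.nan,
    }
    return {"proportions": bins, "histogram": dict(sorted(hist.items())), "n_clusters": n}


def persistent_clusters(
    raster: GridRaster,
    full_span_fraction: float = 1.0,
    connectivity: int = 8,
) -> list[Cluster]:
    """Clusters simultaneously active for (a fraction of) the whole recording.

    A cluster is persistent iff at least one member grid is active in
    >= ``full_span_fraction`` of all frames (1.0: every frame).
    """
    n_frames = raster.activity.shape[1]
    frac = raster.activity.sum(axis=1) / n_frames
    persistent_grids = set(np.flatnonzero(frac >= full_span_fraction).tolist())
    out = []
    for c in link_clusters(raster, connectivity=connectivity):
        if c.grids & persistent_grids:
            out.append(Cluster(c.members, c.grids, c.frame_span,
                               n_cells=c.n_cells, persistent=True))
    return out
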