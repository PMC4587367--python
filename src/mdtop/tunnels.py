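"""Simplified grid-based tunnel detection and pathway statistics.

A regular grid covers the structure's bounding box plus a margin.  Each node
carries a *free radius*: the distance to the nearest atom centre minus that
atom's vdW radius (clipped at zero).  Nodes with free radius at or above the
probe radius are *admissible*; admissible nodes outside the convex hull of the
atom centres are *exits*.  A tunnel is the cheapest admissible path (directed
Dijkstra over 26-connected grid edges, where exit nodes absorb — a path ends
at its first node outside the molecular hull) from the start node to any exit,
with cost ``Σ edge_length / free_radius^exponent`` so long or narrow paths are
expensive.  Throughput is ``exp(-cost)`` in (0, 1].

Tunnels found across frames are grouped into *pathways* by average-linkage
clustering of resampled path polylines; pathways are ranked by the average
throughput of the cheapest member tunnel per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import squareform

from .errors import BlockedStartError, UsageError
from .topology import ToyTopology

__all__ = [
    "TunnelSearchConfig",
    "Tunnel",
    "Pathway",
    "FreeRadiusGrid",
    "free_radius_field",
    "find_tunnels",
    "find_cheapest_tunnel",
    "cluster_tunnels",
    "pathway_statistics",
    "bottleneck_residues",
]

# 26-connectivity offsets
_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass(frozen=True)
class TunnelSearchConfig:
    """Probe 0.7 Å suits proximal-side searches, 1.3 Å distal-side ones."""

    probe_radius: float = 0.7
    grid_spacing: float = 0.5
    start: object = None  # atom index, or explicit (3,) point
    cost_exponent: float = 2.0
    margin: float = 3.0  # grid extension beyond the bounding box, Å
    min_exit_separation: float = 5.0  # Å between distinct tunnel exits
    max_tunnels: int = 8

    def __post_init__(self):
        if self.probe_radius <= 0 or self.grid_spacing <= 0:
            raise UsageError("probe radius and grid spacing must be positive")


@dataclass(eq=False)
class Tunnel:
    frame: int
    path: np.ndarray  # (P, 3) Å
    radii: np.ndarray  # (P,) free radius profile Å
    length: float  # polyline arc length Å
    bottleneck: float  # min of profile Å
    cost: float
    throughput: float  # exp(-cost)


@dataclass(eq=False)
class Pathway:
    tunnels: list[Tunnel]
    frames: np.ndarray  # frame ids in which the pathway exists
    mean_bottleneck: float
    mean_length: float
    mean_throughput: float


@dataclass(eq=False)
class FreeRadiusGrid:
    origin: np.ndarray  # (3,)
    shape: tuple[int, int, int]
    spacing: float
    free: np.ndarray  # (nx, ny, nz)

    def node_coords(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=float) * self.spacing

    def nearest_node(self, point: np.ndarray) -> tuple[int, int, int]:
        ijk = np.round((np.asarray(point, float) - self.origin) / self.spacing)
        ijk = np.clip(ijk, 0, np.array(self.shape) - 1).astype(int)
        return tuple(ijk)


def free_radius_field(
    coords: np.ndarray,
    radii: np.ndarray,
    config: TunnelSearchConfig = TunnelSearchConfig(),
) -> FreeRadiusGrid:
    """Per-node free radius: distance to the nearest atom centre minus that
    atom's vdW radius, clipped at zero (nodes inside atoms read 0)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise UsageError("empty structure")
    lo = coords.min(axis=0) - config.margin
    hi = coords.max(axis=0) + config.margin
    shape = tuple(int(np.floor((h - l) / config.grid_spacing)) + 1 for l, h in zip(lo, hi))
    axes = [lo[d] + np.arange(shape[d]) * config.grid_spacing for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    tree = cKDTree(coords)
    dist, idx = tree.query(nodes, workers=-1)
    free = np.clip(dist - radii[idx], 0.0, None).reshape(shape)
    return FreeRadiusGrid(origin=lo, shape=shape, spacing=config.grid_spacing, free=free)


def _outside_hull_mask(grid: FreeRadiusGrid, coords: np.ndarray) -> np.ndarray:
    """Boolean (flat) mask of grid nodes outside the convex hull of atoms.

    Falls back to the axis-aligned bounding box when the point set is too
    degenerate for a Delaunay triangulation.
    """
    shape = grid.shape
    axes = [grid.origin[d] + np.arange(shape[d]) * grid.spacing for d in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    try:
        tri = Delaunay(coords)
        return tri.find_simplex(nodes) < 0
    except (QhullError, ValueError):
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        inside = np.all((nodes >= lo) & (nodes <= hi), axis=1)
        return ~inside


def _resolve_start_point(config, coords, topology) -> np.ndarray:
    start = config.start
    if start is None:
        if topology is None or topology.start_atom is None:
            raise UsageError("no start point specified")
        return coords[topology.start_atom]
    if np.isscalar(start):
        return coords[int(start)]
    return np.asarray(start, dtype=float)


def find_tunnels(
    coords: np.ndarray,
    topology: ToyTopology | None = None,
    config: TunnelSearchConfig = TunnelSearchConfig(),
    radii: np.ndarray | None = None,
    frame: int = 0,
) -> list[Tunnel]:
    """All distinct tunnels from the start point to the surface in one frame.

    Exits are accepted cheapest-first and must be mutually separated by at
    least ``min_exit_separation``, giving at most one tunnel per exit region.
    Returns an empty list when no admissible path exists; raises
    :class:`BlockedStartError` when the start node itself is inadmissible.
    """
    coords = np.asarray(coords, dtype=float)
    if radii is None:
        if topology is None:
            raise UsageError("need vdW radii or a topology")
        radii = topology.vdw_radii
    grid = free_radius_field(coords, radii, config)
    free_flat = grid.free.ravel()
    admissible = free_flat >= config.probe_radius
    outside = _outside_hull_mask(grid, coords)
    exits_mask = admissible & outside

    start_point = _resolve_start_point(config, coords, topology)
    start_ijk = grid.nearest_node(start_point)
    start_flat = int(np.ravel_multi_index(start_ijk, grid.shape))
    if not admissible[start_flat]:
        raise BlockedStartError(
            f"start node free radius {free_flat[start_flat]:.2f} Å below probe "
            f"{config.probe_radius:.2f} Å"
        )
    if exits_mask[start_flat]:
        r = float(free_flat[start_flat])
        pt = grid.node_coords(np.array(start_ijk))[None]
        return [
            Tunnel(
                frame=frame,
                path=pt,
                radii=np.array([r]),
                length=0.0,
                bottleneck=r,
                cost=0.0,
                throughput=1.0,
            )
        ]
    if not exits_mask.any():
        return []

    graph, node_ids = _build_graph(grid, admissible, outside, config)
    if start_flat not in node_ids:
        return []
    start_idx = node_ids[start_flat]
    dist, pred = dijkstra(
        graph, directed=True, indices=start_idx, return_predecessors=True
    )

    id_to_flat = np.empty(len(node_ids), dtype=np.int64)
    for flat, nid in node_ids.items():
        id_to_flat[nid] = flat
    exit_ids = np.flatnonzero(exits_mask[id_to_flat])
    reachable = exit_ids[np.isfinite(dist[exit_ids])]
    if reachable.size == 0:
        return []
    order = reachable[np.argsort(dist[reachable], kind="stable")]
    exit_coords = grid.node_coords(
        np.array(np.unravel_index(id_to_flat[order], grid.shape)).T
    )
    tunnels: list[Tunnel] = []
    accepted_pts: list[np.ndarray] = []
    for nid, pt in zip(order, exit_coords):
        if len(tunnels) >= config.max_tunnels:
            break
        if any(np.linalg.norm(pt - q) < config.min_exit_separation for q in accepted_pts):
            continue
        path_ids = _walk_predecessors(pred, start_idx, nid)
        path_flat = id_to_flat[path_ids]
        ijk = np.array(np.unravel_index(path_flat, grid.shape)).T
        path = grid.node_coords(ijk)
        radii_profile = free_flat[path_flat]
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        tunnels.append(
            Tunnel(
                frame=frame,
                path=path,
                radii=radii_profile,
                length=float(seg.sum()),
                bottleneck=float(radii_profile.min()),
                cost=float(dist[nid]),
                throughput=float(np.exp(-dist[nid])),
            )
        )
        accepted_pts.append(pt)
    return tunnels


def find_cheapest_tunnel(
    coords: np.ndarray,
    topology: ToyTopology | None = None,
    config: TunnelSearchConfig = TunnelSearchConfig(),
    radii: np.ndarray | None = None,
    frame: int = 0,
) -> Tunnel | None:
    """The single cheapest tunnel in a frame, or None when absent."""
    tunnels = find_tunnels(coords, topology, config, radii=radii, frame=frame)
    return tunnels[0] if tunnels else None


def _build_graph(grid, admissible, outside, config):
    """Directed sparse graph over admissible nodes.

    Edges leave only inside-hull nodes, so outside-hull (exit) nodes are
    absorbing and every shortest path terminates at its first exit.
    """
    shape = grid.shape
    flat_ids = np.flatnonzero(admissible)
    node_ids = {int(f): i for i, f in enumerate(flat_ids)}
    idmap = np.full(np.prod(shape), -1, dtype=np.int64)
    idmap[flat_ids] = np.arange(len(flat_ids))
    adm3 = admissible.reshape(shape)
    out3 = outside.reshape(shape)
    free3 = grid.free
    rows, cols, weights = [], [], []
    for off in _OFFSETS:
        src_slices, dst_slices = [], []
        for d in range(3):
            o = off[d]
            if o >= 0:
                src_slices.append(slice(0, shape[d] - o))
                dst_slices.append(slice(o, shape[d]))
            else:
                src_slices.append(slice(-o, shape[d]))
                dst_slices.append(slice(0, shape[d] + o))
        src_slices, dst_slices = tuple(src_slices), tuple(dst_slices)
        valid = adm3[src_slices] & adm3[dst_slices] & ~out3[src_slices]
        if not valid.any():
            continue
        src_idx3 = np.zeros(shape, dtype=bool)
        src_idx3[src_slices] = valid
        dst_idx3 = np.zeros(shape, dtype=bool)
        dst_idx3[dst_slices] = valid
        src_flat = np.flatnonzero(src_idx3.ravel())
        dst_flat = np.flatnonzero(dst_idx3.ravel())
        step = grid.spacing * float(np.linalg.norm(off))
        free_edge = np.minimum(
            free3[src_slices][valid], free3[dst_slices][valid]
        )
        rows.append(idmap[src_flat])
        cols.append(idmap[dst_flat])
        weights.append(step / free_edge**config.cost_exponent)
    n = len(flat_ids)
    if not rows:
        return csr_matrix((n, n)), node_ids
    graph = csr_matrix(
        (
            np.concatenate(weights),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(n, n),
    )
    return graph, node_ids


def _walk_predecessors(pred, start_idx, end_idx):
    path = [end_idx]
    node = end_idx
    while node != start_idx:
        node = pred[node]
        if node < 0:
            raise UsageError("broken predecessor chain")
        path.append(node)
    return np.array(path[::-1])


def _resample_path(path: np.ndarray, m: int = 20) -> np.ndarray:
    if len(path) == 1:
        return np.repeat(path, m, axis=0)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], m)
    return np.stack(
        [np.interp(target, s, path[:, d]) for d in range(3)], axis=1
    )


def cluster_tunnels(
    tunnels: list[Tunnel],
    linkage_cutoff: float = 3.0,
    resample_points: int = 20,
) -> list[Pathway]:
    """Group per-frame tunnels into pathways by average-linkage clustering.

    The tunnel-tunnel distance is the mean pointwise distance between paths
    resampled to ``resample_points`` equidistant points.  Pathways are ranked
    by decreasing average throughput (cheapest member tunnel per frame).
    """
    if not tunnels:
        raise UsageError("no tunnels to cluster")
    if len(tunnels) == 1:
        groups = [np.array([0])]
    else:
        pts = np.stack([_resample_path(t.path, resample_points) for t in tunnels])
        n = len(tunnels)
        D = np.zeros((n, n))
        for i in range(n - 1):
            d = np.linalg.norm(pts[i + 1 :] - pts[i][None], axis=2).mean(axis=1)
            D[i, i + 1 :] = d
        D = D + D.T
        flat = fcluster(
            linkage(squareform(D, checks=False), method="average"),
            t=linkage_cutoff,
            criterion="distance",
        )
        groups = [np.flatnonzero(flat == c) for c in np.unique(flat)]
    pathways = []
    for g in groups:
        members = [tunnels[i] for i in g]
        per_frame: dict[int, Tunnel] = {}
        for t in members:
            if t.frame not in per_frame or t.cost < per_frame[t.frame].cost:
                per_frame[t.frame] = t
        cheapest = list(per_frame.values())
        pathways.append(
            Pathway(
                tunnels=members,
                frames=np.array(sorted(per_frame)),
                mean_bottleneck=float(np.mean([t.bottleneck for t in cheapest])),
                mean_length=float(np.mean([t.length for t in cheapest])),
                mean_throughput=float(np.mean([t.throughput for t in cheapest])),
            )
        )
    pathways.sort(key=lambda p: -p.mean_throughput)
    return pathways


def pathway_statistics(
    pathways: list[Pathway], total_frames: int
) -> pd.DataFrame:
    """Summary table: frames present, mean bottleneck/length/throughput per
    pathway, sorted by decreasing mean throughput."""
    rows = [
        {
            "pathway": i + 1,
            "frames_present": len(p.frames),
            "total_frames": total_frames,
            "mean_bottleneck_A": p.mean_bottleneck,
            "mean_length_A": p.mean_length,
            "mean_throughput": p.mean_throughput,
        }
        for i, p in enumerate(
            sorted(pathways, key=lambda p: -p.mean_throughput)
        )
    ]
    return pd.DataFrame(rows)


def bottleneck_residues(
    tunnel: Tunnel,
    coords: np.ndarray,
    topology: ToyTopology,
    shell: float = 1.0,
) -> list[int]:
    """Residues whose vdW surface lies within ``shell`` of the bottleneck
    sphere surface."""
    coords = np.asarray(coords, dtype=float)
    b_idx = int(np.argmin(tunnel.radii))
    center = tunnel.path[b_idx]
    r_b = tunnel.radii[b_idx]
    gap = np.linalg.norm(coords - center, axis=1) - topology.vdw_radii - r_b
    hit = np.flatnonzero(gap <= shell)
    return sorted({int(topology.res_ids[i]) for i in hit})
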