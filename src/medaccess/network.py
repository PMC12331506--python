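"""Snapping of off-network points and road-network shortest distances.

Demand and supply points rarely sit exactly on a road centerline.  Each point
is projected onto its nearest road segment; the segment is split at the
projection so distances are measured along the network from the true access
location, and the perpendicular access offset is added to every distance so
off-network points get no free coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .synthetic_city import RoadNetwork

Point = tuple[float, float]


@dataclass
class SnapAssignment:
    """Where one point attaches to the network."""

    point: Point
    edge: tuple[int, int] | None  # original edge split (None if snapped to a node)
    node: object  # node id in the augmented graph
    offset_m: float  # perpendicular access distance
    offset_speed_kmh: float  # speed used to convert the offset to time
    unreachable: bool = False

    @property
    def offset_time_min(self) -> float:
        return self.offset_m / 1000.0 / self.offset_speed_kmh * 60.0


def _project_to_segments(
    pts: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For each point, the nearest segment index, the parameter t in [0,1]
    and the distance to the projection."""
    d = p1 - p0  # (E, 2)
    len2 = np.maximum((d**2).sum(axis=1), 1e-12)
    best_e = np.empty(len(pts), dtype=int)
    best_t = np.empty(len(pts))
    best_dist = np.empty(len(pts))
    # chunk over points to bound memory
    for start in range(0, len(pts), 256):
        chunk = pts[start : start + 256]  # (P, 2)
        t = ((chunk[:, None, :] - p0[None, :, :]) * d[None, :, :]).sum(axis=2) / len2[None, :]
        t = np.clip(t, 0.0, 1.0)
        proj = p0[None, :, :] + t[:, :, None] * d[None, :, :]
        dist = np.linalg.norm(chunk[:, None, :] - proj, axis=2)
        e = dist.argmin(axis=1)
        idx = np.arange(len(chunk))
        best_e[start : start + 256] = e
        best_t[start : start + 256] = t[idx, e]
        best_dist[start : start + 256] = dist[idx, e]
    return best_e, best_t, best_dist


def snap(
    points: Sequence[Point],
    network: RoadNetwork,
    tolerance_m: float = 500.0,
) -> tuple[nx.Graph, list[SnapAssignment]]:
    """Snap points to the road network, splitting edges at projections.

    Returns an augmented copy of the graph (original graph untouched) and one
    :class:`SnapAssignment` per input point.  Points farther than
    ``tolerance_m`` from every edge are flagged unreachable.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    edges = list(g.edges(data=True))
    pos = nx.get_node_attributes(g, "pos")
    p0 = np.array([pos[u] for u, v, _ in edges])
    p1 = np.array([pos[v] for u, v, _ in edges])
    pts = np.asarray([tuple(p) for p in points], dtype=float).reshape(-1, 2)

    aug = g.copy()
    assignments: list[SnapAssignment] = [None] * len(pts)  # type: ignore[list-item]
    if len(pts) == 0:
        return aug, assignments

    e_idx, t_par, dist = _project_to_segments(pts, p0, p1)

    # group snapped points by edge, then split each edge once
    by_edge: dict[int, list[tuple[float, int]]] = {}
    for i in range(len(pts)):
        if dist[i] > tolerance_m:
            assignments[i] = SnapAssignment(
                tuple(pts[i]), None, None, math.inf, 30.0, unreachable=True
            )
            continue
        u, v, data = edges[e_idx[i]]
        t = float(t_par[i])
        if t * data["length_m"] < 1e-9:
            assignments[i] = SnapAssignment(
                tuple(pts[i]), None, u, float(dist[i]), data["speed_kmh"]
            )
        elif (1.0 - t) * data["length_m"] < 1e-9:
            assignments[i] = SnapAssignment(
                tuple(pts[i]), None, v, float(dist[i]), data["speed_kmh"]
            )
        else:
            by_edge.setdefault(e_idx[i], []).append((t, i))

    for ei, items in by_edge.items():
        u, v, data = edges[ei]
        length, cls, speed = data["length_m"], data["road_class"], data["speed_kmh"]
        items.sort(key=lambda ti: ti[0])
        aug.remove_edge(u, v)
        # merge coincident projections into a single split node
        chain: list[tuple[float, object]] = [(0.0, u)]
        for t, i in items:
            prev_t, prev_node = chain[-1]
            if abs(t - prev_t) * length < 1e-9 and prev_node not in (u, v):
                node = prev_node
            else:
                node = ("snap", ei, len(chain))
                x = pos[u][0] + t * (pos[v][0] - pos[u][0])
                y = pos[u][1] + t * (pos[v][1] - pos[u][1])
                aug.add_node(node, pos=(x, y))
                chain.append((t, node))
            assignments[i] = SnapAssignment(tuple(pts[i]), (u, v), node, float(dist[i]), speed)
        chain.append((1.0, v))
        for (ta, na), (tb, nb) in zip(chain[:-1], chain[1:]):
            seg = (tb - ta) * length
            aug.add_edge(
                na, nb,
                length_m=seg,
                road_class=cls,
                speed_kmh=speed,
                time_min=seg / 1000.0 / speed * 60.0,
            )
    return aug, assignments


class NetworkDistanceIndex:
    """Network distances and travel times between sites and demand points.

    Both point sets are snapped into one augmented graph; every reported
    distance is ``access_offset(site) + shortest path + access_offset(point)``.
    """

    def __init__(
        self,
        network: RoadNetwork,
        site_points: Sequence[Point],
        demand_points: Sequence[Point],
        tolerance_m: float = 500.0,
    ) -> None:
        n_sites = len(site_points)
        all_pts = list(site_points) + list(demand_points)
        self.graph, assignments = snap(all_pts, network, tolerance_m)
        self.site_assignments = assignments[:n_sites]
        self.demand_assignments = assignments[n_sites:]
        self.site_points = [tuple(map(float, p)) for p in site_points]
        self.demand_points = [tuple(map(float, p)) for p in demand_points]
        self.n_sites = n_sites
        self.n_demand = len(demand_points)

    def _from_site(self, i: int, weight: str, cutoff: float | None) -> dict:
        a = self.site_assignments[i]
        if a.unreachable:
            return {}
        return nx.single_source_dijkstra_path_length(
            self.graph, a.node, cutoff=cutoff, weight=weight
        )

    def distances_from_site(self, i: int, cutoff_m: float | None = None) -> np.ndarray:
        """Distances (m) from site ``i`` to every demand point; inf beyond
        ``cutoff_m`` or for unreachable endpoints."""
        a = self.site_assignments[i]
        out = np.full(self.n_demand, np.inf)
        if a.unreachable:
            return out
        net_cutoff = None if cutoff_m is None else max(cutoff_m - a.offset_m, 0.0)
        lengths = self._from_site(i, "length_m", net_cutoff)
        site_pt = self.site_points[i]
        for j, dj in enumerate(self.demand_assignments):
            if self.demand_points[j] == site_pt:
                out[j] = 0.0  # co-located pair: identical access location
                continue
            if dj.unreachable or dj.node not in lengths:
                continue
            d = a.offset_m + lengths[dj.node] + dj.offset_m
            if cutoff_m is None or d <= cutoff_m:
                out[j] = d
        return out

    def times_from_site(self, i: int) -> np.ndarray:
        """Travel times (minutes) along the fastest path, access offsets at
        the snapped edge's speed."""
        a = self.site_assignments[i]
        out = np.full(self.n_demand, np.inf)
        if a.unreachable:
            return out
        times = self._from_site(i, "time_min", None)
        site_pt = self.site_points[i]
        for j, dj in enumerate(self.demand_assignments):
            if self.demand_points[j] == site_pt:
                out[j] = 0.0
                continue
            if dj.unreachable or dj.node not in times:
                continue
            out[j] = a.offset_time_min + times[dj.node] + dj.offset_time_min
        return out

    def distance_matrix(self, cutoff_m: float | None = None) -> np.ndarray:
        """(n_sites, n_demand) distances in meters (inf beyond cutoff)."""
        return np.vstack([self.distances_from_site(i, cutoff_m) for i in range(self.n_sites)])

    def time_matrix(self) -> np.ndarray:
        return np.vstack([self.times_from_site(i) for i in range(self.n_sites)])
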