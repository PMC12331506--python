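"""Seeded synthetic cities for testing tiered healthcare accessibility analyses.

The generator emulates the data structure of a Chinese prefecture-level city
with a dense old urban core and sparse newly urbanised periphery: residential
compounds with household counts, three facility tiers (city / district /
community, mapped from tertiary / secondary-and-primary hospitals / community
health service stations), a hierarchical road network with class-dependent
speeds, a 1-km population grid, and administrative units carrying population
and hospital-bed totals.  Blind zones — clusters of residential areas beyond
every same-tier facility's network service radius — are planted with ground
truth so that downstream coverage and location-allocation stages can be
validated against a known answer.

All randomness flows from one root seed; each generation stage uses a child
seed derived by a fixed offset, so stages are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import box

Tier = Literal["city", "district", "community"]

#: Default network service radius per facility tier, meters.
TIER_RADIUS_M: dict[str, float] = {"city": 5000.0, "district": 3000.0, "community": 1000.0}

#: Default service population capacity per facility tier, persons.
TIER_CAPACITY_PERSONS: dict[str, float] = {
    "city": 260_000.0,
    "district": 67_000.0,
    "community": 15_000.0,
}

#: Average travel speed per road class, km/h.
ROAD_SPEED_KMH: dict[str, float] = {
    "expressway": 80.0,
    "primary": 60.0,
    "secondary": 40.0,
    "local": 30.0,
}

_TIERS: tuple[Tier, ...] = ("city", "district", "community")

# fixed child-seed offsets (root seed + offset -> per-stage rng)
_SEED_ROAD, _SEED_RESIDENTIAL, _SEED_FACILITY, _SEED_BEDS = 101, 211, 307, 401


class BlindZoneInfeasibleError(ValueError):
    """A planted blind zone cannot coexist with the requested facility layout."""


@dataclass(frozen=True)
class BlindZoneSpec:
    """A planted cluster of residential areas guaranteed uncovered at ``tier``."""

    center: tuple[float, float]
    radius_m: float
    n_residential: int
    tier: Tier = "community"


@dataclass(frozen=True)
class CityConfig:
    """Parameters of one synthetic city realisation.

    ``extent_m`` is an axis-aligned rectangle ``(width, height)`` in planar
    meters with origin at (0, 0).  ``core_fraction`` of the non-planted
    residential areas are drawn from a Gaussian cluster around the old core;
    the remainder are uniform over the extent (the new periphery).
    """

    extent_m: tuple[float, float] = (12_000.0, 12_000.0)
    n_residential: int = 400
    households_range: tuple[int, int] = (50, 800)
    tier_counts: tuple[int, int, int] = (5, 16, 56)  # city, district, community
    core_fraction: float = 0.6
    blind_zone_spec: tuple[BlindZoneSpec, ...] = ()
    grid_resolution_m: float = 1000.0
    persons_per_household: float = 2.5
    road_spacing_m: float = 1000.0
    admin_grid: tuple[int, int] = (3, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if w <= 0 or h <= 0:
            raise ValueError("extent dimensions must be positive")
        if not (0.0 <= self.core_fraction <= 1.0):
            raise ValueError("core_fraction must lie in [0, 1]")
        if self.grid_resolution_m <= 0:
            raise ValueError("grid_resolution_m must be positive")
        if any(c < 0 for c in self.tier_counts):
            raise ValueError("tier_counts must be nonnegative")
        lo, hi = self.households_range
        if lo < 1 or hi < lo:
            raise ValueError("households_range must satisfy 1 <= lo <= hi")
        for zone in self.blind_zone_spec:
            cx, cy = zone.center
            if not (zone.radius_m < cx < w - zone.radius_m and zone.radius_m < cy < h - zone.radius_m):
                raise BlindZoneInfeasibleError(
                    f"blind zone at {zone.center} (r={zone.radius_m}) does not fit in the extent"
                )


@dataclass
class RoadNetwork:
    """Undirected planar road graph; the carrier of network distances.

    Nodes carry ``pos=(x, y)`` in meters; edges carry ``length_m``,
    ``road_class``, ``speed_kmh`` and ``time_min``.
    """

    graph: nx.Graph

    def node_positions(self) -> dict[int, tuple[float, float]]:
        return {n: d["pos"] for n, d in self.graph.nodes(data=True)}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class ResidentialArea:
    """A residential compound: the demand unit of coverage accounting."""

    id: int
    location: tuple[float, float]
    households: int
    truth_blind: bool = False

    def __post_init__(self) -> None:
        if self.households < 1:
            raise ValueError("households must be >= 1")


@dataclass(frozen=True)
class Facility:
    """A healthcare facility with tier, bed count, radius and person capacity."""

    id: int
    tier: Tier
    location: tuple[float, float]
    beds: int = 0
    service_radius_m: float | None = None
    capacity_persons: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "service_radius_m",
            TIER_RADIUS_M[self.tier] if self.service_radius_m is None else float(self.service_radius_m),
        )
        object.__setattr__(
            self,
            "capacity_persons",
            TIER_CAPACITY_PERSONS[self.tier]
            if self.capacity_persons is None
            else float(self.capacity_persons),
        )
        if self.service_radius_m <= 0 or self.capacity_persons <= 0:
            raise ValueError("service radius and capacity must be positive")
        if self.beds < 0:
            raise ValueError("beds must be nonnegative")


@dataclass
class FacilitySet:
    facilities: list[Facility]

    def by_tier(self, tier: Tier) -> list[Facility]:
        return [f for f in self.facilities if f.tier == tier]

    def __len__(self) -> int:
        return len(self.facilities)

    def __iter__(self):
        return iter(self.facilities)


@dataclass
class PopulationGrid:
    """Regular raster of person counts; ``values[row, col]`` with row 0 at the
    southern (low-y) edge and origin at the grid's lower-left corner."""

    origin: tuple[float, float]
    cell_size_m: float
    n_rows: int
    n_cols: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValueError("values shape must be (n_rows, n_cols)")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-center coordinates, shape (rows, cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_m
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size_m
        return np.meshgrid(xs, ys)

    def total(self) -> float:
        return float(self.values.sum())

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; edge points clip inward."""
        x0, y0 = self.origin
        col = min(int((x - x0) // self.cell_size_m), self.n_cols - 1)
        row = min(int((y - y0) // self.cell_size_m), self.n_rows - 1)
        return max(row, 0), max(col, 0)


@dataclass
class AdminUnit:
    """Administrative unit: the spatial unit of Gini and Moran analyses."""

    id: int
    polygon: object  # shapely Polygon
    population: float
    beds: int


# ---------------------------------------------------------------------------
# road network


def _perturbed_grid_network(
    extent: tuple[float, float], spacing: float, rng: np.random.Generator
) -> RoadNetwork:
    """Perturbed lattice: expressway ring, primary central axes, secondary
    lines every 5th grid line, local streets elsewhere."""
    w, h = extent
    n_cols = int(round(w / spacing)) + 1
    n_rows = int(round(h / spacing)) + 1
    g = nx.Graph()

    def nid(r: int, c: int) -> int:
        return r * n_cols + c

    jitter = 0.2 * spacing
    for r in range(n_rows):
        for c in range(n_cols):
            x = c * (w / (n_cols - 1))
            y = r * (h / (n_rows - 1))
            boundary = r in (0, n_rows - 1) or c in (0, n_cols - 1)
            if not boundary:
                x += rng.uniform(-jitter, jitter)
                y += rng.uniform(-jitter, jitter)
            g.add_node(nid(r, c), pos=(x, y))

    mid_r, mid_c = n_rows // 2, n_cols // 2

    def line_class(idx: int, mid: int, last: int) -> str:
        if idx in (0, last):
            return "expressway"
        if idx == mid:
            return "primary"
        if idx % 5 == 0:
            return "secondary"
        return "local"

    def add_edge(a: int, b: int, road_class: str) -> None:
        pa, pb = g.nodes[a]["pos"], g.nodes[b]["pos"]
        length = math.dist(pa, pb)
        speed = ROAD_SPEED_KMH[road_class]
        g.add_edge(
            a, b,
            length_m=length,
            road_class=road_class,
            speed_kmh=speed,
            time_min=length / 1000.0 / speed * 60.0,
        )

    for r in range(n_rows):
        cls = line_class(r, mid_r, n_rows - 1)
        for c in range(n_cols - 1):
            add_edge(nid(r, c), nid(r, c + 1), cls)
    for c in range(n_cols):
        cls = line_class(c, mid_c, n_cols - 1)
        for r in range(n_rows - 1):
            add_edge(nid(r, c), nid(r + 1, c), cls)

    assert nx.is_connected(g)
    return RoadNetwork(g)


# ---------------------------------------------------------------------------
# residential areas and facilities


def _core_center(extent: tuple[float, float]) -> tuple[float, float]:
    w, h = extent
    return (0.40 * w, 0.55 * h)


def _sample_in_extent(
    rng: np.random.Generator,
    extent: tuple[float, float],
    center: tuple[float, float] | None,
    sigma: float | None,
) -> tuple[float, float]:
    """One point: Gaussian around ``center`` (resampled into the extent) or
    uniform when center is None."""
    w, h = extent
    for _ in range(1000):
        if center is None:
            return (rng.uniform(0, w), rng.uniform(0, h))
        x = rng.normal(center[0], sigma)
        y = rng.normal(center[1], sigma)
        if 0 <= x <= w and 0 <= y <= h:
            return (x, y)
    raise RuntimeError("rejection sampling failed to place a point in the extent")


def _sample_residential(
    config: CityConfig, rng: np.random.Generator
) -> list[ResidentialArea]:
    w, h = config.extent_m
    lo, hi = config.households_range
    n_planted = sum(z.n_residential for z in config.blind_zone_spec)
    n_free = config.n_residential - n_planted
    if n_free < 0:
        raise BlindZoneInfeasibleError(
            "blind zones request more residential areas than n_residential"
        )
    core = _core_center(config.extent_m)
    sigma = min(w, h) / 10.0
    n_core = int(round(config.core_fraction * n_free))

    areas: list[ResidentialArea] = []
    next_id = 0
    for i in range(n_free):
        if i < n_core:
            loc = _sample_in_extent(rng, config.extent_m, core, sigma)
        else:
            loc = _sample_in_extent(rng, config.extent_m, None, None)
        areas.append(
            ResidentialArea(next_id, loc, int(rng.integers(lo, hi + 1)), truth_blind=False)
        )
        next_id += 1
    for zone in config.blind_zone_spec:
        for _ in range(zone.n_residential):
            # uniform in the zone disk
            theta = rng.uniform(0, 2 * math.pi)
            rad = zone.radius_m * math.sqrt(rng.uniform())
            loc = (zone.center[0] + rad * math.cos(theta), zone.center[1] + rad * math.sin(theta))
            areas.append(
                ResidentialArea(next_id, loc, int(rng.integers(lo, hi + 1)), truth_blind=True)
            )
            next_id += 1
    return areas


# euclidean slack added to the planted-zone exclusion radius so that network
# distance (>= euclidean, minus two snap offsets) cannot undercut the tier
# radius; sized for the default 1 km road spacing.
_SNAP_SLACK_M = 1500.0


def _sample_facilities(
    config: CityConfig, rng: np.random.Generator, beds_rng: np.random.Generator
) -> FacilitySet:
    w, h = config.extent_m
    core = _core_center(config.extent_m)
    sigma = min(w, h) / 7.0
    beds_range = {"city": (500, 2000), "district": (100, 600), "community": (5, 30)}
    facilities: list[Facility] = []
    next_id = 0
    for tier, count in zip(_TIERS, config.tier_counts):
        # facilities of every tier stay out of each planted zone's buffer so
        # the zone is blind for its own tier regardless of facility mix
        excl = [
            (z.center, z.radius_m + TIER_RADIUS_M[tier] + _SNAP_SLACK_M)
            for z in config.blind_zone_spec
        ]
        for _ in range(count):
            placed = False
            for _attempt in range(2000):
                if rng.uniform() < 0.8:
                    loc = _sample_in_extent(rng, config.extent_m, core, sigma)
                else:
                    loc = _sample_in_extent(rng, config.extent_m, None, None)
                if all(math.dist(loc, c) > r for c, r in excl):
                    placed = True
                    break
            if not placed:
                raise BlindZoneInfeasibleError(
                    f"cannot place a {tier}-tier facility outside all planted zones"
                )
            lo_b, hi_b = beds_range[tier]
            facilities.append(
                Facility(next_id, tier, loc, beds=int(beds_rng.integers(lo_b, hi_b + 1)))
            )
            next_id += 1
    return FacilitySet(facilities)


# ---------------------------------------------------------------------------
# population grid and admin units


def rasterize_population(
    residential: Sequence[ResidentialArea],
    persons_per_household: float,
    resolution: float,
    extent_m: tuple[float, float] | None = None,
) -> PopulationGrid:
    """Mass-conserving binning of residential persons onto a regular grid.

    Each area contributes ``households * persons_per_household`` to the cell
    containing its location; total grid persons equal total residential
    persons exactly (up to float addition).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    xs = np.array([a.location[0] for a in residential])
    ys = np.array([a.location[1] for a in residential])
    if extent_m is None:
        w = float(np.ceil(xs.max() / resolution) * resolution) if len(xs) else resolution
        h = float(np.ceil(ys.max() / resolution) * resolution) if len(ys) else resolution
    else:
        w, h = extent_m
    n_cols = max(int(math.ceil(w / resolution)), 1)
    n_rows = max(int(math.ceil(h / resolution)), 1)
    persons = np.array([a.households for a in residential], dtype=float) * persons_per_household
    cols = np.minimum((xs // resolution).astype(int), n_cols - 1)
    rows = np.minimum((ys // resolution).astype(int), n_rows - 1)
    values = np.zeros((n_rows, n_cols))
    np.add.at(values, (rows, cols), persons)
    return PopulationGrid((0.0, 0.0), resolution, n_rows, n_cols, values)


def _admin_units(
    config: CityConfig,
    residential: Sequence[ResidentialArea],
    facilities: FacilitySet,
) -> list[AdminUnit]:
    w, h = config.extent_m
    nr, nc = config.admin_grid
    units: list[AdminUnit] = []
    uid = 0
    for r in range(nr):
        for c in range(nc):
            x0, x1 = c * w / nc, (c + 1) * w / nc
            y0, y1 = r * h / nr, (r + 1) * h / nr
            pop = sum(
                a.households * config.persons_per_household
                for a in residential
                if x0 <= a.location[0] < x1 or (c == nc - 1 and a.location[0] == x1)
                if y0 <= a.location[1] < y1 or (r == nr - 1 and a.location[1] == y1)
            )
            beds = sum(
                f.beds
                for f in facilities
                if x0 <= f.location[0] < x1 or (c == nc - 1 and f.location[0] == x1)
                if y0 <= f.location[1] < y1 or (r == nr - 1 and f.location[1] == y1)
            )
            units.append(AdminUnit(uid, box(x0, y0, x1, y1), pop, beds))
            uid += 1
    return units


# ---------------------------------------------------------------------------
# top-level generator


def generate_city(
    config: CityConfig,
) -> tuple[RoadNetwork, list[ResidentialArea], FacilitySet, PopulationGrid, list[AdminUnit]]:
    """Generate one synthetic city; deterministic under ``config.seed``.

    Planted blind zones are enforced by excluding facility placement from a
    buffer around each zone and then *verified* by exact network shortest
    paths; a violated plant raises :class:`BlindZoneInfeasibleError` rather
    than being silently adjusted.
    """
    seed = int(config.seed)
    network = _perturbed_grid_network(
        config.extent_m, config.road_spacing_m, np.random.default_rng(seed + _SEED_ROAD)
    )
    residential = _sample_residential(config, np.random.default_rng(seed + _SEED_RESIDENTIAL))
    facilities = _sample_facilities(
        config,
        np.random.default_rng(seed + _SEED_FACILITY),
        np.random.default_rng(seed + _SEED_BEDS),
    )
    grid = rasterize_population(
        residential, config.persons_per_household, config.grid_resolution_m, config.extent_m
    )
    admin = _admin_units(config, residential, facilities)

    _verify_planted_zones(config, network, residential, facilities)
    return network, residential, facilities, grid, admin


def _verify_planted_zones(
    config: CityConfig,
    network: RoadNetwork,
    residential: Sequence[ResidentialArea],
    facilities: FacilitySet,
) -> None:
    if not config.blind_zone_spec:
        return
    from .network import NetworkDistanceIndex

    planted = [a for a in residential if a.truth_blind]
    if not planted:
        return
    tiers = {z.tier for z in config.blind_zone_spec}
    for tier in tiers:
        same_tier = [f for f in facilities if f.tier == tier]
        if not same_tier:
            continue
        idx = NetworkDistanceIndex(
            network,
            [f.location for f in same_tier],
            [a.location for a in planted],
        )
        radius = TIER_RADIUS_M[tier]
        for i in range(len(same_tier)):
            d = idx.distances_from_site(i, cutoff_m=radius)
            if np.any(d <= radius):
                raise BlindZoneInfeasibleError(
                    f"planted blind zone reachable within {radius} m of a {tier} facility"
                )
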