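"""Road-network service areas, tiered coverage accounting and blind zones.

A facility's service area is the set of residential areas whose network
distance (including access offsets at both ends) is within the tier's service
radius — 5,000 m for city-level hospitals, 3,000 m for district-level
hospitals, 1,000 m for community health stations by default.  Residential
areas outside every same-tier service area are "healthcare deficiency" blind
zones; dense clusters of them are delimited by kernel density of the
uncovered points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Point

from ._util import percentage
from .diagnostics import DensityRaster, kernel_density
from .network import NetworkDistanceIndex, snap  # noqa: F401  (snap re-exported)
from .synthetic_city import (
    TIER_RADIUS_M,
    AdminUnit,
    Facility,
    FacilitySet,
    PopulationGrid,
    ResidentialArea,
    RoadNetwork,
)


@dataclass
class CoverageReport:
    """Coverage bookkeeping for one facility tier."""

    tier: str
    radius_m: float
    covered: set[int]
    uncovered: set[int]
    per_district_uncovered: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.covered & self.uncovered:
            raise ValueError("covered and uncovered sets overlap")

    @property
    def n_covered(self) -> int:
        return len(self.covered)

    @property
    def n_uncovered(self) -> int:
        return len(self.uncovered)

    @property
    def coverage_pct(self) -> float:
        return percentage(self.n_covered, self.n_covered + self.n_uncovered)

    @property
    def uncovered_pct(self) -> float:
        return percentage(self.n_uncovered, self.n_covered + self.n_uncovered)


def build_index(
    facilities: Sequence[Facility],
    residential: Sequence[ResidentialArea],
    network: RoadNetwork,
    tolerance_m: float = 500.0,
) -> NetworkDistanceIndex:
    """Snap facilities and residential areas into one augmented network."""
    return NetworkDistanceIndex(
        network,
        [f.location for f in facilities],
        [a.location for a in residential],
        tolerance_m=tolerance_m,
    )


def service_area(
    facility: Facility,
    network: RoadNetwork,
    residential: Sequence[ResidentialArea],
    radius_m: float | None = None,
    index: NetworkDistanceIndex | None = None,
    facility_pos: int = 0,
) -> set[int]:
    """Residential ids within network radius of one facility.

    Pass a prebuilt ``index`` (with the facility at ``facility_pos``) to avoid
    re-snapping; otherwise a single-facility index is built on the fly.
    """
    radius = facility.service_radius_m if radius_m is None else radius_m
    if index is None:
        index = build_index([facility], residential, network)
        facility_pos = 0
    d = index.distances_from_site(facility_pos, cutoff_m=radius)
    return {residential[j].id for j in np.flatnonzero(d <= radius)}


def tier_coverage(
    facilities: FacilitySet,
    residential: Sequence[ResidentialArea],
    network: RoadNetwork,
    tier: str,
    radius_m: float | None = None,
    admin_units: Sequence[AdminUnit] | None = None,
    index: NetworkDistanceIndex | None = None,
) -> CoverageReport:
    """Union of same-tier service areas and the resulting coverage statistics.

    Per-facility radius overrides (``Facility.service_radius_m``) are honored
    unless ``radius_m`` forces a single radius for the whole tier.
    """
    tier_fac = facilities.by_tier(tier)
    all_ids = {a.id for a in residential}
    if not tier_fac:
        warnings.warn(f"no facilities of tier {tier!r}: all residential areas uncovered")
        return CoverageReport(tier, radius_m or TIER_RADIUS_M[tier], set(), all_ids)
    if index is None:
        index = build_index(tier_fac, residential, network)
    covered: set[int] = set()
    max_radius = 0.0
    for i, f in enumerate(tier_fac):
        r = f.service_radius_m if radius_m is None else radius_m
        max_radius = max(max_radius, r)
        d = index.distances_from_site(i, cutoff_m=r)
        covered |= {residential[j].id for j in np.flatnonzero(d <= r)}
    report = CoverageReport(tier, max_radius, covered, all_ids - covered)
    if admin_units is not None:
        by_loc = {a.id: a.location for a in residential}
        for u in admin_units:
            report.per_district_uncovered[u.id] = sum(
                1 for rid in report.uncovered if u.polygon.covers(Point(by_loc[rid]))
            )
    return report


@dataclass
class BlindZoneCluster:
    """One connected high-density region of uncovered residential areas."""

    member_ids: list[int]
    households: int
    n_cells: int

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def blind_zones(
    report: CoverageReport,
    residential: Sequence[ResidentialArea],
    kde_bandwidth: float,
    grid: PopulationGrid,
    quantile: float = 0.90,
) -> tuple[list[BlindZoneCluster], DensityRaster]:
    """Delimit healthcare-deficiency clusters among uncovered residential areas.

    Kernel density over the uncovered points (household-weighted), thresholded
    at ``quantile`` of the positive raster values; connected raster regions
    above the threshold become clusters, ranked by summed uncovered
    households.  Uncovered points whose cell falls in no region are left
    unclustered.
    """
    uncovered = [a for a in residential if a.id in report.uncovered]
    if not uncovered:
        return [], None
    pts = [a.location for a in uncovered]
    wts = [a.households for a in uncovered]
    raster = kernel_density(pts, wts, kde_bandwidth, grid)
    positive = raster.values[raster.values > 0]
    if positive.size == 0:
        return [], raster
    threshold = float(np.quantile(positive, quantile))
    mask = raster.values > threshold
    labels, n_regions = ndimage.label(mask)
    clusters: dict[int, list[ResidentialArea]] = {}
    for a in uncovered:
        row, col = grid.cell_of(*a.location)
        lab = int(labels[row, col])
        if lab > 0:
            clusters.setdefault(lab, []).append(a)
    out = [
        BlindZoneCluster(
            member_ids=sorted(x.id for x in members),
            households=sum(x.households for x in members),
            n_cells=int((labels == lab).sum()),
        )
        for lab, members in clusters.items()
    ]
    out.sort(key=lambda c: (-c.households, c.member_ids))
    return out, raster


def top_cluster_share(clusters: Sequence[BlindZoneCluster], n_uncovered: int, k: int = 2) -> float:
    """Share (%) of uncovered residential areas in the k largest clusters."""
    part = sum(c.n_members for c in clusters[:k])
    return percentage(part, n_uncovered)
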