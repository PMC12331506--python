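"""End-to-end orchestration: generate -> diagnose -> equity -> coverage ->
allocate -> report, reproducible under one seed, writing every intermediate
artifact plus a final validation summary."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import percentage, round_half_up
from . import io as mio
from .diagnostics import (
    SpatialWeights,
    bivariate_moran,
    default_bandwidth,
    deviation_ellipse,
    ellipse_polygon,
    kernel_density,
    population_centroid,
)
from .equity import gini_report
from .location_allocation import (
    AllocationPlan,
    compare_plans,
    incremental_plan,
    redistribution_plan,
)
from .service_area import CoverageReport, blind_zones, tier_coverage
from .synthetic_city import (
    TIER_RADIUS_M,
    BlindZoneSpec,
    CityConfig,
    Facility,
    FacilitySet,
    generate_city,
)

logger = logging.getLogger(__name__)

_TIERS = ("city", "district", "community")


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    city: CityConfig = field(default_factory=lambda: CityConfig(
        blind_zone_spec=(BlindZoneSpec((10_000.0, 2_000.0), 1000.0, 25, "community"),)
    ))
    seed: int = 0
    kde_bandwidth_m: float | None = None  # None -> extent diagonal / 30
    n_permutations: int = 199
    alpha: float = 0.05
    blind_zone_quantile: float = 0.90
    max_new: dict = field(default_factory=lambda: {"city": 6, "district": 6, "community": None})
    community_mode: str = "redistribution"  # or "increment"
    community_budget: int | None = None

    def __post_init__(self) -> None:
        if self.seed != self.city.seed:
            self.city = dataclasses.replace(self.city, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        city_raw = raw.pop("city", {})
        zones = tuple(
            BlindZoneSpec(tuple(z["center"]), z["radius_m"], z["n_residential"], z.get("tier", "community"))
            for z in city_raw.pop("blind_zone_spec", [])
        )
        for key in ("extent_m", "households_range", "tier_counts", "admin_grid"):
            if key in city_raw:
                city_raw[key] = tuple(city_raw[key])
        city = CityConfig(blind_zone_spec=zones, **city_raw)
        return cls(city=city, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["city"]["blind_zone_spec"] = [
            {"center": list(z["center"]), "radius_m": z["radius_m"],
             "n_residential": z["n_residential"], "tier": z["tier"]}
            for z in d["city"]["blind_zone_spec"]
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class ValidationSummary:
    """Per-tier coverage before/after optimization plus union coverage."""

    table: pd.DataFrame  # tier, before_pct, after_pct, improvement_pp
    combined_pct: float

    def to_markdown(self) -> str:
        lines = ["| Tier | Original coverage (%) | Optimized coverage (%) | Improvement (pp) |",
                 "|---|---|---|---|"]
        for row in self.table.itertuples(index=False):
            lines.append(f"| {row.tier} | {row.before_pct:.2f} | {row.after_pct:.2f} | {row.improvement_pp:.2f} |")
        lines.append(f"\nCombined coverage (any tier): {self.combined_pct:.2f}%")
        return "\n".join(lines)


def validation_summary(
    reports_before: dict[str, CoverageReport],
    reports_after: dict[str, CoverageReport],
    residential: Sequence,
) -> ValidationSummary:
    """Tabulate per-tier improvement and the union coverage across tiers."""
    if set(reports_before) != set(reports_after):
        raise ValueError("before/after reports cover different tiers")
    n_total = len(residential)
    all_ids = {a.id for a in residential}
    rows = []
    union: set = set()
    for tier in reports_before:
        b, a = reports_before[tier], reports_after[tier]
        if b.covered | b.uncovered != all_ids or a.covered | a.uncovered != all_ids:
            raise ValueError("coverage reports do not match the residential universe")
        rows.append(
            {
                "tier": tier,
                "before_pct": b.coverage_pct,
                "after_pct": a.coverage_pct,
                "improvement_pp": round_half_up(a.coverage_pct - b.coverage_pct, 2),
            }
        )
        union |= a.covered
    return ValidationSummary(pd.DataFrame(rows), percentage(len(union), n_total))


def _optimized_facilities(
    existing: FacilitySet, tier: str, plan: AllocationPlan, residential_by_id: dict
) -> list[Facility]:
    """Facility set implied by a plan: retained existing + new sites at
    selected candidate residential locations."""
    next_id = max((f.id for f in existing), default=0) + 1
    if plan.mode == "redistribution":
        by_id = {f.id: f for f in existing.by_tier(tier)}
        kept = [by_id[s[1][1]] for s in plan.retained_existing]
        new_locs = [residential_by_id[s[1][1]].location for s in plan.selected_new]
    else:
        kept = existing.by_tier(tier)
        new_locs = [residential_by_id[s[1]].location for s in plan.selected_new]
    new = [Facility(next_id + k, tier, loc, beds=0) for k, loc in enumerate(new_locs)]
    return kept + new


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> ValidationSummary:
    """Execute every stage, writing artifacts under ``out_dir``.

    Deterministic under ``config.seed``; any stage failure propagates with the
    stage named in the log.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    t0 = time.time()

    def stage(name: str) -> None:
        logger.info("stage=%s seed=%d elapsed_s=%.1f", name, config.seed, time.time() - t0)

    # --- generate -----------------------------------------------------------
    stage("generate")
    network, residential, facilities, grid, admin = generate_city(config.city)
    mio.write_residential_geojson(out / "residential.geojson", residential)
    mio.write_facilities_geojson(out / "facilities.geojson", facilities)
    mio.write_road_geojson(out / "roads.geojson", network)
    mio.write_road_csvs(out / "road_nodes.csv", out / "road_edges.csv", network)
    mio.write_admin_geojson(out / "admin_units.geojson", admin)
    mio.write_ascii_grid(out / "population.asc", grid.values, grid.origin, grid.cell_size_m)

    # --- diagnostics --------------------------------------------------------
    stage("diagnostics")
    h = config.kde_bandwidth_m or default_bandwidth(config.city.extent_m)
    ellipse_rows = []
    for tier in _TIERS:
        pts = [f.location for f in facilities.by_tier(tier)]
        if len(pts) >= 1:
            raster = kernel_density(pts, None, h, grid)
            mio.write_ascii_grid(out / f"kde_{tier}.asc", raster.values, grid.origin, grid.cell_size_m)
        if len(pts) >= 3:
            ell = deviation_ellipse(pts)
            ellipse_rows.append(
                {"tier": tier, "center_x": ell.center[0], "center_y": ell.center[1],
                 "sigma_x": ell.sigma_x, "sigma_y": ell.sigma_y, "theta_deg": ell.theta_deg}
            )
            mio.write_geojson_polygons(
                out / f"sde_{tier}.geojson", [ellipse_polygon(ell)], [{"tier": tier}]
            )
    pd.DataFrame(ellipse_rows).to_csv(out / "deviation_ellipses.csv", index=False)

    w = SpatialWeights.queen_from_polygons([u.polygon for u in admin], [u.id for u in admin])
    pops = np.array([u.population for u in admin], dtype=float)
    beds = np.array([u.beds for u in admin], dtype=float)
    moran = bivariate_moran(
        pops, beds, w, n_perm=config.n_permutations, alpha=config.alpha,
        seed=config.seed + 977,
    )
    mio.write_geojson_polygons(
        out / "moran_clusters.geojson",
        [list(u.polygon.exterior.coords) for u in admin],
        [
            {"id": u.id, "cluster": cls, "local_I": float(li), "local_p": float(lp)}
            for u, cls, li, lp in zip(admin, moran.clusters, moran.local_I, moran.local_p)
        ],
    )
    (out / "moran.json").write_text(json.dumps(
        {"I": moran.I, "p_value": moran.p_value, "n_permutations": moran.n_permutations}
    ))
    cx, cy = population_centroid(grid)
    (out / "population_centroid.json").write_text(json.dumps({"x": cx, "y": cy}))

    # --- equity -------------------------------------------------------------
    stage("equity")
    report = gini_report([(u.population, u.beds) for u in admin], [u.id for u in admin])
    report.table.assign(gini=report.G, label=report.label).to_csv(out / "equity.csv", index=False)

    # --- coverage (before) --------------------------------------------------
    stage("coverage")
    residential_by_id = {a.id: a for a in residential}
    before: dict[str, CoverageReport] = {}
    for tier in _TIERS:
        rep = tier_coverage(facilities, residential, network, tier, admin_units=admin)
        before[tier] = rep
        clusters, _ = blind_zones(rep, residential, h, grid, config.blind_zone_quantile)
        pd.DataFrame(
            [
                {"rank": k + 1, "n_members": c.n_members, "households": c.households}
                for k, c in enumerate(clusters)
            ]
        ).to_csv(out / f"blind_zones_{tier}.csv", index=False)
    pd.DataFrame(
        [
            {"tier": t, "radius_m": r.radius_m, "n_covered": r.n_covered,
             "n_uncovered": r.n_uncovered, "coverage_pct": r.coverage_pct}
            for t, r in before.items()
        ]
    ).to_csv(out / "coverage_before.csv", index=False)

    # --- allocation ---------------------------------------------------------
    stage("allocate")
    pph = config.city.persons_per_household
    plans: dict[str, AllocationPlan] = {}
    for tier in ("city", "district"):
        plans[tier] = incremental_plan(
            facilities, residential, network, tier,
            max_new=config.max_new.get(tier), persons_per_household=pph,
            compute_times=True,
        )
    comm_inc = incremental_plan(
        facilities, residential, network, "community",
        max_new=config.max_new.get("community"), persons_per_household=pph,
    )
    comm_red = redistribution_plan(
        facilities, residential, network, "community",
        budget=config.community_budget, persons_per_household=pph,
    )
    n_comm = len(facilities.by_tier("community"))
    compare_plans(comm_inc, comm_red, n_comm).to_csv(out / "community_plan_comparison.csv")
    plans["community"] = comm_red if config.community_mode == "redistribution" else comm_inc
    for tier, plan in plans.items():
        if plan.site_table is not None:
            plan.site_table.to_csv(out / f"plan_sites_{tier}.csv", index=False)
        (out / f"plan_{tier}.json").write_text(json.dumps(
            {
                "mode": plan.mode,
                "selected_new": [repr(s) for s in plan.selected_new],
                "n_new": len(plan.selected_new),
                "net_new": plan.net_new,
                "relocations": plan.relocated_count,
                "coverage_before_pct": plan.coverage_before_pct,
                "coverage_after_pct": plan.coverage_after_pct,
                "mean_travel_time_min": plan.mean_travel_time_min,
            }
        ))

    # --- validation ---------------------------------------------------------
    stage("report")
    after: dict[str, CoverageReport] = {}
    for tier, plan in plans.items():
        opt = FacilitySet(
            [dataclasses.replace(f, id=k) for k, f in enumerate(
                _optimized_facilities(facilities, tier, plan, residential_by_id)
            )]
        )
        after[tier] = tier_coverage(opt, residential, network, tier)
    summary = validation_summary(before, after, residential)
    summary.table.to_csv(out / "validation_summary.csv", index=False)
    (out / "summary.md").write_text(
        "# Pipeline validation summary\n\n" + summary.to_markdown() + "\n"
    )
    stage("done")
    return summary
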