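"""Capacitated maximal-coverage location-allocation for tiered facilities.

Sites are chosen to maximise the person-demand assignable within the tier's
service radius without exceeding any facility's service-population capacity.
Two planning modes mirror common practice in facility planning:

* **incremental** — existing facilities are immovable; candidate sites are the
  residential areas currently outside every service area, and the plan adds
  the fewest sites needed to reach a coverage target (or until no candidate
  adds coverage);
* **redistribution** — a fixed budget of facilities (by default the current
  count) is re-sited freely over the union of existing locations and
  uncovered residential locations, so redundant co-located stations can move
  into blind zones without increasing the total.

Selection uses the classical greedy heuristic for maximal coverage (largest
marginal newly-assigned person-demand first), which carries the (1 - 1/e)
approximation guarantee in the uncapacitated case; an enumeration-based exact
solver is provided as an oracle for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from ._util import percentage, round_half_up
from .network import NetworkDistanceIndex
from .synthetic_city import (
    TIER_CAPACITY_PERSONS,
    TIER_RADIUS_M,
    FacilitySet,
    ResidentialArea,
    RoadNetwork,
)

SiteId = Hashable


@dataclass
class AllocationProblem:
    """A capacitated coverage instance on precomputed network distances.

    Sites (rows of ``dist``) are ordered fixed-first then candidates, each
    block ascending by site id; that order is the deterministic tie-break.
    ``dist`` holds meters with ``inf`` beyond the service radius.
    """

    demand_ids: np.ndarray
    demand_persons: np.ndarray
    demand_households: np.ndarray
    site_ids: list[SiteId]
    n_fixed: int
    radius_m: float
    capacity_persons: float
    dist: np.ndarray  # (n_sites, n_demand)
    time_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.radius_m <= 0 or self.capacity_persons <= 0:
            raise ValueError("radius and capacity must be positive")
        if self.dist.shape != (len(self.site_ids), len(self.demand_ids)):
            raise ValueError("distance matrix shape mismatch")

    @property
    def n_demand(self) -> int:
        return len(self.demand_ids)

    @property
    def fixed_rows(self) -> list[int]:
        return list(range(self.n_fixed))

    @property
    def candidate_rows(self) -> list[int]:
        return list(range(self.n_fixed, len(self.site_ids)))


@dataclass
class Assignment:
    """Demand-to-facility assignment with per-facility person loads."""

    demand_to_site: dict[Hashable, SiteId]
    loads: dict[SiteId, float]
    total_persons: float
    covered_ids: set

    @property
    def n_assigned(self) -> int:
        return len(self.demand_to_site)


def assign_demand(problem: AllocationProblem, selected_rows: Sequence[int]) -> Assignment:
    """Assign demands to selected sites, nearest pairs first, capacity-aware.

    All in-radius (site, demand) pairs are processed in ascending distance
    order (ties: site order, then demand order); a demand takes the first
    site with enough residual capacity, so it spills to its next-nearest
    in-radius site when the nearest is full.  Unassigned is a valid outcome.
    """
    rows = sorted(set(selected_rows))
    persons = problem.demand_persons
    residual = {s: problem.capacity_persons for s in rows}
    pairs: list[tuple[float, int, int]] = []
    for s in rows:
        d = problem.dist[s]
        for j in np.flatnonzero(d <= problem.radius_m):
            pairs.append((float(d[j]), s, int(j)))
    pairs.sort()
    demand_to_site: dict[Hashable, SiteId] = {}
    loads: dict[SiteId, float] = {problem.site_ids[s]: 0.0 for s in rows}
    assigned = np.zeros(problem.n_demand, dtype=bool)
    for d, s, j in pairs:
        if assigned[j] or residual[s] < persons[j]:
            continue
        assigned[j] = True
        residual[s] -= persons[j]
        sid = problem.site_ids[s]
        demand_to_site[problem.demand_ids[j]] = sid
        loads[sid] += float(persons[j])
    for sid, load in loads.items():
        assert load <= problem.capacity_persons + 1e-9, "capacity violated"
    total = float(persons[assigned].sum())
    covered = {problem.demand_ids[j] for j in np.flatnonzero(assigned)}
    return Assignment(demand_to_site, loads, total, covered)


@dataclass
class AllocationPlan:
    """Outcome of one planning run."""

    mode: str
    selected_new: list[SiteId]
    retained_existing: list[SiteId]
    relocated_count: int
    assignment: Assignment
    coverage_before_pct: float
    coverage_after_pct: float
    selection_order: list[SiteId] = field(default_factory=list)
    infeasible: bool = False
    mean_travel_time_min: float | None = None
    site_table: pd.DataFrame | None = None
    n_existing: int = 0

    @property
    def net_new(self) -> int:
        """Change in total facility count (negative under redistribution)."""
        if self.mode == "redistribution":
            return len(self.selected_new) + len(self.retained_existing) - self.n_existing
        return len(self.selected_new)

    @property
    def coverage_increase_pp(self) -> float:
        return round_half_up(self.coverage_after_pct - self.coverage_before_pct, 2)


def _coverage_pct(assignment: Assignment, problem: AllocationProblem) -> float:
    return percentage(len(assignment.covered_ids), problem.n_demand)


def greedy_mclp(
    problem: AllocationProblem,
    target_coverage_pct: float | None = None,
    max_new: int | None = None,
    mode: str = "increment",
) -> AllocationPlan:
    """Greedy capacitated maximal coverage over the candidate sites.

    Repeatedly adds the candidate with the largest marginal newly-assigned
    person-demand (evaluated by a full re-assignment, so capacity spill is
    respected); stops at the coverage target, the ``max_new`` budget, or when
    the best marginal gain is zero.
    """
    fixed = problem.fixed_rows
    current = assign_demand(problem, fixed)
    before_pct = _coverage_pct(current, problem)
    selected: list[int] = []
    remaining = set(problem.candidate_rows)
    infeasible = False
    while remaining:
        if max_new is not None and len(selected) >= max_new:
            break
        if target_coverage_pct is not None and _coverage_pct(current, problem) >= target_coverage_pct:
            break
        best_row, best_gain, best_assign = None, 0.0, None
        for c in sorted(remaining):
            trial = assign_demand(problem, fixed + selected + [c])
            gain = trial.total_persons - current.total_persons
            if gain > best_gain + 1e-9:
                best_row, best_gain, best_assign = c, gain, trial
        if best_row is None:
            break
        selected.append(best_row)
        remaining.discard(best_row)
        current = best_assign
    after_pct = _coverage_pct(current, problem)
    if target_coverage_pct is not None and after_pct < target_coverage_pct:
        infeasible = True
    return AllocationPlan(
        mode=mode,
        selected_new=[problem.site_ids[s] for s in selected],
        retained_existing=[problem.site_ids[s] for s in fixed],
        relocated_count=0,
        assignment=current,
        coverage_before_pct=before_pct,
        coverage_after_pct=after_pct,
        selection_order=[problem.site_ids[s] for s in selected],
        infeasible=infeasible,
    )


def exact_mclp(problem: AllocationProblem, p: int) -> AllocationPlan:
    """Provably optimal covered-person demand for exactly ``p`` new sites.

    Exhaustive enumeration over candidate subsets; limited to instances with
    at most 20 candidates.
    """
    cands = problem.candidate_rows
    if len(cands) > 20:
        raise ValueError("exact_mclp enumerates subsets: at most 20 candidate sites")
    p = min(p, len(cands))
    fixed = problem.fixed_rows
    baseline = assign_demand(problem, fixed)
    best_subset: tuple[int, ...] = ()
    best_assign, best_total = baseline, baseline.total_persons
    for subset in itertools.combinations(cands, p):
        trial = assign_demand(problem, fixed + list(subset))
        if trial.total_persons > best_total + 1e-9:
            best_subset, best_assign, best_total = subset, trial, trial.total_persons
    return AllocationPlan(
        mode="exact",
        selected_new=[problem.site_ids[s] for s in best_subset],
        retained_existing=[problem.site_ids[s] for s in fixed],
        relocated_count=0,
        assignment=best_assign,
        coverage_before_pct=_coverage_pct(baseline, problem),
        coverage_after_pct=_coverage_pct(best_assign, problem),
    )


# ---------------------------------------------------------------------------
# problem construction from a city


def build_problem(
    fixed_facilities: Sequence,
    candidate_locations: Sequence[tuple[float, float]],
    candidate_ids: Sequence[SiteId],
    residential: Sequence[ResidentialArea],
    network: RoadNetwork,
    radius_m: float,
    capacity_persons: float,
    persons_per_household: float = 2.5,
    compute_times: bool = False,
) -> AllocationProblem:
    """Assemble distances for fixed + candidate sites against all demands."""
    fixed_sorted = sorted(fixed_facilities, key=lambda f: f.id)
    order = sorted(range(len(candidate_ids)), key=lambda i: candidate_ids[i])
    cand_ids = [candidate_ids[i] for i in order]
    cand_locs = [candidate_locations[i] for i in order]
    site_points = [f.location for f in fixed_sorted] + list(cand_locs)
    index = NetworkDistanceIndex(network, site_points, [a.location for a in residential])
    dist = index.distance_matrix(cutoff_m=radius_m)
    times = index.time_matrix() if compute_times else None
    households = np.array([a.households for a in residential], dtype=float)
    return AllocationProblem(
        demand_ids=np.array([a.id for a in residential]),
        demand_persons=households * persons_per_household,
        demand_households=households,
        site_ids=[("fixed", f.id) for f in fixed_sorted] + [("cand", c) for c in cand_ids],
        n_fixed=len(fixed_sorted),
        radius_m=radius_m,
        capacity_persons=capacity_persons,
        dist=dist,
        time_min=times,
    )


def _uncovered_ids(
    facilities: Sequence, residential: Sequence[ResidentialArea], network: RoadNetwork, radius_m: float
) -> set:
    if not facilities:
        return {a.id for a in residential}
    index = NetworkDistanceIndex(
        network, [f.location for f in facilities], [a.location for a in residential]
    )
    d = index.distance_matrix(cutoff_m=radius_m)
    covered = (d <= radius_m).any(axis=0)
    return {a.id for a, c in zip(residential, covered) if not c}


def _site_table(plan: AllocationPlan, problem: AllocationProblem) -> pd.DataFrame:
    """Per-new-site served residential areas and household totals."""
    hh = dict(zip(problem.demand_ids.tolist(), problem.demand_households.tolist()))
    rows = []
    for sid in plan.selected_new:
        members = [d for d, s in plan.assignment.demand_to_site.items() if s == sid]
        rows.append(
            {
                "site": sid,
                "served_residential": len(members),
                "households": int(sum(hh[m] for m in members)),
                "load_persons": plan.assignment.loads.get(sid, 0.0),
            }
        )
    return pd.DataFrame(rows, columns=["site", "served_residential", "households", "load_persons"])


def incremental_plan(
    existing: FacilitySet,
    residential: Sequence[ResidentialArea],
    network: RoadNetwork,
    tier: str,
    radius_m: float | None = None,
    capacity_persons: float | None = None,
    target_coverage_pct: float | None = None,
    max_new: int | None = None,
    persons_per_household: float = 2.5,
    compute_times: bool = False,
) -> AllocationPlan:
    """Minimal-increment optimization: keep existing sites, add the fewest new
    ones (at currently uncovered residential locations) that maximise
    coverage."""
    radius = TIER_RADIUS_M[tier] if radius_m is None else radius_m
    capacity = TIER_CAPACITY_PERSONS[tier] if capacity_persons is None else capacity_persons
    fixed = existing.by_tier(tier)
    uncovered = _uncovered_ids(fixed, residential, network, radius)
    by_id = {a.id: a for a in residential}
    cand_ids = sorted(uncovered)
    problem = build_problem(
        fixed,
        [by_id[i].location for i in cand_ids],
        cand_ids,
        residential,
        network,
        radius,
        capacity,
        persons_per_household,
        compute_times,
    )
    plan = greedy_mclp(problem, target_coverage_pct, max_new, mode="increment")
    plan.site_table = _site_table(plan, problem)
    plan.n_existing = len(fixed)
    if compute_times:
        plan.mean_travel_time_min = mean_travel_time(plan.assignment, problem)
    return plan


def redistribution_plan(
    existing: FacilitySet,
    residential: Sequence[ResidentialArea],
    network: RoadNetwork,
    tier: str = "community",
    budget: int | None = None,
    radius_m: float | None = None,
    capacity_persons: float | None = None,
    persons_per_household: float = 2.5,
    compute_times: bool = False,
) -> AllocationPlan:
    """Re-site up to ``budget`` facilities (default: the existing count) over
    existing locations plus uncovered residential locations, with no site
    fixed — redundant stations compete against blind-zone candidates."""
    radius = TIER_RADIUS_M[tier] if radius_m is None else radius_m
    capacity = TIER_CAPACITY_PERSONS[tier] if capacity_persons is None else capacity_persons
    fixed = existing.by_tier(tier)
    if budget is None:
        budget = len(fixed)
    if budget < 1:
        raise ValueError("budget must be at least 1")
    uncovered = _uncovered_ids(fixed, residential, network, radius)
    by_id = {a.id: a for a in residential}
    cand_ids: list[SiteId] = [("exist", f.id) for f in sorted(fixed, key=lambda f: f.id)] + [
        ("res", i) for i in sorted(uncovered)
    ]
    cand_locs = [f.location for f in sorted(fixed, key=lambda f: f.id)] + [
        by_id[i].location for i in sorted(uncovered)
    ]
    problem = build_problem(
        [], cand_locs, cand_ids, residential, network, radius, capacity,
        persons_per_household, compute_times,
    )
    # baseline: current layout, capacity-aware
    existing_rows = [
        r for r in problem.candidate_rows if problem.site_ids[r][1][0] == "exist"
    ]
    baseline = assign_demand(problem, existing_rows)
    before_pct = _coverage_pct(baseline, problem)

    plan = greedy_mclp(problem, max_new=budget, mode="redistribution")
    selected = plan.selected_new  # [("cand", ("exist", fid)) | ("cand", ("res", rid))]
    retained = [s for s in selected if s[1][0] == "exist"]
    new_sites = [s for s in selected if s[1][0] == "res"]
    n_exist, n_ret = len(fixed), len(retained)
    relocations = min(n_exist - n_ret, len(selected) - n_ret)
    plan.selected_new = new_sites
    plan.retained_existing = retained
    plan.relocated_count = relocations
    plan.coverage_before_pct = before_pct
    plan.n_existing = n_exist
    plan.site_table = _site_table(plan, problem)
    if compute_times:
        plan.mean_travel_time_min = mean_travel_time(plan.assignment, problem)
    return plan


def compare_plans(
    plan_a: AllocationPlan, plan_b: AllocationPlan, existing_count: int,
    names: tuple[str, str] = ("Plan 1", "Plan 2"),
) -> pd.DataFrame:
    """Side-by-side comparison in the standard planning-table layout:
    total after optimization, net new units, relocations, coverage after,
    and coverage increase rate (percentage points)."""
    if plan_a.coverage_before_pct != plan_b.coverage_before_pct:
        raise ValueError("plans must share the same baseline city and tier")
    rows = {}
    for name, p in zip(names, (plan_a, plan_b)):
        rows[name] = {
            "total_after": existing_count + p.net_new,
            "new_units": p.net_new,
            "relocations": p.relocated_count,
            "coverage_after_pct": p.coverage_after_pct,
            "coverage_increase_pp": p.coverage_increase_pp,
        }
    return pd.DataFrame(rows)


def mean_travel_time(assignment: Assignment, problem: AllocationProblem) -> float:
    """Demand-weighted mean travel time (minutes) over assigned demands."""
    if not assignment.demand_to_site:
        raise ValueError("empty assignment")
    if problem.time_min is None:
        raise ValueError("problem was built without travel times")
    site_row = {sid: r for r, sid in enumerate(problem.site_ids)}
    demand_row = {d: j for j, d in enumerate(problem.demand_ids.tolist())}
    total_w = total_t = 0.0
    for d, sid in assignment.demand_to_site.items():
        j = demand_row[d]
        w = problem.demand_persons[j]
        total_w += w
        total_t += w * problem.time_min[site_row[sid], j]
    return total_t / total_w
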