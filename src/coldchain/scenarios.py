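"""Two-stage pipeline orchestration and scenario comparison.

``run_two_stage`` builds the model-specific network (depot in Oslo for
models 1 and 3; relocated to Hamar — or a greenfield center-of-gravity —
for model 2), solves the per-group routing problems with the model's vehicle
assignment, and Monte-Carlo-simulates the plan under the scenario's fleet.

``compare_scenarios`` sweeps several scenarios on one instance, optionally
with common random numbers (paired seed streams) so that fleet-nesting
comparisons are variance-reduced, and reports pairwise KPI deltas plus a
monotonicity verdict for nested fleets.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .instance import HAMAR, Instance, ValidationError, build_distance_matrix
from .kpi import (
    KPIReport,
    MonteCarloSummary,
    aggregate_replications,
    compute_report,
    summary_row,
)
from .routing import (
    CVRPConfig,
    ExactSizeError,
    Route,
    RoutePlan,
    assign_vehicle_types,
    greenfield_location,
    route_demands,
    solve_cvrp_exact,
    solve_cvrp_heuristic,
    validate_route_plan,
)
from .sim import SimConfig, run_replication
from .synth import assign_customer_groups


@dataclass
class Scenario:
    """A network model + fleet composition to evaluate."""

    id: int
    model_id: int
    fleet: dict[str, int]
    use_gfa: bool = False
    sim_overrides: dict = field(default_factory=dict)
    elt_override: dict[int, float] | None = None
    instance_ref: str | None = None

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValidationError(f"scenario {self.id}: model_id must be 1, 2 or 3")
        if any(c < 0 for c in self.fleet.values()) or sum(self.fleet.values()) < 1:
            raise ValidationError(f"scenario {self.id}: fleet needs at least one vehicle")

    @property
    def elt_days(self) -> dict[int, float]:
        if self.elt_override is not None:
            return dict(self.elt_override)
        # the relocated DC of model 2 is close to all centers: both groups get a 1-day target
        if self.model_id == 2:
            return {1: 1.0, 2: 1.0}
        return {1: 1.0, 2: 2.0}


@dataclass
class TwoStageResult:
    scenario: Scenario
    plan: RoutePlan
    summary: MonteCarloSummary
    reports: list[KPIReport]
    per_rep_service_level: list[float]


@dataclass
class ComparisonReport:
    summaries: dict[int, MonteCarloSummary]
    deltas: dict[tuple[int, int], dict[str, float]]
    nested_monotonic: dict[tuple[int, int], bool]
    paired: bool


# ---------------------------------------------------------------------------
# model-specific network construction
# ---------------------------------------------------------------------------

def build_model_instance(instance: Instance, model_id: int, use_gfa: bool = False) -> Instance:
    """Instance with the model's DC location and customer-group assignment.

    Models 1 and 3 keep the instance depot; model 2 relocates it to Hamar or,
    with ``use_gfa``, to the demand-weighted geometric median of the centers.
    Customer groups are split at the median center-DC road distance, capped
    at half the group-1 vehicle's range so that every group-1 customer is
    individually reachable by its (possibly short-range electric) vehicle.
    """
    inst = copy.deepcopy(instance)
    if model_id == 2:
        if use_gfa:
            weights = [instance.demand.by_center().get(c.id, 0) or c.population_18plus
                       for c in inst.centers]
            lat, lon = greenfield_location(inst.centers, weights)
            name = "DC-greenfield"
        else:
            lat, lon = HAMAR
            name = "DC-Hamar"
        inst.locations[0] = replace(inst.locations[0], name=name, lat=lat, lon=lon)
        inst.distances = build_distance_matrix(inst.locations, inst.circuity)

    mapping = assign_vehicle_types(inst.vehicle_catalogue, model_id)
    g1_range = inst.vehicle(mapping[1]).range_km
    centers = inst.centers
    road = [inst.distances[0, c.id] for c in centers]
    threshold = min(float(np.median(road)), g1_range / 2.0) if road else 0.0
    assign_customer_groups(inst.locations, inst.locations[0],
                           threshold_km=threshold / inst.circuity, circuity=inst.circuity)
    return inst


def plan_model(
    instance: Instance,
    model_id: int,
    mode: str = "auto",
    stop_limit: int = 10,
    capacity_mode: str = "unit_stop_limit",
    use_gfa: bool = False,
) -> tuple[RoutePlan, Instance]:
    """Stage 1 for a network model: per-group CVRP with the assigned type."""
    inst = build_model_instance(instance, model_id, use_gfa=use_gfa)
    mapping = assign_vehicle_types(inst.vehicle_catalogue, model_id)
    demands = route_demands(inst) if capacity_mode == "volume" else None

    routes: list[Route] = []
    objective = 0.0
    tags: list[str] = []
    for group in sorted({c.group for c in inst.centers}):
        members = [c.id for c in inst.centers if c.group == group]
        if not members:
            continue
        cfg = CVRPConfig(
            capacity_mode=capacity_mode,
            stop_limit=stop_limit,
            customers=members,
            vehicle_types=[inst.vehicle(mapping[group])],
            demands=demands,
            doses_per_m3=inst.doses_per_m3,
        )
        if mode == "exact":
            sub = solve_cvrp_exact(inst, cfg)
        elif mode == "heuristic":
            sub = solve_cvrp_heuristic(inst, cfg)
        elif mode == "auto":
            try:
                sub = solve_cvrp_exact(inst, cfg)
            except ExactSizeError:
                sub = solve_cvrp_heuristic(inst, cfg)
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        violations = validate_route_plan(sub, inst, cfg)
        if violations:  # pragma: no cover - solver contract
            raise AssertionError(f"stage-1 plan invalid for group {group}: {violations}")
        routes.extend(sub.routes)
        objective += sub.objective_nok_km
        tags.append(sub.optimality_tag)
    tag = "exact" if tags and all(t == "exact" for t in tags) else "heuristic"
    return RoutePlan(routes=routes, objective_nok_km=objective, optimality_tag=tag), inst


# ---------------------------------------------------------------------------
# seed derivation
# ---------------------------------------------------------------------------

def replication_seed(base_seed: int, scenario_id: int, rep: int, paired: bool) -> int:
    """Deterministic per-replication seed.

    Paired mode omits the scenario id so that all scenarios of a comparison
    share one common-random-number stream.
    """
    entropy = [base_seed, rep] if paired else [base_seed, scenario_id, rep]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_two_stage(
    instance: Instance,
    scenario: Scenario,
    n_reps: int = 30,
    base_seed: int = 0,
    mode: str = "auto",
    paired: bool = False,
    stop_limit: int = 10,
    plan_cache: dict | None = None,
) -> TwoStageResult:
    """Stage-1 plan + stage-2 Monte-Carlo summary for one scenario."""
    cache_key = (scenario.model_id, scenario.use_gfa, mode, stop_limit)
    if plan_cache is not None and cache_key in plan_cache:
        plan, inst = plan_cache[cache_key]
    else:
        plan, inst = plan_model(instance, scenario.model_id, mode=mode,
                                stop_limit=stop_limit, use_gfa=scenario.use_gfa)
        if plan_cache is not None:
            plan_cache[cache_key] = (plan, inst)

    cfg = SimConfig(fleet=dict(scenario.fleet), elt_days=scenario.elt_days,
                    **scenario.sim_overrides)
    elt_by_center = {c.id: scenario.elt_days[c.group] for c in inst.centers if c.group is not None}

    reports: list[KPIReport] = []
    sls: list[float] = []
    for r in range(n_reps):
        seed = replication_seed(base_seed, scenario.id, r, paired)
        log = run_replication(inst, plan, cfg, seed)
        rep = compute_report(log, inst.vehicle_catalogue, elt_by_center, tag=f"rep={r}")
        reports.append(rep)
        sls.append(rep.elt_service_level)
    summary = aggregate_replications(reports, base_seed=base_seed)
    return TwoStageResult(scenario=scenario, plan=plan, summary=summary,
                          reports=reports, per_rep_service_level=sls)


def _fleet_nested(a: dict[str, int], b: dict[str, int]) -> bool:
    keys = set(a) | set(b)
    return all(a.get(k, 0) <= b.get(k, 0) for k in keys)


def compare_scenarios(
    instance: Instance,
    scenarios: list[Scenario],
    n_reps: int = 30,
    base_seed: int = 0,
    paired: bool = True,
    mode: str = "auto",
) -> tuple[ComparisonReport, dict[int, TwoStageResult]]:
    """Sweep scenarios on one instance; pairwise deltas of summarized means.

    With ``paired`` the same seed stream drives every scenario (common random
    numbers); the report then includes, for each nested-fleet pair within a
    model, whether the service level was non-decreasing in fleet size.
    """
    if len(scenarios) < 2:
        raise ValidationError("need at least 2 scenarios to compare")
    refs = {s.instance_ref for s in scenarios}
    if len(refs) > 1:
        raise ValidationError(f"scenarios reference different instances: {sorted(map(str, refs))}")

    plan_cache: dict = {}
    results: dict[int, TwoStageResult] = {}
    for s in scenarios:
        results[s.id] = run_two_stage(instance, s, n_reps=n_reps, base_seed=base_seed,
                                      mode=mode, paired=paired, plan_cache=plan_cache)

    deltas: dict[tuple[int, int], dict[str, float]] = {}
    nested: dict[tuple[int, int], bool] = {}
    ids = [s.id for s in scenarios]
    by_id = {s.id: s for s in scenarios}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ma, mb = results[a].summary.mean, results[b].summary.mean
            deltas[(a, b)] = {k: mb[k] - ma[k] for k in ma}
            sa, sb = by_id[a], by_id[b]
            if paired and sa.model_id == sb.model_id and _fleet_nested(sa.fleet, sb.fleet):
                pairs = zip(results[a].per_rep_service_level, results[b].per_rep_service_level)
                nested[(a, b)] = all(slb >= sla - 1e-12 for sla, slb in pairs)
    report = ComparisonReport(
        summaries={sid: results[sid].summary for sid in ids},
        deltas=deltas,
        nested_monotonic=nested,
        paired=paired,
    )
    return report, results


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def write_kpi_csv(result: TwoStageResult, path: str | Path) -> None:
    """One row per replication plus an aggregate row, Table-5-style columns."""
    path = Path(path)
    cols = ["scenario", "replication", "fleet_size", "cost_nok", "co2_g",
            "elt_service_level", "mean_lead_time_days", "max_lead_time_days"]
    fleet_size = sum(result.scenario.fleet.values())
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for i, r in enumerate(result.reports):
            w.writerow([result.scenario.id, i, fleet_size,
                        f"{r.total_cost_nok:.2f}", f"{r.total_co2_g:.2f}",
                        f"{r.elt_service_level:.6f}", f"{r.mean_lead_time_days:.6f}",
                        f"{r.max_lead_time_days:.6f}"])
        m = result.summary.mean
        w.writerow([result.scenario.id, "mean", fleet_size,
                    f"{m['total_cost_nok']:.2f}", f"{m['total_co2_g']:.2f}",
                    f"{m['elt_service_level']:.6f}", f"{m['mean_lead_time_days']:.6f}",
                    f"{m['max_lead_time_days']:.6f}"])


def write_comparison_csv(report: ComparisonReport, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        header = ["scenario", "n"] + [f"{k}_{s}" for k in next(iter(report.summaries.values())).mean
                                      for s in ("mean", "sd", "hw")]
        w.writerow(header)
        for sid, summary in report.summaries.items():
            row = summary_row(summary)
            w.writerow([sid, summary.n] + [
                f"{row[f'{k}_{s}']:.6f}" for k in summary.mean for s in ("mean", "sd", "hw")
            ])
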