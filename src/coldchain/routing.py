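"""Stage 1: heterogeneous-fleet capacitated vehicle routing.

Routes are depot-anchored milk runs.  Two capacity readings are supported:

* ``unit_stop_limit`` — every stop counts 1 against a per-tour stop budget
  (default 10), the operational choice for responsiveness;
* ``volume`` — per-center dose demands are checked against the vehicle's
  dose capacity.

The exact solver is a set-partitioning dynamic program over customer subsets
with Held–Karp optimal tours per subset; it is provably optimal for the
default size ceiling (15 customers) and handles heterogeneous vehicle types
by pricing each candidate tour with the cheapest feasible type.  The
heuristic is Clarke–Wright savings construction followed by 2-opt and
inter-route relocation.  A Weiszfeld geometric-median routine locates a
greenfield DC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .instance import (
    EARTH_RADIUS_KM,
    Instance,
    Location,
    ValidationError,
    VehicleType,
    capacity_in_doses,
)


class InfeasibleError(Exception):
    """No feasible route plan exists; names the offending customer."""

    def __init__(self, message: str, customers: list[int] | None = None):
        super().__init__(message)
        self.customers = customers or []


class ExactSizeError(Exception):
    """Instance exceeds the exact-mode ceiling; use the heuristic solver."""


@dataclass
class Route:
    """One milk run: depot -> stops -> depot with an assigned vehicle type."""

    vehicle_type: str
    stops: list[int]
    length_km: float

    def arcs(self) -> list[tuple[int, int]]:
        path = [0, *self.stops, 0]
        return list(zip(path[:-1], path[1:]))


@dataclass
class RoutePlan:
    routes: list[Route]
    objective_nok_km: float
    optimality_tag: str  # "exact" | "heuristic"

    def total_distance_km(self) -> float:
        return sum(r.length_km for r in self.routes)


@dataclass
class CVRPConfig:
    """Solver configuration.

    ``customers`` restricts planning to a subset of center ids (default: all
    centers of the instance).  ``vehicle_types`` lists the types available to
    the planner; counts do not bound routes in stage 1 (a physical vehicle
    may run several tours), so any number of routes per type is allowed.
    ``demands`` supplies per-center doses for volume mode; when omitted the
    caller should derive them from the instance (see :func:`route_demands`).
    """

    capacity_mode: str = "unit_stop_limit"  # or "volume"
    stop_limit: int = 10
    customers: list[int] | None = None
    vehicle_types: list[VehicleType] = field(default_factory=list)
    demands: dict[int, int] | None = None
    doses_per_m3: int = 600
    exact_ceiling: int = 15

    def __post_init__(self) -> None:
        if self.stop_limit < 1:
            raise ValidationError("stop_limit must be >= 1")
        if self.capacity_mode not in ("unit_stop_limit", "volume"):
            raise ValidationError(f"unknown capacity_mode {self.capacity_mode!r}")


@dataclass(frozen=True)
class SubtourCut:
    """A set of customers forming a depot-disconnected component."""

    W: frozenset[int]

    def __post_init__(self) -> None:
        if 0 in self.W:
            raise ValidationError("subtour cut may not contain the depot")
        if len(self.W) < 2:
            raise ValidationError("subtour cut needs at least 2 customers")


def route_demands(instance: Instance, agg: str = "max") -> dict[int, int]:
    """Per-center doses for volume-mode planning: max (default) or mean week."""
    totals: dict[int, list[int]] = {}
    for e in instance.demand.entries:
        totals.setdefault(e.center_id, []).append(e.doses)
    if agg == "max":
        return {c: max(v) for c, v in totals.items()}
    if agg == "mean":
        return {c: int(math.ceil(sum(v) / len(v))) for c, v in totals.items()}
    raise ValidationError(f"unknown demand aggregation {agg!r}")


# ---------------------------------------------------------------------------
# shared feasibility / costing helpers
# ---------------------------------------------------------------------------

def _resolve_customers(instance: Instance, cfg: CVRPConfig) -> list[int]:
    customers = cfg.customers if cfg.customers is not None else [c.id for c in instance.centers]
    customers = sorted(customers)
    known = {loc.id for loc in instance.locations}
    for c in customers:
        if c not in known or c == 0:
            raise ValidationError(f"customer id {c} is not a center of the instance")
    return customers


def _load_of(stops: list[int], cfg: CVRPConfig) -> int:
    if cfg.capacity_mode != "volume":
        return 0
    demands = cfg.demands or {}
    return sum(demands.get(s, 0) for s in stops)


def _tour_length(stops: list[int], d: np.ndarray) -> float:
    path = [0, *stops, 0]
    return float(sum(d[a, b] for a, b in zip(path[:-1], path[1:])))


def _cheapest_type(length: float, load: int, n_stops: int, cfg: CVRPConfig) -> tuple[float, str] | None:
    """(cost, type name) of the cheapest vehicle type able to run this tour."""
    if n_stops > cfg.stop_limit:
        return None
    best: tuple[float, int, str] | None = None
    for idx, vt in enumerate(cfg.vehicle_types):
        if length > vt.range_km + 1e-9:
            continue
        if cfg.capacity_mode == "volume" and load > capacity_in_doses(vt, cfg.doses_per_m3):
            continue
        cand = (vt.var_cost_per_km * length, idx, vt.name)
        if best is None or (round(cand[0], 9), cand[1]) < (round(best[0], 9), best[1]):
            best = cand
    if best is None:
        return None
    return best[0], best[2]


def _check_individual_feasibility(customers: list[int], d: np.ndarray, cfg: CVRPConfig) -> None:
    bad = []
    for c in customers:
        length = d[0, c] + d[c, 0]
        if _cheapest_type(length, _load_of([c], cfg), 1, cfg) is None:
            bad.append(c)
    if bad:
        raise InfeasibleError(
            f"customer(s) {bad} cannot be served by any available vehicle type "
            "(round-trip beyond range or demand beyond capacity)",
            customers=bad,
        )


def _canonical_stops(stops: tuple[int, ...]) -> tuple[int, ...]:
    rev = tuple(reversed(stops))
    return stops if stops <= rev else rev


def _plan_repr(routes: list[tuple[float, str, tuple[int, ...]]]) -> tuple:
    return tuple(sorted(_canonical_stops(s) for _, _, s in routes))


# ---------------------------------------------------------------------------
# exact solver: Held–Karp tours + set-partitioning DP
# ---------------------------------------------------------------------------

def solve_cvrp_exact(instance: Instance, cfg: CVRPConfig) -> RoutePlan:
    """Provably optimal plan minimizing sum of c_k * d_ij over chosen arcs.

    Raises :class:`ExactSizeError` above ``cfg.exact_ceiling`` customers and
    :class:`InfeasibleError` when some customer cannot be served at all.
    Among equal-cost optima the lexicographically smallest canonical route
    set is returned.
    """
    if not cfg.vehicle_types:
        raise ValidationError("no vehicle types available")
    customers = _resolve_customers(instance, cfg)
    n = len(customers)
    if n == 0:
        return RoutePlan(routes=[], objective_nok_km=0.0, optimality_tag="exact")
    if n > cfg.exact_ceiling:
        raise ExactSizeError(
            f"{n} customers exceed the exact-mode ceiling of {cfg.exact_ceiling}; "
            "use solve_cvrp_heuristic"
        )
    d = instance.distances.d
    _check_individual_feasibility(customers, d, cfg)

    node = {i: customers[i] for i in range(n)}  # bit index -> node id

    # Held–Karp over subsets of size <= stop_limit:
    # hk[(mask, last)] = (path length depot->...->last, path tuple of bit idx)
    hk: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
    by_popcount: dict[int, list[int]] = {}
    for mask in range(1, 1 << n):
        pc = mask.bit_count()
        if pc <= cfg.stop_limit:
            by_popcount.setdefault(pc, []).append(mask)
    for i in range(n):
        hk[(1 << i, i)] = (float(d[0, node[i]]), (i,))
    for pc in range(2, cfg.stop_limit + 1):
        for mask in by_popcount.get(pc, []):
            m = mask
            while m:
                last_bit = m & (-m)
                last = last_bit.bit_length() - 1
                m ^= last_bit
                prev_mask = mask ^ last_bit
                best: tuple[float, tuple[int, ...]] | None = None
                pm = prev_mask
                while pm:
                    pbit = pm & (-pm)
                    p = pbit.bit_length() - 1
                    pm ^= pbit
                    entry = hk.get((prev_mask, p))
                    if entry is None:
                        continue
                    cand = (entry[0] + float(d[node[p], node[last]]), entry[1] + (last,))
                    if best is None or (round(cand[0], 9), cand[1]) < (round(best[0], 9), best[1]):
                        best = cand
                if best is not None:
                    hk[(mask, last)] = best

    # best single tour per subset, priced with the cheapest feasible type
    tours: dict[int, tuple[float, str, tuple[int, ...], float]] = {}  # mask -> (cost, type, stops, length)
    for pc, masks in by_popcount.items():
        for mask in masks:
            best_tour: tuple[float, tuple[int, ...]] | None = None
            m = mask
            while m:
                bit = m & (-m)
                last = bit.bit_length() - 1
                m ^= bit
                entry = hk.get((mask, last))
                if entry is None:
                    continue
                cand = (entry[0] + float(d[node[last], 0]), entry[1])
                if best_tour is None or (round(cand[0], 9), cand[1]) < (round(best_tour[0], 9), best_tour[1]):
                    best_tour = cand
            if best_tour is None:
                continue
            length, path = best_tour
            load = _load_of([node[i] for i in path], cfg)
            priced = _cheapest_type(length, load, pc, cfg)
            if priced is not None:
                stops = tuple(node[i] for i in path)
                tours[mask] = (priced[0], priced[1], stops, length)

    # set-partitioning DP over customer bitmasks
    full = (1 << n) - 1
    INF = float("inf")
    best_cost = [INF] * (full + 1)
    best_routes: list[list[tuple[float, str, tuple[int, ...]]] | None] = [None] * (full + 1)
    best_cost[0] = 0.0
    best_routes[0] = []
    for mask in range(1, full + 1):
        low = mask & (-mask)
        sub = mask
        while sub:
            if sub & low:
                tour = tours.get(sub)
                if tour is not None:
                    rest = mask ^ sub
                    if best_routes[rest] is not None:
                        cost = best_cost[rest] + tour[0]
                        cand_routes = best_routes[rest] + [(tour[0], tour[1], tour[2])]
                        cur = best_cost[mask]
                        if round(cost, 9) < round(cur, 9) or (
                            round(cost, 9) == round(cur, 9)
                            and best_routes[mask] is not None
                            and _plan_repr(cand_routes) < _plan_repr(best_routes[mask])
                        ):
                            best_cost[mask] = cost
                            best_routes[mask] = cand_routes
            sub = (sub - 1) & mask

    if best_routes[full] is None:
        raise InfeasibleError("no feasible partition of customers into tours exists")
    lengths = {tuple(s): tours[sum(1 << i for i in range(n) if node[i] in s)][3]
               for _, _, s in best_routes[full]}
    routes = [
        Route(vehicle_type=t, stops=list(s), length_km=lengths[tuple(s)])
        for _, t, s in sorted(best_routes[full], key=lambda r: _canonical_stops(r[2]))
    ]
    return RoutePlan(routes=routes, objective_nok_km=float(best_cost[full]), optimality_tag="exact")


# ---------------------------------------------------------------------------
# subtour separation
# ---------------------------------------------------------------------------

def separate_subtours(arcs) -> list[SubtourCut]:
    """Find depot-disconnected components in an integer arc solution.

    ``arcs`` is an iterable of (i, j) pairs (a dict of arc -> value accepts
    values > 0.5 as selected).  Returns one cut per connected component that
    does not reach the depot; empty list iff every route reaches node 0.
    """
    if isinstance(arcs, dict):
        arc_list = [ij for ij, v in arcs.items() if v > 0.5]
    else:
        arc_list = list(arcs)
    adj: dict[int, set[int]] = {}
    for i, j in arc_list:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    if not adj:
        return []
    # BFS from the depot, then from every still-unvisited node
    seen: set[int] = set()

    def bfs(start: int) -> set[int]:
        comp = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v not in comp:
                        comp.add(v)
                        nxt.append(v)
            frontier = nxt
        return comp

    if 0 in adj:
        seen |= bfs(0)
    cuts = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp = bfs(start)
        seen |= comp
        cuts.append(SubtourCut(W=frozenset(comp)))
    return cuts


# ---------------------------------------------------------------------------
# heuristic solver: Clarke–Wright + 2-opt + relocate
# ---------------------------------------------------------------------------

def _route_cost(stops: list[int], d: np.ndarray, cfg: CVRPConfig) -> tuple[float, str, float] | None:
    """(cost, type, length) for a stop sequence, or None if infeasible."""
    length = _tour_length(stops, d)
    priced = _cheapest_type(length, _load_of(stops, cfg), len(stops), cfg)
    if priced is None:
        return None
    return priced[0], priced[1], length


def _two_opt(stops: list[int], d: np.ndarray) -> list[int]:
    """First-improvement 2-opt on one tour until no improving move remains."""
    improved = True
    stops = list(stops)
    while improved:
        improved = False
        path = [0, *stops, 0]
        n = len(path)
        for a in range(n - 3):
            for b in range(a + 2, n - 1):
                delta = (d[path[a], path[b]] + d[path[a + 1], path[b + 1]]
                         - d[path[a], path[a + 1]] - d[path[b], path[b + 1]])
                if delta < -1e-9:
                    path[a + 1:b + 1] = reversed(path[a + 1:b + 1])
                    improved = True
        stops = path[1:-1]
    return stops


def solve_cvrp_heuristic(instance: Instance, cfg: CVRPConfig) -> RoutePlan:
    """Clarke–Wright savings construction, then 2-opt and inter-route
    relocation until no strict improvement.  Deterministic for a given
    instance; always returns a feasible plan or raises
    :class:`InfeasibleError`.
    """
    if not cfg.vehicle_types:
        raise ValidationError("no vehicle types available")
    customers = _resolve_customers(instance, cfg)
    d = instance.distances.d
    if not customers:
        return RoutePlan(routes=[], objective_nok_km=0.0, optimality_tag="heuristic")
    _check_individual_feasibility(customers, d, cfg)

    routes: list[list[int]] = [[c] for c in customers]
    route_of = {c: i for i, c in enumerate(customers)}

    savings = []
    for ai, i in enumerate(customers):
        for j in customers[ai + 1:]:
            savings.append((d[0, i] + d[0, j] - d[i, j], i, j))
    savings.sort(key=lambda s: (-round(s[0], 9), s[1], s[2]))

    for _, i, j in savings:
        ri, rj = route_of[i], route_of[j]
        if ri == rj:
            continue
        a, b = routes[ri], routes[rj]
        # connect an end of a to an end of b so that i and j become adjacent
        if a[-1] == i and b[0] == j:
            merged = a + b
        elif a[0] == i and b[-1] == j:
            merged = b + a
        elif a[-1] == i and b[-1] == j:
            merged = a + b[::-1]
        elif a[0] == i and b[0] == j:
            merged = a[::-1] + b
        else:
            continue
        if _route_cost(merged, d, cfg) is None:
            continue
        routes[ri] = merged
        routes[rj] = []
        for c in merged:
            route_of[c] = ri
    routes = [r for r in routes if r]

    # local improvement: intra-route 2-opt + inter-route relocate
    routes = [_two_opt(r, d) for r in routes]
    improved = True
    guard = 0
    while improved and guard < 200:
        improved = False
        guard += 1
        for src_idx in range(len(routes)):
            src = routes[src_idx]
            for c in list(src):
                base_src = _route_cost(src, d, cfg)
                removed = [s for s in src if s != c]
                cost_removed = _route_cost(removed, d, cfg)[0] if removed else 0.0
                for dst_idx in range(len(routes)):
                    if dst_idx == src_idx:
                        continue
                    dst = routes[dst_idx]
                    base_dst = _route_cost(dst, d, cfg)
                    best_insert = None
                    for pos in range(len(dst) + 1):
                        cand = dst[:pos] + [c] + dst[pos:]
                        rc = _route_cost(cand, d, cfg)
                        if rc is None:
                            continue
                        if best_insert is None or round(rc[0], 9) < round(best_insert[0][0], 9):
                            best_insert = (rc, cand)
                    if best_insert is None:
                        continue
                    delta = (cost_removed + best_insert[0][0]) - (base_src[0] + base_dst[0])
                    if delta < -1e-9:
                        routes[dst_idx] = best_insert[1]
                        routes[src_idx] = removed
                        src = routes[src_idx]
                        improved = True
                        break
                if improved:
                    break
            if improved:
                break
        if improved:
            routes = [_two_opt(r, d) for r in routes if r]

    routes = [r for r in routes if r]
    priced_routes = []
    for r in routes:
        rc = _route_cost(r, d, cfg)
        assert rc is not None  # construction preserves feasibility
        priced_routes.append((rc[0], rc[1], tuple(r), rc[2]))
    priced_routes.sort(key=lambda pr: _canonical_stops(pr[2]))
    plan = RoutePlan(
        routes=[Route(vehicle_type=t, stops=list(s), length_km=ln) for _, t, s, ln in priced_routes],
        objective_nok_km=float(sum(c for c, _, _, _ in priced_routes)),
        optimality_tag="heuristic",
    )
    return plan


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_route_plan(plan: RoutePlan, instance: Instance, cfg: CVRPConfig) -> list[str]:
    """Return a list of constraint violations (empty iff the plan is valid)."""
    violations: list[str] = []
    d = instance.distances.d
    customers = set(_resolve_customers(instance, cfg))
    types = {v.name: v for v in cfg.vehicle_types} or {v.name: v for v in instance.vehicle_catalogue}

    counts: dict[int, int] = {}
    all_arcs: list[tuple[int, int]] = []
    for r_idx, route in enumerate(plan.routes):
        if not route.stops:
            violations.append(f"route {r_idx}: empty stop list")
            continue
        if 0 in route.stops:
            violations.append(f"route {r_idx}: depot among stops")
        if len(set(route.stops)) != len(route.stops):
            violations.append(f"route {r_idx}: repeated stop")
        for s in route.stops:
            counts[s] = counts.get(s, 0) + 1
        if len(route.stops) > cfg.stop_limit:
            violations.append(
                f"route {r_idx}: {len(route.stops)} stops exceed stop limit {cfg.stop_limit}"
            )
        vt = types.get(route.vehicle_type)
        if vt is None:
            violations.append(f"route {r_idx}: unknown vehicle type {route.vehicle_type!r}")
        recomputed = _tour_length(route.stops, d)
        if abs(recomputed - route.length_km) > 1e-6:
            violations.append(
                f"route {r_idx}: stored length {route.length_km:.6f} km != recomputed {recomputed:.6f} km"
            )
        if vt is not None and recomputed > vt.range_km + 1e-9:
            violations.append(
                f"route {r_idx} ({vt.name}): length {recomputed:.3f} km exceeds range {vt.range_km:g} km"
            )
        if vt is not None and cfg.capacity_mode == "volume":
            load = _load_of(route.stops, cfg)
            cap = capacity_in_doses(vt, cfg.doses_per_m3)
            if load > cap:
                violations.append(
                    f"route {r_idx} ({vt.name}): load {load} doses exceeds capacity {cap}"
                )
        all_arcs.extend(route.arcs())

    for c in sorted(customers):
        if counts.get(c, 0) != 1:
            violations.append(f"customer {c} multiplicity {counts.get(c, 0)}")
    for c in sorted(set(counts) - customers):
        violations.append(f"unexpected customer {c} in plan")

    for cut in separate_subtours(all_arcs):
        violations.append(f"subtour over customers {sorted(cut.W)}")
    return violations


# ---------------------------------------------------------------------------
# greenfield (center-of-gravity) location
# ---------------------------------------------------------------------------

def greenfield_location(
    customers: list[Location],
    weights,
    tol_km: float = 1e-3,
    max_iter: int = 10_000,
    return_trace: bool = False,
):
    """Weighted geometric median of customer coordinates (Weiszfeld).

    Coordinates are projected onto a local tangent plane around the weighted
    centroid; iteration stops when the move is below ``tol_km`` (1 m).
    Returns ``(lat, lon)``, or ``((lat, lon), objective_trace)`` when
    ``return_trace`` is set.
    """
    if not customers:
        raise ValidationError("at least one customer required")
    w = np.asarray(list(weights), dtype=float)
    if len(w) != len(customers) or np.any(w < 0):
        raise ValidationError("weights must be non-negative, one per customer")
    if not np.any(w > 0):
        raise ValidationError("weights must not all be zero")
    if len(customers) == 1:
        result = (customers[0].lat, customers[0].lon)
        return (result, [0.0]) if return_trace else result

    lats = np.array([c.lat for c in customers])
    lons = np.array([c.lon for c in customers])
    lat0 = float(np.average(lats, weights=w))
    lon0 = float(np.average(lons, weights=w))
    coslat = math.cos(math.radians(lat0))
    x = EARTH_RADIUS_KM * np.radians(lons - lon0) * coslat
    y = EARTH_RADIUS_KM * np.radians(lats - lat0)
    pts = np.column_stack([x, y])

    cur = np.average(pts, axis=0, weights=w)
    trace = []
    eps = 1e-12
    for _ in range(max_iter):
        dist = np.sqrt(((pts - cur) ** 2).sum(axis=1))
        trace.append(float(np.sum(w * dist)))
        inv = w / np.maximum(dist, eps)
        nxt = (pts * inv[:, None]).sum(axis=0) / inv.sum()
        move = float(np.linalg.norm(nxt - cur))
        cur = nxt
        if move < tol_km:
            break
    dist = np.sqrt(((pts - cur) ** 2).sum(axis=1))
    trace.append(float(np.sum(w * dist)))

    lat = lat0 + math.degrees(cur[1] / EARTH_RADIUS_KM)
    lon = lon0 + math.degrees(cur[0] / (EARTH_RADIUS_KM * coslat))
    result = (lat, lon)
    return (result, trace) if return_trace else result


# ---------------------------------------------------------------------------
# per-model vehicle assignment
# ---------------------------------------------------------------------------

_MODEL_VEHICLES = {
    1: {1: "e-NV200", 2: "NV200"},
    2: {1: "e-NV200", 2: "NV200"},
    3: {1: "NV200", 2: "VW Transporter"},
}


def assign_vehicle_types(
    catalogue: list[VehicleType],
    model_id: int,
    override: dict[int, str] | None = None,
) -> dict[int, str]:
    """Customer-group -> vehicle-type-name map for a network model (1-3)."""
    names = {v.name for v in catalogue}
    if override is not None:
        for g, name in override.items():
            if name not in names:
                raise ValidationError(f"override for group {g}: unknown vehicle type {name!r}")
        return dict(override)
    if model_id not in _MODEL_VEHICLES:
        raise ValidationError(f"unknown model id {model_id}; expected 1, 2 or 3")
    mapping = dict(_MODEL_VEHICLES[model_id])
    for g, name in mapping.items():
        if name not in names:
            raise ValidationError(f"model {model_id} requires vehicle type {name!r} not in catalogue")
    return mapping


# ---------------------------------------------------------------------------
# plan serialization
# ---------------------------------------------------------------------------

def plan_to_dict(plan: RoutePlan) -> dict:
    return {
        "optimality_tag": plan.optimality_tag,
        "objective_nok_km": plan.objective_nok_km,
        "routes": [
            {"vehicle_type": r.vehicle_type, "stops": r.stops, "length_km": r.length_km}
            for r in plan.routes
        ],
    }


def plan_from_dict(payload: dict) -> RoutePlan:
    return RoutePlan(
        routes=[Route(r["vehicle_type"], list(r["stops"]), float(r["length_km"]))
                for r in payload["routes"]],
        objective_nok_km=float(payload["objective_nok_km"]),
        optimality_tag=payload["optimality_tag"],
    )


def write_plan(plan: RoutePlan, path: str | Path, instance: Instance | None = None) -> None:
    """Write a plan as JSON; with an instance, also a GeoJSON of the tours."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(plan_to_dict(plan), fh, indent=2)
    if instance is not None:
        coords = {loc.id: (loc.lon, loc.lat) for loc in instance.locations}
        features = [
            {
                "type": "Feature",
                "properties": {"vehicle_type": r.vehicle_type, "length_km": r.length_km},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [coords[i] for i in (0, *r.stops, 0)],
                },
            }
            for r in plan.routes
        ]
        geo = {"type": "FeatureCollection", "features": features}
        with open(path.with_suffix(".geojson"), "w", encoding="utf-8") as fh:
            json.dump(geo, fh, indent=2)


def read_plan(path: str | Path) -> RoutePlan:
    with open(path, encoding="utf-8") as fh:
        return plan_from_dict(json.load(fh))
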