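"""Synthetic instance generation.

The real weekly demand table and road network behind the study region are not
publicly available, so this module generates statistically similar stand-ins:
46 municipalities with an adult (18+) population of 301,975 split via a
Dirichlet draw, supply-driven weekly dose totals allocated proportionally to
adult population with a +20% uplift for flagged high-infection municipalities,
and uniform coordinate placement in a bounding box north of the Oslo depot.

:func:`default_fixtures` returns the fixed experiment inputs: the three-vehicle
catalogue, the ten fleet scenarios and default simulation parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .instance import (
    DEFAULT_CIRCUITY,
    DEFAULT_DOSES_PER_M3,
    OSLO,
    DemandEntry,
    DemandSeries,
    Instance,
    Location,
    ValidationError,
    VehicleType,
    build_distance_matrix,
    haversine_km,
)

DEFAULT_BBOX = (60.0, 62.7, 9.5, 12.5)  # lat_min, lat_max, lon_min, lon_max
DEFAULT_HORIZON = (date(2020, 12, 28), date(2021, 3, 15))


@dataclass
class SynthConfig:
    """Parameters of the synthetic instance generator."""

    n_centers: int = 46
    total_population_18plus: int = 301_975
    concentration: float = 1.0          # Dirichlet alpha for population shares
    n_high_infection: int = 5
    uplift_fraction: float = 0.20
    weekly_base_doses: int = 6000
    weekly_growth: float = 0.08
    n_weeks: int = 12
    sigma: float = 0.25                 # lognormal noise on center allocations
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high_infection > self.n_centers:
            raise ValidationError("n_high_infection exceeds n_centers")
        if self.uplift_fraction < 0 or self.sigma < 0:
            raise ValidationError("uplift_fraction and sigma must be >= 0")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValidationError(f"degenerate bounding box {self.bbox}")


def largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative real quotas to integers summing exactly to ``total``.

    Floors every quota, then hands the remaining units to the largest
    fractional remainders (ties broken by lower index).
    """
    targets = np.asarray(targets, dtype=float)
    if len(targets) == 0:
        if total:
            raise ValidationError("cannot allocate a positive total to zero recipients")
        return np.zeros(0, dtype=int)
    if targets.sum() <= 0:
        base = np.full(len(targets), total // len(targets), dtype=int)
        base[: total % len(targets)] += 1
        return base
    scaled = (targets / targets.sum()) * total
    base = np.floor(scaled).astype(int)
    short = total - int(base.sum())
    if short > 0:
        remainders = scaled - base
        order = np.lexsort((np.arange(len(targets)), -remainders))
        base[order[:short]] += 1
    return base


def generate_locations(cfg: SynthConfig) -> list[Location]:
    """One Oslo depot plus ``cfg.n_centers`` centers placed uniformly in the box.

    Population shares come from a symmetric Dirichlet(``concentration``) draw,
    integerized with largest-remainder so they sum exactly to the configured
    total. The ``n_high_infection`` most populous centers are flagged.
    """
    rng = np.random.default_rng(cfg.seed)
    lat_min, lat_max, lon_min, lon_max = cfg.bbox
    lats = rng.uniform(lat_min, lat_max, cfg.n_centers)
    lons = rng.uniform(lon_min, lon_max, cfg.n_centers)
    shares = rng.dirichlet(np.full(cfg.n_centers, cfg.concentration))
    pops = largest_remainder(shares, cfg.total_population_18plus)
    # flag the most populous centers (tie -> lower id)
    order = np.lexsort((np.arange(cfg.n_centers), -pops))
    flagged = set(order[: cfg.n_high_infection].tolist())

    locations = [Location(id=0, name="DC-Oslo", lat=OSLO[0], lon=OSLO[1], role="depot")]
    for i in range(cfg.n_centers):
        locations.append(Location(
            id=i + 1,
            name=f"Center-{i + 1:02d}",
            lat=float(lats[i]),
            lon=float(lons[i]),
            role="center",
            population_18plus=int(pops[i]),
            high_infection=i in flagged,
        ))
    return locations


def allocation_weights(locations: list[Location], uplift_fraction: float) -> np.ndarray:
    """Per-center allocation weight: population x (1 + uplift if flagged)."""
    centers = [loc for loc in locations if loc.role == "center"]
    return np.array([
        loc.population_18plus * (1.0 + (uplift_fraction if loc.high_infection else 0.0))
        for loc in centers
    ])


def generate_demand(cfg: SynthConfig, locations: list[Location]) -> DemandSeries:
    """Weekly supply-driven demand allocation.

    Week ``w`` distributes ``round(base * (1+growth)^w)`` doses across centers
    proportionally to uplifted population weights, perturbed by multiplicative
    lognormal noise, and integerized with largest-remainder so the weekly
    total is conserved exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    centers = [loc for loc in locations if loc.role == "center"]
    weights = allocation_weights(locations, cfg.uplift_fraction)
    entries: list[DemandEntry] = []
    for w in range(cfg.n_weeks):
        total = int(round(cfg.weekly_base_doses * (1.0 + cfg.weekly_growth) ** w))
        noise = rng.lognormal(mean=0.0, sigma=cfg.sigma, size=len(centers)) if cfg.sigma > 0 else np.ones(len(centers))
        doses = largest_remainder(weights * noise, total)
        for loc, q in zip(centers, doses):
            entries.append(DemandEntry(week=w, center_id=loc.id, doses=int(q)))
    return DemandSeries(entries=entries)


def assign_customer_groups(
    locations: list[Location],
    dc: Location,
    threshold_km: float | None = None,
    circuity: float = 1.0,
) -> dict[int, int]:
    """Partition centers into near (1) / far (2) groups by distance to the DC.

    ``threshold_km`` is compared against geodesic-times-circuity distance;
    when omitted it defaults to the median center-DC distance. Labels are
    written back onto the Location objects and returned as an id->group map.
    """
    centers = [loc for loc in locations if loc.role == "center"]
    dists = {loc.id: haversine_km(loc, dc) * circuity for loc in centers}
    if threshold_km is None:
        threshold_km = float(np.median(list(dists.values()))) if dists else 0.0
    groups: dict[int, int] = {}
    for loc in centers:
        loc.group = 1 if dists[loc.id] <= threshold_km else 2
        groups[loc.id] = loc.group
    return groups


# ---------------------------------------------------------------------------
# fixed experiment inputs
# ---------------------------------------------------------------------------

E_NV200 = "e-NV200"
NV200 = "NV200"
VW_TRANSPORTER = "VW Transporter"

_SPEED = (40.0, 50.0, 70.0)  # triangular min/mode/max, km/h


def vehicle_catalogue() -> list[VehicleType]:
    """The three-vehicle catalogue used throughout the experiments."""
    return [
        VehicleType(E_NV200, capacity_m3=2.1, range_km=300.0, speed_kmh=_SPEED,
                    var_cost_per_km=6.0, fixed_cost=1500.0, emission_g_per_km=0.0),
        VehicleType(NV200, capacity_m3=2.1, range_km=1000.0, speed_kmh=_SPEED,
                    var_cost_per_km=8.0, fixed_cost=1500.0, emission_g_per_km=131.0),
        VehicleType(VW_TRANSPORTER, capacity_m3=6.7, range_km=1000.0, speed_kmh=_SPEED,
                    var_cost_per_km=10.0, fixed_cost=1500.0, emission_g_per_km=159.0),
    ]


@dataclass(frozen=True)
class ScenarioFixture:
    id: int
    model_id: int
    fleet: dict[str, int] = field(hash=False)


def scenario_table() -> list[ScenarioFixture]:
    """The ten fleet-size/composition scenarios over network models 1-3."""
    rows = [
        (1, 1, {E_NV200: 1, NV200: 2}),
        (2, 1, {E_NV200: 3, NV200: 2}),
        (3, 1, {E_NV200: 4, NV200: 2}),
        (4, 2, {E_NV200: 1, NV200: 2}),
        (5, 2, {E_NV200: 3, NV200: 2}),
        (6, 2, {E_NV200: 4, NV200: 2}),
        (7, 2, {E_NV200: 4, NV200: 3}),
        (8, 3, {NV200: 1, VW_TRANSPORTER: 2}),
        (9, 3, {NV200: 2, VW_TRANSPORTER: 3}),
        (10, 3, {NV200: 3, VW_TRANSPORTER: 3}),
    ]
    return [ScenarioFixture(id=i, model_id=m, fleet=f) for i, m, f in rows]


def default_sim_parameters() -> dict:
    """Default stage-2 parameters (processing times, window, horizon, ELTs)."""
    return {
        "horizon": DEFAULT_HORIZON,
        "shipping_window": ("06:00", "15:00"),
        "shipping_days": (0, 1, 2, 3, 4),  # Monday..Friday
        "outbound_minutes": (20.0, 30.0),
        "inbound_minutes": (10.0, 20.0),
        "elt_days": {1: 1.0, 2: 2.0},
        "n_replications": 30,
        "doses_per_m3": DEFAULT_DOSES_PER_M3,
    }


def default_fixtures() -> tuple[list[VehicleType], list[ScenarioFixture], dict]:
    """(vehicle catalogue, scenario list, default simulation parameters)."""
    return vehicle_catalogue(), scenario_table(), default_sim_parameters()


def generate_instance(cfg: SynthConfig | None = None, circuity: float = DEFAULT_CIRCUITY) -> Instance:
    """End-to-end synthetic instance: locations, groups, demand, catalogue."""
    cfg = cfg or SynthConfig()
    locations = generate_locations(cfg)
    assign_customer_groups(locations, locations[0], circuity=circuity)
    demand = generate_demand(cfg, locations)
    return Instance(
        locations=locations,
        demand=demand,
        vehicle_catalogue=vehicle_catalogue(),
        distances=build_distance_matrix(locations, circuity),
        elt_days={1: 1.0, 2: 2.0},
        horizon=DEFAULT_HORIZON,
        doses_per_m3=DEFAULT_DOSES_PER_M3,
        circuity=circuity,
    )
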