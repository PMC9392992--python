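"""Domain types, instance file I/O, distance matrices and unit conversions.

A distribution *instance* bundles everything both pipeline stages need:
locations (one depot + vaccination centers), weekly dose demands, a vehicle
catalogue, a distance matrix, expected-lead-time (ELT) targets per customer
group, the planning horizon and the dose/volume conversion factor.

Road distances are approximated as great-circle distance times a configurable
circuity factor (default 1.3); the construction is recorded in
:attr:`DistanceMatrix.metric_tag`.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

#: doses of vaccine per cubic meter of refrigerated cargo space
DEFAULT_DOSES_PER_M3 = 600

#: multiplier turning great-circle km into approximate road km
DEFAULT_CIRCUITY = 1.3

#: default depot coordinates (Oslo)
OSLO = (59.913, 10.752)
#: default relocated-DC coordinates (Hamar)
HAMAR = (60.794, 11.068)


class ValidationError(ValueError):
    """An instance file or record violates the schema or an invariant."""


@dataclass
class Location:
    """A depot/DC or a vaccination center.

    Node ids are contiguous integers starting at 0; node 0 is the single
    depot.  ``group`` is the customer-group id (1 = near, 2 = far) and is
    ``None`` for the depot or before group assignment.
    """

    id: int
    name: str
    lat: float
    lon: float
    role: str  # "depot" | "center"
    population_18plus: int = 0
    high_infection: bool = False
    group: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("depot", "center"):
            raise ValidationError(f"location {self.id}: unknown role {self.role!r}")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(f"location {self.id}: latitude {self.lat} out of range")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(f"location {self.id}: longitude {self.lon} out of range")
        if self.population_18plus < 0:
            raise ValidationError(f"location {self.id}: negative population")


@dataclass(frozen=True)
class VehicleType:
    """A vehicle model with capacity, range, speed and cost/emission rates.

    ``speed_kmh`` is a ``(min, mode, max)`` triple of a triangular
    distribution in km/h.
    """

    name: str
    capacity_m3: float
    range_km: float
    speed_kmh: tuple[float, float, float]
    var_cost_per_km: float
    fixed_cost: float
    emission_g_per_km: float

    def __post_init__(self) -> None:
        lo, mode, hi = self.speed_kmh
        if not (0 < lo <= mode <= hi):
            raise ValidationError(
                f"vehicle {self.name}: speed triple {self.speed_kmh} must satisfy 0 < min <= mode <= max"
            )
        for attr in ("capacity_m3", "range_km", "var_cost_per_km", "fixed_cost", "emission_g_per_km"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"vehicle {self.name}: {attr} must be >= 0")


@dataclass(frozen=True)
class DemandEntry:
    week: int
    center_id: int
    doses: int


@dataclass
class DemandSeries:
    """Weekly dose demands per center; at most one entry per (week, center)."""

    entries: list[DemandEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.doses < 0:
                raise ValidationError(f"demand week {e.week} center {e.center_id}: negative doses")
            if e.week < 0:
                raise ValidationError(f"demand center {e.center_id}: negative week index {e.week}")
            key = (e.week, e.center_id)
            if key in seen:
                raise ValidationError(f"duplicate demand entry for week {e.week}, center {e.center_id}")
            seen.add(key)

    @property
    def n_weeks(self) -> int:
        return max((e.week for e in self.entries), default=-1) + 1

    def for_week(self, week: int) -> dict[int, int]:
        """Doses per center for one week (centers with zero demand omitted)."""
        return {e.center_id: e.doses for e in self.entries if e.week == week and e.doses > 0}

    def by_center(self) -> dict[int, int]:
        """Total doses per center over the whole horizon."""
        out: dict[int, int] = {}
        for e in self.entries:
            out[e.center_id] = out.get(e.center_id, 0) + e.doses
        return out

    def weekly_totals(self) -> list[int]:
        totals = [0] * self.n_weeks
        for e in self.entries:
            totals[e.week] += e.doses
        return totals


@dataclass
class DistanceMatrix:
    """Symmetric inter-node distance matrix in km with zero diagonal."""

    d: np.ndarray
    metric_tag: str = "geodesic"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValidationError("distances must be non-negative")

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.d[ij])

    def __len__(self) -> int:
        return self.d.shape[0]


@dataclass
class Instance:
    """A full distribution instance shared by both pipeline stages."""

    locations: list[Location]
    demand: DemandSeries
    vehicle_catalogue: list[VehicleType]
    distances: DistanceMatrix
    elt_days: dict[int, float]
    horizon: tuple[date, date]
    doses_per_m3: int = DEFAULT_DOSES_PER_M3
    circuity: float = DEFAULT_CIRCUITY

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [loc.id for loc in self.locations]
        if ids != list(range(len(ids))):
            raise ValidationError("location ids must be contiguous from 0")
        depots = [loc for loc in self.locations if loc.role == "depot"]
        if len(depots) != 1:
            raise ValidationError(f"exactly one depot required, found {len(depots)}")
        if depots[0].id != 0:
            raise ValidationError("the depot must be node 0")
        if len(self.distances) != len(self.locations):
            raise ValidationError("distance matrix size does not match location count")
        known = set(ids)
        for e in self.demand.entries:
            if e.center_id not in known:
                raise ValidationError(f"demand references unknown center id {e.center_id}")
            if e.center_id == 0:
                raise ValidationError("demand may not target the depot (node 0)")
        groups = {loc.group for loc in self.locations if loc.role == "center" and loc.group is not None}
        missing = groups - set(self.elt_days)
        if missing:
            raise ValidationError(f"elt_days missing for group(s) {sorted(missing)}")
        if self.horizon[1] < self.horizon[0]:
            raise ValidationError("horizon end precedes start")
        if self.doses_per_m3 <= 0:
            raise ValidationError("doses_per_m3 must be positive")

    @property
    def depot(self) -> Location:
        return self.locations[0]

    @property
    def centers(self) -> list[Location]:
        return [loc for loc in self.locations if loc.role == "center"]

    def vehicle(self, name: str) -> VehicleType:
        for v in self.vehicle_catalogue:
            if v.name == name:
                return v
        raise KeyError(f"unknown vehicle type {name!r}")


# ---------------------------------------------------------------------------
# distances and conversions
# ---------------------------------------------------------------------------

def haversine_km(a: Location, b: Location) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(la1) * math.cos(la2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def build_distance_matrix(locations: list[Location], circuity: float = DEFAULT_CIRCUITY) -> DistanceMatrix:
    """Pairwise geodesic distances scaled by a road-circuity factor >= 1."""
    if circuity < 1.0:
        raise ValidationError(f"circuity must be >= 1, got {circuity}")
    n = len(locations)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(locations[i], locations[j]) * circuity
    return DistanceMatrix(d=d, metric_tag=f"geodesic x circuity {circuity:g}")


def capacity_in_doses(v: VehicleType, doses_per_m3: int = DEFAULT_DOSES_PER_M3) -> int:
    """Vehicle payload in doses: floor(capacity_m3 * doses_per_m3)."""
    if doses_per_m3 <= 0:
        raise ValidationError("doses_per_m3 must be positive")
    return math.floor(v.capacity_m3 * doses_per_m3)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------
# Layout (all UTF-8 CSV with header rows, plus one JSON manifest):
#   locations.csv  id,name,lat,lon,role,population_18plus,high_infection,group
#   demand.csv     week,center_id,doses
#   vehicles.csv   name,capacity_m3,range_km,speed_min,speed_mode,speed_max,
#                  var_cost_per_km,fixed_cost,emission_g_per_km
#   instance.json  horizon, elt_days, doses_per_m3, circuity, file references

def write_instance(instance: Instance, path: str | Path) -> Path:
    """Write an instance as CSV files + JSON manifest into directory ``path``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    with open(root / "locations.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "lat", "lon", "role", "population_18plus", "high_infection", "group"])
        for loc in instance.locations:
            w.writerow([
                loc.id, loc.name, repr(loc.lat), repr(loc.lon), loc.role,
                loc.population_18plus, int(loc.high_infection),
                "" if loc.group is None else loc.group,
            ])

    with open(root / "demand.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["week", "center_id", "doses"])
        for e in instance.demand.entries:
            w.writerow([e.week, e.center_id, e.doses])

    with open(root / "vehicles.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "capacity_m3", "range_km", "speed_min", "speed_mode", "speed_max",
                    "var_cost_per_km", "fixed_cost", "emission_g_per_km"])
        for v in instance.vehicle_catalogue:
            w.writerow([v.name, repr(v.capacity_m3), repr(v.range_km),
                        repr(v.speed_kmh[0]), repr(v.speed_kmh[1]), repr(v.speed_kmh[2]),
                        repr(v.var_cost_per_km), repr(v.fixed_cost), repr(v.emission_g_per_km)])

    manifest = {
        "horizon": [instance.horizon[0].isoformat(), instance.horizon[1].isoformat()],
        "elt_days": {str(g): d for g, d in instance.elt_days.items()},
        "doses_per_m3": instance.doses_per_m3,
        "circuity": instance.circuity,
        "files": {"locations": "locations.csv", "demand": "demand.csv", "vehicles": "vehicles.csv"},
    }
    with open(root / "instance.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return root


def _parse_row(row: dict, key: str, conv, context: str):
    try:
        return conv(row[key])
    except (KeyError, ValueError, TypeError) as exc:
        raise ValidationError(f"{context}: bad field {key!r}: {row.get(key)!r}") from exc


def read_instance(path: str | Path) -> Instance:
    """Read an instance written by :func:`write_instance`.

    ``path`` may be the directory or the ``instance.json`` manifest inside it.
    The distance matrix is rebuilt deterministically from coordinates and the
    stored circuity factor.
    """
    p = Path(path)
    root = p.parent if p.name.endswith(".json") else p
    manifest_path = root / "instance.json" if not p.name.endswith(".json") else p
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)

    files = manifest.get("files", {})
    locations: list[Location] = []
    with open(root / files.get("locations", "locations.csv"), encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            ctx = f"locations.csv row {i + 1}"
            grp = row.get("group", "")
            locations.append(Location(
                id=_parse_row(row, "id", int, ctx),
                name=_parse_row(row, "name", str, ctx),
                lat=_parse_row(row, "lat", float, ctx),
                lon=_parse_row(row, "lon", float, ctx),
                role=_parse_row(row, "role", str, ctx),
                population_18plus=_parse_row(row, "population_18plus", int, ctx),
                high_infection=bool(_parse_row(row, "high_infection", int, ctx)),
                group=None if grp in ("", None) else int(grp),
            ))

    entries: list[DemandEntry] = []
    with open(root / files.get("demand", "demand.csv"), encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            ctx = f"demand.csv row {i + 1}"
            entries.append(DemandEntry(
                week=_parse_row(row, "week", int, ctx),
                center_id=_parse_row(row, "center_id", int, ctx),
                doses=_parse_row(row, "doses", int, ctx),
            ))

    vehicles: list[VehicleType] = []
    with open(root / files.get("vehicles", "vehicles.csv"), encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            ctx = f"vehicles.csv row {i + 1}"
            vehicles.append(VehicleType(
                name=_parse_row(row, "name", str, ctx),
                capacity_m3=_parse_row(row, "capacity_m3", float, ctx),
                range_km=_parse_row(row, "range_km", float, ctx),
                speed_kmh=(_parse_row(row, "speed_min", float, ctx),
                           _parse_row(row, "speed_mode", float, ctx),
                           _parse_row(row, "speed_max", float, ctx)),
                var_cost_per_km=_parse_row(row, "var_cost_per_km", float, ctx),
                fixed_cost=_parse_row(row, "fixed_cost", float, ctx),
                emission_g_per_km=_parse_row(row, "emission_g_per_km", float, ctx),
            ))

    circuity = float(manifest.get("circuity", DEFAULT_CIRCUITY))
    horizon = (date.fromisoformat(manifest["horizon"][0]), date.fromisoformat(manifest["horizon"][1]))
    return Instance(
        locations=locations,
        demand=DemandSeries(entries=entries),
        vehicle_catalogue=vehicles,
        distances=build_distance_matrix(locations, circuity),
        elt_days={int(g): float(d) for g, d in manifest["elt_days"].items()},
        horizon=horizon,
        doses_per_m3=int(manifest.get("doses_per_m3", DEFAULT_DOSES_PER_M3)),
        circuity=circuity,
    )


def instances_equal(a: Instance, b: Instance) -> bool:
    """Field-by-field equality (distance matrices compared numerically)."""
    if dataclasses.asdict(a)["locations"] != dataclasses.asdict(b)["locations"]:
        return False
    return (
        a.demand == b.demand
        and a.vehicle_catalogue == b.vehicle_catalogue
        and np.allclose(a.distances.d, b.distances.d)
        and a.elt_days == b.elt_days
        and a.horizon == b.horizon
        and a.doses_per_m3 == b.doses_per_m3
        and a.circuity == b.circuity
    )
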