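"""Stage 2: discrete-event execution of a route plan over the horizon.

Weekly order epochs (Monday 00:00) turn demands into orders; orders merge
with any unfilled backlog ("allowed total").  Each planned route is executed
as one or more trips per week — a route is repeated until the backlog of its
stops is cleared, with loads split proportionally using largest-remainder
rounding.  Trips dispatch less-than-truckload at the earliest shipping-window
instant at which a vehicle of the route's type is idle; departure is preceded
by one outbound-processing draw, each leg's travel time uses a fresh
triangular speed draw, and every stop incurs an inbound-processing draw after
which that stop's doses count as delivered.  Departures are constrained to
the Monday–Friday 06:00–15:00 window; a tour in progress always runs to
completion (milk runs cannot pause).

All stochastic durations are rounded to the nearest second; identical
(inputs, seed) produce an identical replication log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np

from .instance import Instance, ValidationError, capacity_in_doses
from .routing import RoutePlan
from .synth import largest_remainder

ONE_DAY = timedelta(days=1)


@dataclass
class SimConfig:
    """Stage-2 operating parameters.

    ``horizon_start``/``horizon_end`` default to the instance horizon.
    ``fleet`` maps vehicle-type name to the number of physical vehicles.
    ``outbound_minutes``/``inbound_minutes`` are Uniform(lo, hi) processing
    times; collapse them to (x, x) for deterministic traces.
    """

    fleet: dict[str, int] = field(default_factory=dict)
    horizon_start: date | None = None
    horizon_end: date | None = None
    window_start: time = time(6, 0)
    window_end: time = time(15, 0)
    shipping_days: tuple[int, ...] = (0, 1, 2, 3, 4)  # Monday..Friday
    order_weekday: int = 0  # Monday
    outbound_minutes: tuple[float, float] = (20.0, 30.0)
    inbound_minutes: tuple[float, float] = (10.0, 20.0)
    turnaround_minutes: float = 30.0
    elt_days: dict[int, float] | None = None  # override of instance.elt_days
    speed_override: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValidationError("shipping window start must precede end")
        for name, count in self.fleet.items():
            if count < 0:
                raise ValidationError(f"fleet count for {name!r} must be >= 0")


@dataclass(frozen=True)
class ShipmentRecord:
    center_id: int
    doses: int
    order_time: datetime
    delivery_time: datetime
    lead_time_days: float
    on_time: bool


@dataclass(frozen=True)
class TripRecord:
    vehicle_type: str
    vehicle_index: int
    stops: tuple[int, ...]
    departure_time: datetime
    return_time: datetime
    distance_km: float
    doses_carried: int


@dataclass
class ReplicationLog:
    shipments: list[ShipmentRecord]
    trips: list[TripRecord]
    undelivered_at_horizon: dict[int, int]
    seed: int

    def delivered_by_center(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.shipments:
            out[s.center_id] = out.get(s.center_id, 0) + s.doses
        return out


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------

def next_shipping_time(t: datetime, cfg: SimConfig) -> datetime:
    """Earliest instant >= t inside the shipping calendar."""
    for _ in range(15):  # at most a handful of days to the next window
        if t.weekday() in cfg.shipping_days:
            if t.time() < cfg.window_start:
                return datetime.combine(t.date(), cfg.window_start)
            if t.time() < cfg.window_end:
                return t
        t = datetime.combine(t.date() + ONE_DAY, time(0, 0))
    raise RuntimeError("no shipping window found within 15 days")  # pragma: no cover


def _window_close(t: datetime, cfg: SimConfig) -> datetime:
    return datetime.combine(t.date(), cfg.window_end)


def first_order_epoch(start: date, cfg: SimConfig) -> datetime:
    d = start
    while d.weekday() != cfg.order_weekday:
        d += ONE_DAY
    return datetime.combine(d, time(0, 0))


# ---------------------------------------------------------------------------
# samplers (inverse-CDF, reproducible from the rng state)
# ---------------------------------------------------------------------------

def sample_triangular(dist: tuple[float, float, float], rng: np.random.Generator) -> float:
    """Inverse-CDF draw from Triangular(min, mode, max)."""
    lo, mode, hi = dist
    if not (lo <= mode <= hi):
        raise ValidationError(f"invalid triangular parameters {dist}")
    u = rng.random()
    if hi == lo:
        return lo
    c = (mode - lo) / (hi - lo)
    if u < c:
        return lo + ((u * (hi - lo) * (mode - lo)) ** 0.5)
    return hi - (((1.0 - u) * (hi - lo) * (hi - mode)) ** 0.5)


def sample_uniform(dist: tuple[float, float], rng: np.random.Generator) -> float:
    """Inverse-CDF draw from Uniform(lo, hi)."""
    lo, hi = dist
    if hi < lo:
        raise ValidationError(f"invalid uniform parameters {dist}")
    return lo + (hi - lo) * rng.random()


def _round_seconds(minutes: float) -> timedelta:
    return timedelta(seconds=round(minutes * 60.0))


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

@dataclass
class _TripJob:
    route_idx: int
    order_epoch: datetime
    loads: dict[int, int]          # center -> doses on this trip
    outbound: timedelta
    leg_travel: list[timedelta]    # per leg, depot->s1->...->sk->depot
    stop_inbound: list[timedelta]  # per stop


def run_replication(instance: Instance, plan: RoutePlan, cfg: SimConfig, seed: int) -> ReplicationLog:
    """Execute one stochastic replication of a plan; see the module docstring.

    Every order is eventually served (drivers finish queued tours even past
    the horizon end); doses delivered after the horizon are reported in
    ``undelivered_at_horizon`` so that per-center conservation
    ``delivered_by_horizon + undelivered == demanded`` holds exactly.
    """
    rng = np.random.default_rng(seed)
    start = cfg.horizon_start or instance.horizon[0]
    end = cfg.horizon_end or instance.horizon[1]
    horizon_close = datetime.combine(end, time(0, 0)) + ONE_DAY

    types = {v.name: v for v in instance.vehicle_catalogue}
    group_of = {loc.id: loc.group for loc in instance.centers}
    elt = cfg.elt_days if cfg.elt_days is not None else instance.elt_days

    used_types = {r.vehicle_type for r in plan.routes}
    for t in sorted(used_types):
        if t not in types:
            raise ValidationError(f"plan references unknown vehicle type {t!r}")
        if cfg.fleet.get(t, 0) < 1:
            raise ValidationError(f"fleet has no vehicle of required type {t!r}")

    caps = {}
    for t in used_types:
        caps[t] = capacity_in_doses(types[t], instance.doses_per_m3)
        if caps[t] <= 0:
            raise ValidationError(f"vehicle type {t!r} has zero dose capacity")
    d = instance.distances.d

    def speed_params(type_name: str) -> tuple[float, float, float]:
        return cfg.speed_override or types[type_name].speed_kmh

    # --- order generation + trip construction (fleet-independent) ---------
    epoch0 = first_order_epoch(start, cfg)
    n_weeks = instance.demand.n_weeks
    epochs = []
    for w in range(n_weeks):
        e = epoch0 + timedelta(days=7 * w)
        if e.date() <= end:
            epochs.append((w, e))

    backlog: dict[int, int] = {}
    jobs: list[_TripJob] = []
    demanded: dict[int, int] = {}
    for w, epoch in epochs:
        for c, q in sorted(instance.demand.for_week(w).items()):
            backlog[c] = backlog.get(c, 0) + q
            demanded[c] = demanded.get(c, 0) + q
        for r_idx, route in enumerate(plan.routes):
            remaining = {s: backlog.get(s, 0) for s in route.stops if backlog.get(s, 0) > 0}
            total = sum(remaining.values())
            cap = caps[route.vehicle_type]
            while total > 0:
                load = min(cap, total)
                stops_sorted = sorted(remaining)
                alloc = largest_remainder(
                    np.array([remaining[s] for s in stops_sorted], dtype=float), load
                )
                alloc = np.minimum(alloc, [remaining[s] for s in stops_sorted])
                # clamping can only under-allocate; hand the slack to stops with room
                slack = load - int(alloc.sum())
                for i, s in enumerate(stops_sorted):
                    if slack <= 0:
                        break
                    room = remaining[s] - int(alloc[i])
                    take = min(room, slack)
                    alloc[i] += take
                    slack -= take
                loads = {s: int(a) for s, a in zip(stops_sorted, alloc) if a > 0}
                path = [0, *route.stops, 0]
                sp = speed_params(route.vehicle_type)
                outbound = _round_seconds(sample_uniform(cfg.outbound_minutes, rng))
                leg_travel = []
                for a, b in zip(path[:-1], path[1:]):
                    speed = sample_triangular(sp, rng)
                    leg_travel.append(_round_seconds(float(d[a, b]) / speed * 60.0))
                stop_inbound = [
                    _round_seconds(sample_uniform(cfg.inbound_minutes, rng))
                    for _ in route.stops
                ]
                jobs.append(_TripJob(r_idx, epoch, loads, outbound, leg_travel, stop_inbound))
                for s, a in loads.items():
                    remaining[s] -= a
                    backlog[s] -= a
                    if remaining[s] <= 0:
                        remaining.pop(s)
                total -= load

    # --- dispatch & execution ---------------------------------------------
    far_past = datetime.combine(start, time(0, 0)) - ONE_DAY
    pools = {t: [far_past] * cfg.fleet.get(t, 0) for t in used_types}

    shipments: list[ShipmentRecord] = []
    trips: list[TripRecord] = []
    for job in jobs:
        route = plan.routes[job.route_idx]
        pool = pools[route.vehicle_type]
        v_idx = min(range(len(pool)), key=lambda i: (pool[i], i))
        ready = max(job.order_epoch, pool[v_idx])
        t0 = next_shipping_time(ready, cfg)
        while t0 + job.outbound >= _window_close(t0, cfg):
            t0 = next_shipping_time(datetime.combine(t0.date() + ONE_DAY, time(0, 0)), cfg)
        departure = t0 + job.outbound

        now = departure
        for leg, stop in zip(job.leg_travel, route.stops):
            now += leg
            now += job.stop_inbound[route.stops.index(stop)]
            doses = job.loads.get(stop, 0)
            if doses > 0:
                lead = (now - job.order_epoch) / ONE_DAY
                grp = group_of.get(stop)
                limit = elt.get(grp, float("inf")) if grp is not None else float("inf")
                shipments.append(ShipmentRecord(
                    center_id=stop,
                    doses=doses,
                    order_time=job.order_epoch,
                    delivery_time=now,
                    lead_time_days=lead,
                    on_time=lead <= limit + 1e-12,
                ))
        now += job.leg_travel[-1]  # final return leg
        pool[v_idx] = now + _round_seconds(cfg.turnaround_minutes)
        trips.append(TripRecord(
            vehicle_type=route.vehicle_type,
            vehicle_index=v_idx,
            stops=tuple(route.stops),
            departure_time=departure,
            return_time=now,
            distance_km=route.length_km,
            doses_carried=sum(job.loads.values()),
        ))

    undelivered: dict[int, int] = {}
    for s in shipments:
        if s.delivery_time >= horizon_close:
            undelivered[s.center_id] = undelivered.get(s.center_id, 0) + s.doses
    for c in demanded:
        undelivered.setdefault(c, 0)

    log = ReplicationLog(shipments=shipments, trips=trips,
                         undelivered_at_horizon=undelivered, seed=seed)
    _check_conservation(log, demanded, horizon_close)
    return log


def _check_conservation(log: ReplicationLog, demanded: dict[int, int], horizon_close: datetime) -> None:
    delivered_in = {}
    for s in log.shipments:
        if s.delivery_time < horizon_close:
            delivered_in[s.center_id] = delivered_in.get(s.center_id, 0) + s.doses
    for c, q in demanded.items():
        got = delivered_in.get(c, 0) + log.undelivered_at_horizon.get(c, 0)
        if got != q:
            raise AssertionError(
                f"dose conservation violated for center {c}: delivered {delivered_in.get(c, 0)} "
                f"+ undelivered {log.undelivered_at_horizon.get(c, 0)} != demanded {q}"
            )


# ---------------------------------------------------------------------------
# log serialization
# ---------------------------------------------------------------------------

def write_log(log: ReplicationLog, out_dir) -> None:
    """Write shipments.csv and trips.csv with ISO timestamps."""
    import csv
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "shipments.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["center_id", "doses", "order_time", "delivery_time", "lead_time_days", "on_time"])
        for s in log.shipments:
            w.writerow([s.center_id, s.doses, s.order_time.isoformat(),
                        s.delivery_time.isoformat(), f"{s.lead_time_days:.6f}", int(s.on_time)])
    with open(out / "trips.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["vehicle_type", "vehicle_index", "stops", "departure_time",
                    "return_time", "distance_km", "doses_carried"])
        for t in log.trips:
            w.writerow([t.vehicle_type, t.vehicle_index, " ".join(map(str, t.stops)),
                        t.departure_time.isoformat(), t.return_time.isoformat(),
                        f"{t.distance_km:.6f}", t.doses_carried])
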