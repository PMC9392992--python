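"""Sustainability indicators and Monte-Carlo aggregation.

Societal: ELT service level (on-time fraction of delivered doses) and lead
time (dose-weighted mean, max).  Economic: transportation cost as fixed cost
per dispatch plus a distance rate.  Environmental: CO2 as distance times the
vehicle emission factor.  Replication reports are aggregated with mean,
standard deviation and two-sided t confidence half-widths; a stability check
compares KPI means across independent replication batches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .instance import VehicleType
from .sim import ReplicationLog, ShipmentRecord, TripRecord


@dataclass
class KPIReport:
    elt_service_level: float
    mean_lead_time_days: float
    max_lead_time_days: float
    total_cost_nok: float
    total_co2_g: float
    trips_per_vehicle_type: dict[str, int]
    tag: str = ""

    _NUMERIC = ("elt_service_level", "mean_lead_time_days", "max_lead_time_days",
                "total_cost_nok", "total_co2_g")

    def numeric(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self._NUMERIC}


@dataclass
class MonteCarloSummary:
    n: int
    mean: dict[str, float]
    sd: dict[str, float]
    half_width: dict[str, float]
    confidence: float
    base_seed: int | None = None


# ---------------------------------------------------------------------------
# per-replication indicators
# ---------------------------------------------------------------------------

def _elt_for(center_id: int, elt_by_center: dict[int, float] | float) -> float:
    if isinstance(elt_by_center, dict):
        return elt_by_center.get(center_id, float("inf"))
    return float(elt_by_center)


def service_level(
    shipments: Iterable[ShipmentRecord] | ReplicationLog,
    elt_by_center: dict[int, float] | float,
    dose_weighted: bool = True,
) -> float:
    """On-time fraction of delivered doses (or shipments, unweighted).

    A shipment is on time when its lead time does not exceed the expected
    lead time of its center.  An empty log yields 1.0 by convention (no late
    deliveries occurred) with a warning.
    """
    if isinstance(shipments, ReplicationLog):
        shipments = shipments.shipments
    shipments = list(shipments)
    if not shipments:
        warnings.warn("service level of an empty shipment log defined as 1.0", stacklevel=2)
        return 1.0
    num = den = 0.0
    for s in shipments:
        w = s.doses if dose_weighted else 1.0
        den += w
        if s.lead_time_days <= _elt_for(s.center_id, elt_by_center) + 1e-12:
            num += w
    return num / den


def lead_time_stats(
    shipments: Iterable[ShipmentRecord] | ReplicationLog,
    dose_weighted: bool = True,
) -> tuple[float, float]:
    """(mean, max) lead time in days; mean is dose-weighted by default."""
    if isinstance(shipments, ReplicationLog):
        shipments = shipments.shipments
    shipments = list(shipments)
    if not shipments:
        raise ValueError("lead time undefined for an empty shipment log")
    weights = [s.doses if dose_weighted else 1.0 for s in shipments]
    leads = [s.lead_time_days for s in shipments]
    mean = float(np.average(leads, weights=weights))
    return mean, float(max(leads))


def transport_cost(
    trips: Iterable[TripRecord] | ReplicationLog,
    catalogue: Sequence[VehicleType],
    fixed_cost_basis: str = "per_trip",
) -> float:
    """Total NOK: sum over trips of fixed cost x units + rate x distance.

    ``fixed_cost_basis`` is ``per_trip`` (one fixed charge per dispatch,
    default) or ``per_stop`` (one per visited stop).
    """
    if fixed_cost_basis not in ("per_trip", "per_stop"):
        raise ValueError(f"unknown fixed_cost_basis {fixed_cost_basis!r}")
    if isinstance(trips, ReplicationLog):
        trips = trips.trips
    types = {v.name: v for v in catalogue}
    total = 0.0
    for t in trips:
        try:
            vt = types[t.vehicle_type]
        except KeyError:
            raise KeyError(f"trip uses unknown vehicle type {t.vehicle_type!r}") from None
        units = len(t.stops) if fixed_cost_basis == "per_stop" else 1
        total += vt.fixed_cost * units + vt.var_cost_per_km * t.distance_km
    return total


def co2_emissions(trips: Iterable[TripRecord] | ReplicationLog, catalogue: Sequence[VehicleType]) -> float:
    """Total grams CO2: sum over trips of distance x emission factor."""
    if isinstance(trips, ReplicationLog):
        trips = trips.trips
    types = {v.name: v for v in catalogue}
    total = 0.0
    for t in trips:
        try:
            vt = types[t.vehicle_type]
        except KeyError:
            raise KeyError(f"trip uses unknown vehicle type {t.vehicle_type!r}") from None
        total += vt.emission_g_per_km * t.distance_km
    return total


def compute_report(
    log: ReplicationLog,
    catalogue: Sequence[VehicleType],
    elt_by_center: dict[int, float] | float,
    dose_weighted: bool = True,
    fixed_cost_basis: str = "per_trip",
    tag: str = "",
) -> KPIReport:
    """All Table-2-style indicators for one replication log."""
    if log.shipments:
        mean_lead, max_lead = lead_time_stats(log, dose_weighted=dose_weighted)
    else:
        mean_lead = max_lead = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sl = service_level(log, elt_by_center, dose_weighted=dose_weighted)
    per_type: dict[str, int] = {}
    for t in log.trips:
        per_type[t.vehicle_type] = per_type.get(t.vehicle_type, 0) + 1
    return KPIReport(
        elt_service_level=sl,
        mean_lead_time_days=mean_lead,
        max_lead_time_days=max_lead,
        total_cost_nok=transport_cost(log, catalogue, fixed_cost_basis),
        total_co2_g=co2_emissions(log, catalogue),
        trips_per_vehicle_type=per_type,
        tag=tag or f"seed={log.seed}",
    )


# ---------------------------------------------------------------------------
# Monte-Carlo aggregation
# ---------------------------------------------------------------------------

def t_interval_half_width(values: Sequence[float], confidence: float = 0.95) -> float:
    """Two-sided Student-t confidence half-width of the sample mean."""
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 replications for an interval")
    sd = float(np.std(values, ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    return tcrit * sd / math.sqrt(n)


def aggregate_replications(
    reports: Sequence[KPIReport],
    confidence: float = 0.95,
    base_seed: int | None = None,
) -> MonteCarloSummary:
    """Per-KPI mean, sample sd and t-interval half-width over replications."""
    if len(reports) < 2:
        raise ValueError("need at least 2 replications to aggregate")
    keys = KPIReport._NUMERIC
    cols = {k: [r.numeric()[k] for r in reports] for k in keys}
    return MonteCarloSummary(
        n=len(reports),
        mean={k: float(np.mean(v)) for k, v in cols.items()},
        sd={k: float(np.std(v, ddof=1)) for k, v in cols.items()},
        half_width={k: t_interval_half_width(v, confidence) for k, v in cols.items()},
        confidence=confidence,
        base_seed=base_seed,
    )


def stability_check(
    run_replication_kpis: Callable[[int], KPIReport],
    seeds_per_batch: Sequence[Sequence[int]],
    tolerance: float = 0.05,
) -> tuple[bool, dict[str, float]]:
    """Compare per-KPI means across independent replication batches.

    ``seeds_per_batch`` gives disjoint seed streams, one sequence per batch.
    Returns (passed, per-KPI relative spread), where the spread is
    (max batch mean - min batch mean) / |grand mean| (0 when all batch means
    coincide, inf when means differ around a zero grand mean).
    """
    if len(seeds_per_batch) < 2:
        raise ValueError("need at least 2 batches")
    keys = KPIReport._NUMERIC
    batch_means: list[dict[str, float]] = []
    for seeds in seeds_per_batch:
        reports = [run_replication_kpis(s) for s in seeds]
        batch_means.append({k: float(np.mean([r.numeric()[k] for r in reports])) for k in keys})
    spread: dict[str, float] = {}
    for k in keys:
        vals = [bm[k] for bm in batch_means]
        lo, hi = min(vals), max(vals)
        grand = float(np.mean(vals))
        if hi == lo:
            spread[k] = 0.0
        elif grand == 0.0:
            spread[k] = float("inf")
        else:
            spread[k] = (hi - lo) / abs(grand)
    return max(spread.values()) <= tolerance, spread


def summary_row(summary: MonteCarloSummary) -> dict[str, float]:
    """Flatten a summary for CSV output."""
    row: dict[str, float] = {"n": summary.n, "confidence": summary.confidence}
    for k, v in summary.mean.items():
        row[f"{k}_mean"] = v
        row[f"{k}_sd"] = summary.sd[k]
        row[f"{k}_hw"] = summary.half_width[k]
    return row
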