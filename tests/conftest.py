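from datetime import date

import numpy as np
import pytest

from coldchain.instance import (
    DemandEntry,
    DemandSeries,
    DistanceMatrix,
    Instance,
    Location,
    VehicleType,
)
from coldchain.synth import SynthConfig, generate_instance, vehicle_catalogue

DEFAULT_HORIZON = (date(2020, 12, 28), date(2021, 3, 15))


def make_instance(
    dmat,
    demand=None,
    vehicles=None,
    elt=None,
    groups=None,
    horizon=DEFAULT_HORIZON,
    doses_per_m3=600,
):
    """Build a small instance directly from a distance matrix.

    ``demand`` is a list of (week, center_id, doses); ``groups`` maps
    center_id -> group (default: all group 1).
    """
    dmat = np.asarray(dmat, dtype=float)
    n = dmat.shape[0]
    groups = groups or {}
    locations = [Location(id=0, name="DC", lat=0.0, lon=0.0, role="depot")]
    for i in range(1, n):
        locations.append(Location(
            id=i, name=f"C{i}", lat=0.0, lon=float(i) * 1e-3, role="center",
            population_18plus=1000, group=groups.get(i, 1),
        ))
    entries = [DemandEntry(week=w, center_id=c, doses=q) for (w, c, q) in (demand or [])]
    return Instance(
        locations=locations,
        demand=DemandSeries(entries=entries),
        vehicle_catalogue=vehicles or vehicle_catalogue(),
        distances=DistanceMatrix(d=dmat, metric_tag="test"),
        elt_days=elt or {1: 1.0, 2: 2.0},
        horizon=horizon,
        doses_per_m3=doses_per_m3,
    )


def euclidean_instance(points, demand=None, vehicles=None, **kw):
    """Instance whose distances are Euclidean between 2-D points (km);
    points[0] is the depot."""
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1))
    return make_instance(d, demand=demand, vehicles=vehicles, **kw)


def random_euclidean_instance(rng, n_customers, box_km=120.0, demand_range=(50, 400)):
    """Seeded random planar instance with one week of random dose demands."""
    pts = rng.uniform(0.0, box_km, size=(n_customers + 1, 2))
    demand = [(0, i, int(rng.integers(*demand_range))) for i in range(1, n_customers + 1)]
    return euclidean_instance(pts, demand=demand)


@pytest.fixture
def catalogue():
    return vehicle_catalogue()


@pytest.fixture
def nv200(catalogue):
    return next(v for v in catalogue if v.name == "NV200")


@pytest.fixture
def e_nv200(catalogue):
    return next(v for v in catalogue if v.name == "e-NV200")


@pytest.fixture(scope="session")
def synthetic_instance():
    """The packaged Inland-like synthetic instance (46 centers, 12 weeks)."""
    return generate_instance(SynthConfig(seed=1))


@pytest.fixture
def line_instance():
    """Five customers on a 20-km-spaced line from the depot."""
    d = np.abs(np.subtract.outer(np.arange(6), np.arange(6))) * 20.0
    return make_instance(d)
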