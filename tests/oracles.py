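"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's solver code paths: the CVRP oracle
enumerates every set partition of the customers and every stop permutation
per block; the geometric-median oracle is a refining grid search; the
subtour oracle uses networkx connected components.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def iter_set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_tour(block, d):
    """(min tour length, best permutation) over all stop orders of a block."""
    best = None
    for perm in itertools.permutations(block):
        path = (0, *perm, 0)
        length = sum(d[a][b] for a, b in zip(path[:-1], path[1:]))
        if best is None or length < best[0]:
            best = (length, perm)
    return best


def brute_force_cvrp(d, customers, vehicle_types, stop_limit,
                     capacity_mode="unit_stop_limit", demands=None, doses_per_m3=600):
    """Optimal objective by exhaustive enumeration over ordered partitions.

    ``vehicle_types`` is a list of (var_cost_per_km, range_km, capacity_m3)
    tuples; each block is priced with its cheapest feasible type.
    Returns (objective, partition) or None if infeasible.
    """
    d = np.asarray(d)
    tour_cache = {}

    def block_cost(block):
        key = frozenset(block)
        if key not in tour_cache:
            if len(block) > stop_limit:
                tour_cache[key] = None
            else:
                length, _ = best_tour(sorted(block), d)
                load = sum((demands or {}).get(c, 0) for c in block)
                best = None
                for cost_km, range_km, cap_m3 in vehicle_types:
                    if length > range_km + 1e-9:
                        continue
                    if capacity_mode == "volume" and load > math.floor(cap_m3 * doses_per_m3):
                        continue
                    c = cost_km * length
                    if best is None or c < best:
                        best = c
                tour_cache[key] = best
        return tour_cache[key]

    best = None
    for partition in iter_set_partitions(sorted(customers)):
        total = 0.0
        ok = True
        for block in partition:
            c = block_cost(block)
            if c is None:
                ok = False
                break
            total += c
        if ok and (best is None or total < best[0] - 1e-12):
            best = (total, partition)
    return best


def grid_search_median(points, weights, box, levels=6, grid=41):
    """Refining grid search for the weighted geometric median (planar).

    Starts on the bounding box and zooms 6 times; the final grid spacing is
    well under 1 m for km-scale boxes.  Returns (best objective, (x, y)).
    """
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    (x_lo, x_hi), (y_lo, y_hi) = box

    def objective(x, y):
        return float(np.sum(w * np.sqrt((pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2)))

    best = None
    for _ in range(levels):
        xs = np.linspace(x_lo, x_hi, grid)
        ys = np.linspace(y_lo, y_hi, grid)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        D = np.zeros_like(X)
        for p, wi in zip(pts, w):
            D += wi * np.sqrt((X - p[0]) ** 2 + (Y - p[1]) ** 2)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        best = (float(D[i, j]), (float(xs[i]), float(ys[j])))
        span_x = (x_hi - x_lo) / (grid - 1) * 2
        span_y = (y_hi - y_lo) / (grid - 1) * 2
        x_lo, x_hi = best[1][0] - span_x, best[1][0] + span_x
        y_lo, y_hi = best[1][1] - span_y, best[1][1] + span_y
    return best


def haversine_reference(lat1, lon1, lat2, lon2, radius_km=6371.0):
    """Second, independent haversine implementation (law-of-cosines-free)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * radius_km * math.atan2(math.sqrt(a), math.sqrt(1 - a))
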