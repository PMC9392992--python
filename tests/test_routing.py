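import itertools

import networkx as nx
import numpy as np
import pytest

from coldchain.instance import Location, ValidationError, VehicleType
from coldchain.routing import (
    CVRPConfig,
    ExactSizeError,
    InfeasibleError,
    Route,
    RoutePlan,
    assign_vehicle_types,
    greenfield_location,
    plan_from_dict,
    plan_to_dict,
    read_plan,
    separate_subtours,
    solve_cvrp_exact,
    solve_cvrp_heuristic,
    validate_route_plan,
    write_plan,
)
from coldchain.synth import vehicle_catalogue

from .conftest import euclidean_instance, make_instance, random_euclidean_instance
from .oracles import brute_force_cvrp, grid_search_median, iter_set_partitions

NV200 = next(v for v in vehicle_catalogue() if v.name == "NV200")


def cfg_for(instance, vehicles=None, **kw):
    return CVRPConfig(vehicle_types=vehicles or [NV200], **kw)


class TestExactSolver:
    def test_single_customer_forced_route(self):
        inst = make_instance([[0.0, 50.0], [50.0, 0.0]])
        plan = solve_cvrp_exact(inst, cfg_for(inst))
        assert [r.stops for r in plan.routes] == [[1]]
        assert plan.routes[0].length_km == pytest.approx(100.0)
        # NV200 runs at 8 NOK/km
        assert plan.objective_nok_km == pytest.approx(800.0)
        assert plan.optimality_tag == "exact"

    def test_line_instance_matches_enumeration(self, line_instance):
        plan = solve_cvrp_exact(line_instance, cfg_for(line_instance))
        oracle = brute_force_cvrp(line_instance.distances.d, [1, 2, 3, 4, 5],
                                  [(8.0, 1000.0, 2.1)], stop_limit=10)
        assert plan.objective_nok_km == pytest.approx(oracle[0])

    def test_size_ceiling_redirects_to_heuristic(self, synthetic_instance):
        cfg = cfg_for(synthetic_instance)
        with pytest.raises(ExactSizeError, match="heuristic"):
            solve_cvrp_exact(synthetic_instance, cfg)

    def test_out_of_range_customer_named(self):
        short = VehicleType("short", 2.1, 80.0, (40, 50, 70), 6.0, 1500.0, 0.0)
        inst = make_instance([[0.0, 50.0], [50.0, 0.0]])
        with pytest.raises(InfeasibleError, match=r"\[1\]"):
            solve_cvrp_exact(inst, cfg_for(inst, vehicles=[short]))

    def test_stop_limit_forces_split(self, line_instance):
        plan = solve_cvrp_exact(line_instance, cfg_for(line_instance, stop_limit=2))
        assert all(len(r.stops) <= 2 for r in plan.routes)
        oracle = brute_force_cvrp(line_instance.distances.d, [1, 2, 3, 4, 5],
                                  [(8.0, 1000.0, 2.1)], stop_limit=2)
        assert plan.objective_nok_km == pytest.approx(oracle[0])

    def test_volume_mode_matches_enumeration(self):
        rng = np.random.default_rng(4)
        inst = random_euclidean_instance(rng, 5)
        demands = {c: q for (_, c, q) in
                   [(e.week, e.center_id, e.doses) for e in inst.demand.entries]}
        cfg = cfg_for(inst, capacity_mode="volume")
        cfg.demands = demands
        plan = solve_cvrp_exact(inst, cfg)
        oracle = brute_force_cvrp(inst.distances.d, list(demands), [(8.0, 1000.0, 2.1)],
                                  stop_limit=10, capacity_mode="volume", demands=demands)
        assert plan.objective_nok_km == pytest.approx(oracle[0])
        assert not validate_route_plan(plan, inst, cfg)

    def test_heterogeneous_types_price_each_tour_cheapest(self):
        # a far customer only the long-range type can reach, near ones go electric
        e = VehicleType("e-NV200", 2.1, 300.0, (40, 50, 70), 6.0, 1500.0, 0.0)
        inst = make_instance(np.array([
            [0, 40, 45, 400],
            [40, 0, 10, 600],
            [45, 10, 0, 600],
            [400, 600, 600, 0],
        ], dtype=float))
        plan = solve_cvrp_exact(inst, cfg_for(inst, vehicles=[e, NV200]))
        by_stops = {tuple(sorted(r.stops)): r.vehicle_type for r in plan.routes}
        assert by_stops[(3,)] == "NV200"
        assert all(v == "e-NV200" for s, v in by_stops.items() if 3 not in s)

    def test_objective_equals_recomputation(self, line_instance):
        plan = solve_cvrp_exact(line_instance, cfg_for(line_instance))
        recomputed = sum(NV200.var_cost_per_km * r.length_km for r in plan.routes)
        assert plan.objective_nok_km == pytest.approx(recomputed, rel=1e-12)

    def test_deterministic_output(self, line_instance):
        a = solve_cvrp_exact(line_instance, cfg_for(line_instance))
        b = solve_cvrp_exact(line_instance, cfg_for(line_instance))
        assert plan_to_dict(a) == plan_to_dict(b)


class TestSeparateSubtours:
    def test_disconnected_cycle_detected(self):
        arcs = [(0, 4), (4, 0), (1, 2), (2, 3), (3, 1)]
        cuts = separate_subtours(arcs)
        assert [set(c.W) for c in cuts] == [{1, 2, 3}]

    def test_single_tour_no_cuts(self):
        arcs = [(0, 1), (1, 2), (2, 3), (3, 0)]
        assert separate_subtours(arcs) == []

    def test_dict_input_thresholded(self):
        arcs = {(1, 2): 1.0, (2, 1): 1.0, (0, 3): 0.2}
        cuts = separate_subtours(arcs)
        assert [set(c.W) for c in cuts] == [{1, 2}]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        # random degree-feasible solution: a permutation decomposed into cycles
        perm = rng.permutation(n)
        arcs = [(i, int(perm[i])) for i in range(n) if i != perm[i]]
        g = nx.Graph(arcs)
        expected = sorted(
            tuple(sorted(c)) for c in nx.connected_components(g) if 0 not in c
        )
        got = sorted(tuple(sorted(c.W)) for c in separate_subtours(arcs))
        assert got == expected

    def test_cut_never_excludes_depot_connected_plans(self):
        # every cut from disconnected solutions keeps all valid plans feasible:
        # arcs of a valid plan inside W always form paths, so <= |W|-1 of them
        rng = np.random.default_rng(1)
        inst = random_euclidean_instance(rng, 5)
        customers = [1, 2, 3, 4, 5]
        cuts = [frozenset({1, 2}), frozenset({2, 3, 4}), frozenset(customers)]
        for partition in iter_set_partitions(customers):
            for block in partition:
                if len(block) > 10:
                    continue
            arcs = []
            for block in partition:
                path = [0, *block, 0]
                arcs += list(zip(path[:-1], path[1:]))
            for W in cuts:
                inside = sum(1 for i, j in arcs if i in W and j in W)
                assert inside <= len(W) - 1


class TestHeuristic:
    def test_single_customer_matches_exact(self):
        inst = make_instance([[0.0, 50.0], [50.0, 0.0]])
        h = solve_cvrp_heuristic(inst, cfg_for(inst))
        e = solve_cvrp_exact(inst, cfg_for(inst))
        assert plan_to_dict(h)["routes"] == plan_to_dict(e)["routes"]

    @pytest.mark.parametrize("seed", range(5))
    def test_never_beats_exact_and_always_feasible(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_euclidean_instance(rng, 6)
        cfg = cfg_for(inst)
        h = solve_cvrp_heuristic(inst, cfg)
        e = solve_cvrp_exact(inst, cfg)
        assert h.objective_nok_km >= e.objective_nok_km - 1e-9
        assert not validate_route_plan(h, inst, cfg)

    def test_respects_stop_limit_and_range(self):
        rng = np.random.default_rng(7)
        inst = random_euclidean_instance(rng, 20)
        short = VehicleType("short", 2.1, 320.0, (40, 50, 70), 6.0, 1500.0, 0.0)
        cfg = cfg_for(inst, vehicles=[short], stop_limit=4)
        plan = solve_cvrp_heuristic(inst, cfg)
        assert not validate_route_plan(plan, inst, cfg)
        assert all(len(r.stops) <= 4 for r in plan.routes)
        assert all(r.length_km <= 320.0 + 1e-9 for r in plan.routes)

    def test_infeasible_customer_reported(self):
        short = VehicleType("short", 2.1, 80.0, (40, 50, 70), 6.0, 1500.0, 0.0)
        inst = make_instance([[0.0, 50.0], [50.0, 0.0]])
        with pytest.raises(InfeasibleError):
            solve_cvrp_heuristic(inst, cfg_for(inst, vehicles=[short]))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        inst = random_euclidean_instance(rng, 15)
        a = solve_cvrp_heuristic(inst, cfg_for(inst))
        b = solve_cvrp_heuristic(inst, cfg_for(inst))
        assert plan_to_dict(a) == plan_to_dict(b)


class TestValidateRoutePlan:
    def test_duplicate_customer_flagged(self, line_instance):
        plan = RoutePlan(
            routes=[Route("NV200", [1, 3], 120.0), Route("NV200", [3, 2, 4, 5], 200.0)],
            objective_nok_km=0.0, optimality_tag="heuristic")
        v = validate_route_plan(plan, line_instance, cfg_for(line_instance))
        assert any("customer 3 multiplicity 2" in msg for msg in v)

    def test_stop_limit_violation_flagged(self):
        d = np.abs(np.subtract.outer(np.arange(12), np.arange(12))) * 1.0
        inst = make_instance(d)
        stops = list(range(1, 12))
        plan = RoutePlan(routes=[Route("NV200", stops, 22.0)],
                         objective_nok_km=0.0, optimality_tag="heuristic")
        v = validate_route_plan(plan, inst, cfg_for(inst, stop_limit=10))
        assert any("11 stops exceed stop limit 10" in msg for msg in v)

    def test_range_violation_flagged(self, e_nv200):
        inst = make_instance([[0.0, 160.0], [160.0, 0.0]])
        plan = RoutePlan(routes=[Route("e-NV200", [1], 320.0)],
                         objective_nok_km=0.0, optimality_tag="heuristic")
        v = validate_route_plan(plan, inst, cfg_for(inst, vehicles=[e_nv200]))
        assert any("exceeds range 300 km" in msg for msg in v)

    def test_valid_plan_clean(self, line_instance):
        plan = solve_cvrp_exact(line_instance, cfg_for(line_instance))
        assert validate_route_plan(plan, line_instance, cfg_for(line_instance)) == []

    def test_wrong_length_flagged(self, line_instance):
        plan = RoutePlan(routes=[Route("NV200", [1, 2, 3, 4, 5], 999.0)],
                         objective_nok_km=0.0, optimality_tag="heuristic")
        v = validate_route_plan(plan, line_instance, cfg_for(line_instance))
        assert any("recomputed" in msg for msg in v)


class TestGreenfield:
    @staticmethod
    def _center(i, lat, lon):
        return Location(id=i, name=f"C{i}", lat=lat, lon=lon, role="center")

    def test_single_customer_fixed_point(self):
        c = self._center(1, 61.1, 10.3)
        assert greenfield_location([c], [5.0]) == (61.1, 10.3)

    def test_two_equal_weights_midpoint(self):
        a, b = self._center(1, 60.0, 10.0), self._center(2, 60.2, 10.0)
        lat, lon = greenfield_location([a, b], [1.0, 1.0])
        assert lat == pytest.approx(60.1, abs=1e-5)
        assert lon == pytest.approx(10.0, abs=1e-5)

    def test_all_zero_weights_rejected(self):
        a = self._center(1, 60.0, 10.0)
        with pytest.raises(ValidationError):
            greenfield_location([a, a], [0.0, 0.0])

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(2)
        custs = [self._center(i, float(rng.uniform(60, 62)), float(rng.uniform(9.5, 12)))
                 for i in range(10)]
        w = rng.uniform(1, 10, size=10)
        _, trace = greenfield_location(custs, w, return_trace=True)
        assert all(b <= a + 1e-9 for a, b in zip(trace[:-1], trace[1:]))

    def test_matches_grid_search_oracle(self):
        from coldchain.instance import EARTH_RADIUS_KM
        import math
        rng = np.random.default_rng(5)
        custs = [self._center(i, float(rng.uniform(60, 62)), float(rng.uniform(9.5, 12)))
                 for i in range(10)]
        w = rng.uniform(1, 10, size=10)
        (lat, lon), trace = greenfield_location(custs, w, return_trace=True)

        # evaluate both in the same local plane used by the implementation
        lat0 = float(np.average([c.lat for c in custs], weights=w))
        lon0 = float(np.average([c.lon for c in custs], weights=w))
        coslat = math.cos(math.radians(lat0))
        pts = np.array([
            [EARTH_RADIUS_KM * math.radians(c.lon - lon0) * coslat,
             EARTH_RADIUS_KM * math.radians(c.lat - lat0)] for c in custs
        ])
        box = ((pts[:, 0].min(), pts[:, 0].max()), (pts[:, 1].min(), pts[:, 1].max()))
        oracle_obj, _ = grid_search_median(pts, w, box)
        assert trace[-1] <= oracle_obj * 1.001


class TestAssignVehicleTypes:
    def test_model_1(self, catalogue):
        assert assign_vehicle_types(catalogue, 1) == {1: "e-NV200", 2: "NV200"}

    def test_model_2_same_as_1(self, catalogue):
        assert assign_vehicle_types(catalogue, 2) == {1: "e-NV200", 2: "NV200"}

    def test_model_3(self, catalogue):
        assert assign_vehicle_types(catalogue, 3) == {1: "NV200", 2: "VW Transporter"}

    def test_override_checked_and_returned(self, catalogue):
        override = {1: "NV200", 2: "NV200"}
        assert assign_vehicle_types(catalogue, 1, override=override) == override
        with pytest.raises(ValidationError, match="unknown vehicle type"):
            assign_vehicle_types(catalogue, 1, override={1: "Tesla"})

    def test_unknown_model_rejected(self, catalogue):
        with pytest.raises(ValidationError, match="model id"):
            assign_vehicle_types(catalogue, 4)


class TestPlanIO:
    def test_json_round_trip(self, tmp_path, line_instance):
        plan = solve_cvrp_exact(line_instance, cfg_for(line_instance))
        write_plan(plan, tmp_path / "plan.json", instance=line_instance)
        back = read_plan(tmp_path / "plan.json")
        assert plan_to_dict(back) == plan_to_dict(plan)
        geo = (tmp_path / "plan.geojson").read_text()
        assert "LineString" in geo
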