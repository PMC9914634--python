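"""Four-phase dispatch: locate, candidate set, ranking, selection, costs."""

import dataclasses

import pytest

from emsroute import (
    CatchmentAdjacency,
    DispatchRequest,
    ExhaustionError,
    FixtureSpec,
    NetworkValidationError,
    NoCoverageError,
    adjacency,
    build_nvd,
    candidate_set,
    dispatch,
    locate,
    make_fixture,
    rank_candidates,
    route_costs,
    time_weights,
)
from conftest import brute_force_shortest, facilities_at, path_network


def star_adjacency():
    """Hand-built catchment adjacency mirroring the worked dispatch example:
    home p5 surrounded by p2, p3, p4, p6, p7; p1 one ring further out."""
    ring = {"p2", "p3", "p4", "p6", "p7"}
    neighbors = {"p5": set(ring), "p1": {"p2"}}
    for g in ring:
        neighbors[g] = {"p5"}
    neighbors["p2"].add("p1")
    return CatchmentAdjacency(neighbors=neighbors, boundary_edges=set())


class TestCandidateSet:
    def test_unavailable_home_yields_all_adjacent_facilities(self):
        adj = star_adjacency()
        avail = {f: 1 for f in adj.neighbors}
        avail["p5"] = 0
        assert candidate_set("p5", adj, avail) == {"p3", "p6", "p7", "p4", "p2"}

    def test_available_home_plus_neighbors(self):
        adj = CatchmentAdjacency({"pa": {"pb", "pc"}, "pb": {"pa"}, "pc": {"pa"}}, set())
        assert candidate_set("pa", adj, {"pa": 1, "pb": 1, "pc": 1}) == {"pa", "pb", "pc"}

    def test_unavailable_neighbors_are_filtered_out(self):
        adj = CatchmentAdjacency({"pa": {"pb", "pc"}, "pb": {"pa"}, "pc": {"pa"}}, set())
        assert candidate_set("pa", adj, {"pa": 1, "pb": 0, "pc": 1}) == {"pa", "pc"}

    def test_ring_expansion_reaches_second_ring(self):
        adj = star_adjacency()
        avail = {f: 0 for f in adj.neighbors}
        avail["p1"] = 1  # only the second-ring facility has a unit
        assert candidate_set("p5", adj, avail) == {"p1"}

    def test_everything_down_is_exhaustion(self):
        adj = star_adjacency()
        with pytest.raises(ExhaustionError, match="candidate_set"):
            candidate_set("p5", adj, {f: 0 for f in adj.neighbors})


class TestLocate:
    def test_demand_at_anchor_homes_to_that_facility(self):
        net = path_network(5)
        fs = facilities_at(net, {"pa": "n0", "pb": "n4"})
        ca = build_nvd(net, fs, {e: 1.0 for e in net.edges})
        node, home = locate(ca, DispatchRequest(demand_node="n4"), net)
        assert (node, home) == ("n4", "pb")

    def test_uncovered_component_raises_no_coverage(self):
        net = path_network(5)
        del net.edges["e2"]
        net._graph = None
        fs = facilities_at(net, {"pa": "n0"})
        ca = build_nvd(net, fs, {e: 1.0 for e in net.edges})
        with pytest.raises(NoCoverageError, match="locate"):
            locate(ca, DispatchRequest(demand_node="n4"), net)

    def test_request_must_identify_a_demand(self):
        with pytest.raises(ValueError):
            DispatchRequest()


class TestRanking:
    def test_single_candidate_equals_plain_dijkstra(self):
        net = path_network(6)
        w = time_weights(net)
        anchors = {"pa": "n0"}
        ranked = rank_candidates(net, w, {"pa"}, "n4", anchors)
        assert len(ranked) == 1
        assert ranked[0].travel_time_s == pytest.approx(brute_force_shortest(net, w, "n0", "n4"), rel=1e-12)
        assert ranked[0].path[0] == "n0" and ranked[0].path[-1] == "n4"

    def test_order_matches_exhaustive_path_enumeration(self):
        fx = make_fixture(
            FixtureSpec(
                kind="random_planar",
                node_count=11,
                speed_set=(30.0, 60.0),
                congestion=("uniform", 0.0, 0.7),
                facility_count=5,
                seed=23,
            )
        )
        net, fs = fx.network, fx.facilities
        w = time_weights(net)
        anchors = fs.anchors()
        demand = sorted(net.nodes)[3]
        ranked = rank_candidates(net, w, set(anchors), demand, anchors)
        expect = sorted(
            ((brute_force_shortest(net, w, anchors[f], demand), f) for f in anchors),
        )
        assert [c.facility_id for c in ranked] == [f for _, f in expect]
        for c, (t, _) in zip(ranked, expect):
            assert c.travel_time_s == pytest.approx(t, rel=1e-9)

    def test_path_cost_consistency(self, planar_fixture):
        net, fs = planar_fixture.network, planar_fixture.facilities
        w = time_weights(net)
        anchors = fs.anchors()
        ranked = rank_candidates(net, w, set(anchors), sorted(net.nodes)[10], anchors)
        for c in ranked:
            recomputed = sum(
                min(w[s.edge_id] for s in net.edges.values() if {s.u, s.v} == {a, b})
                for a, b in zip(c.path, c.path[1:])
            )
            assert c.travel_time_s == pytest.approx(recomputed, rel=1e-9)


class TestDispatch:
    def build(self, fx):
        w = time_weights(fx.network)
        ca = build_nvd(fx.network, fx.facilities, w)
        adj = adjacency(fx.network, ca)
        return w, ca, adj

    def test_all_available_selects_the_home_facility(self, planar_fixture):
        fx = planar_fixture
        w, ca, adj = self.build(fx)
        for node in sorted(fx.network.nodes)[::7]:
            res = dispatch(fx.network, fx.facilities, ca, adj, w, DispatchRequest(demand_node=node))
            assert res.selected.facility_id == ca.label[node]
            assert res.selected.source == "home_catchment"
            assert res.selected.travel_time_s == pytest.approx(ca.dist[node], rel=1e-9)

    def test_home_down_falls_back_to_an_adjacent_catchment(self, planar_fixture):
        fx = planar_fixture
        w, ca, adj = self.build(fx)
        node = sorted(fx.network.nodes)[17]
        home = ca.label[node]
        res = dispatch(
            fx.network, fx.facilities, ca, adj, w,
            DispatchRequest(demand_node=node, availability_override={home: 0}),
        )
        assert res.selected.facility_id in adj.neighbors[home]
        assert res.selected.source == "adjacent_catchment"
        # exact argmin over the constructed candidate set
        cands = candidate_set(home, adj, {home: 0})
        anchors = fx.facilities.anchors()
        best = min((brute_force_shortest_via_nx(fx.network, w, anchors[f], node), f) for f in cands)
        assert res.selected.facility_id == best[1]

    def test_shrinking_availability_never_shortens_the_response(self, planar_fixture):
        fx = planar_fixture
        w, ca, adj = self.build(fx)
        node = sorted(fx.network.nodes)[40]
        down: dict[str, int] = {}
        prev = -1.0
        for fid in sorted(f.facility_id for f in fx.facilities)[:-1]:
            try:
                res = dispatch(fx.network, fx.facilities, ca, adj, w, DispatchRequest(demand_node=node, availability_override=dict(down)))
            except ExhaustionError:
                break
            assert res.selected.travel_time_s >= prev
            prev = res.selected.travel_time_s
            down[res.selected.facility_id] = 0

    def test_rerun_is_identical(self, planar_fixture):
        fx = planar_fixture
        w, ca, adj = self.build(fx)
        req = DispatchRequest(demand_lon=fx.demands[3][0], demand_lat=fx.demands[3][1])
        a = dispatch(fx.network, fx.facilities, ca, adj, w, req)
        b = dispatch(fx.network, fx.facilities, ca, adj, w, req)
        assert a == b

    def test_phase_log_records_all_four_phases(self, planar_fixture):
        fx = planar_fixture
        w, ca, adj = self.build(fx)
        res = dispatch(fx.network, fx.facilities, ca, adj, w, DispatchRequest(demand_node=sorted(fx.network.nodes)[5]))
        assert [p["phase"] for p in res.phase_log] == ["locate", "candidate_set", "rank", "select"]


def brute_force_shortest_via_nx(net, w, src, dst):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for seg in net.edges.values():
        ww = w[seg.edge_id]
        if not g.has_edge(seg.u, seg.v) or ww < g[seg.u][seg.v]["w"]:
            g.add_edge(seg.u, seg.v, w=ww)
    return nx.dijkstra_path_length(g, src, dst, weight="w")


class TestRouteCosts:
    def two_edge_net(self, count=None):
        net = path_network(3, length_m=400.0)
        net.edges["e0"] = dataclasses.replace(net.edges["e0"], vehicle_count=count)
        net.edges["e1"] = dataclasses.replace(
            net.edges["e1"], length_m=600.0,
            vehicle_count=None if count is None else count * 1.5,
        )
        return net

    def test_free_flow_two_edge_route(self):
        # 400 m + 600 m at 36 km/h, empty roads: 1 km and 100 s
        net = self.two_edge_net(count=0.0)
        dist, times = route_costs(net, ["n0", "n1", "n2"])
        assert dist == pytest.approx(1000.0)
        assert times["greenshields_division"] == pytest.approx(100.0, rel=1e-12)
        assert times["as_printed"] == pytest.approx(100.0, rel=1e-12)

    def test_saturation_070_inflates_division_time_only(self):
        # counts chosen so density/k_max = 0.70 on both edges
        net = self.two_edge_net(count=0.70 * 100.0 * 400.0 / 1000.0)
        dist, times = route_costs(net, ["n0", "n1", "n2"])
        assert dist == pytest.approx(1000.0)
        assert times["greenshields_division"] == pytest.approx(100.0 / 0.3, rel=1e-9)
        assert times["as_printed"] == pytest.approx(30.0, rel=1e-9)

    def test_empty_path_costs_nothing(self, grid3):
        assert route_costs(grid3.network, ["n0000"]) == (0.0, {"greenshields_division": 0.0, "as_printed": 0.0})

    def test_non_adjacent_nodes_rejected(self):
        net = path_network(4)
        with pytest.raises(NetworkValidationError, match="not adjacent"):
            route_costs(net, ["n0", "n2"])
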