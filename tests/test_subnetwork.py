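"""Flow model: construction, exact/LP solving, extraction, R scan, oracle."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cocktailnet import (
    MolecularNetwork,
    AffectedSubnetworkModel,
    brute_force_oracle,
    build_model,
    extract_subnetwork,
    find_affected_subnetwork,
    r_bounds,
    solve,
)
from cocktailnet.simulate import random_flow_instance as random_instance
from cocktailnet.subnetwork import FlowSolution, InfeasibleModelError


class TestBuildModel:
    def test_variable_and_arc_counts(self, path_net):
        model = build_model(path_net, {"A"}, 2, weights={})
        assert model.n_nodes == 3
        assert model.n_arcs == 4          # both directions of 2 edges
        assert model.targets == ["A"]     # 1 dummy arc

    def test_target_selection_forced(self, path_net):
        model = build_model(path_net, {"A", "B"}, 2, weights={})
        sol = solve(model, exact=True)
        assert sol.x["A"] == pytest.approx(1.0) and sol.x["B"] == pytest.approx(1.0)

    def test_missing_target_is_error(self, path_net):
        with pytest.raises(InfeasibleModelError, match="X"):
            build_model(path_net, {"X"}, 2)

    def test_r_below_target_count_is_error(self, path_net):
        with pytest.raises(ValueError):
            build_model(path_net, {"A", "C"}, 1)


class TestSolve:
    def test_zero_weights_zero_objective(self, path_net):
        model = build_model(path_net, {"A"}, 2, weights={})
        assert solve(model).objective == pytest.approx(0.0)

    def test_star_exact_enumeration(self, star_net):
        # size-2 connected supersets of A: {A,B}, {A,C}, {A,D} -> best {A,B}
        w = {"A": 1.0, "B": 5.0, "C": 1.0, "D": 0.0}
        model = build_model(star_net, {"A"}, 2, weights=w)
        res = extract_subnetwork(model, solve(model, exact=True))
        assert res.genes == ("A", "B") and res.objective == pytest.approx(6.0)

    def test_path_forced_set(self, path_net):
        w = {"A": 1.0, "B": 0.0, "C": 10.0}
        model = build_model(path_net, {"A"}, 3, weights=w)
        res = extract_subnetwork(model, solve(model, exact=True))
        assert res.genes == ("A", "B", "C") and res.objective == pytest.approx(11.0)

    def test_infeasible_size_is_error(self):
        # R=3 with target A forces a third node in a target-free component
        net = MolecularNetwork.from_edges([("A", "B"), ("C", "D")])
        model = build_model(net, {"A"}, 3, weights={})
        with pytest.raises(InfeasibleModelError, match="A"):
            solve(model, exact=True)

    def test_targets_in_separate_components_feasible_via_dummy(self):
        # the dummy drug node feeds each target, so per-component coverage
        # is feasible even when the targets are mutually unreachable
        net = MolecularNetwork.from_edges([("A", "B"), ("C", "D")])
        model = build_model(net, {"A", "C"}, 2, weights={"B": 1.0})
        res = extract_subnetwork(model, solve(model, exact=True))
        assert set(res.genes) == {"A", "C"}


class TestExtract:
    def _sol(self, model, xvals):
        x = pd.Series(xvals)
        return FlowSolution(x=x, z={}, objective=float("nan"), exact=False)

    def test_integral_selection(self, path_net):
        model = build_model(path_net, {"A"}, 2, weights={})
        res = extract_subnetwork(model, self._sol(model, {"A": 1.0, "B": 1.0, "C": 0.0}))
        assert res.genes == ("A", "B") and res.lp_integral

    def test_fractional_above_threshold_included(self, path_net):
        model = build_model(path_net, {"A"}, 2, weights={})
        res = extract_subnetwork(model, self._sol(model, {"A": 1.0, "B": 1.0, "C": 0.5}))
        assert "C" in res.genes and not res.lp_integral

    def test_only_targets_survive_threshold(self, path_net):
        model = build_model(path_net, {"A"}, 2, weights={})
        res = extract_subnetwork(model, self._sol(model, {"A": 1.0, "B": 0.0, "C": 0.0}))
        assert res.genes == ("A",)

    def test_target_free_component_dropped(self):
        net = MolecularNetwork.from_edges([("A", "B"), ("C", "D")])
        model = build_model(net, {"A"}, 2, weights={})
        res = extract_subnetwork(model, self._sol(
            model, {"A": 1.0, "B": 1.0, "C": 1.0, "D": 0.0}))
        assert res.genes == ("A", "B")


class TestRBounds:
    def test_single_target(self, path_net):
        assert r_bounds(path_net, {"B"})[0] == 1

    def test_adjacent_targets(self, path_net):
        assert r_bounds(path_net, {"A", "B"})[0] == 2

    def test_padded_path_bounds(self):
        # path A-B-C-D plus 36 padding nodes => |V| = 40, R_max = 4
        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        edges += [(f"P{i:02d}", f"P{i+1:02d}") for i in range(35)]
        edges += [("D", "P00")]
        net = MolecularNetwork.from_edges(edges)
        assert net.n_nodes == 40
        assert r_bounds(net, {"A", "C"}) == (3, 4)

    def test_unreachable_pair_is_error(self):
        net = MolecularNetwork.from_edges([("A", "B"), ("C", "D")])
        with pytest.raises(InfeasibleModelError):
            r_bounds(net, {"A", "C"})

    def test_r_max_never_below_r_min(self, path_net):
        r_min, r_max = r_bounds(path_net, {"A", "C"})
        assert r_min == 3 and r_max == 3


class TestFindAffectedSubnetwork:
    def test_hub_always_captured(self):
        edges = [("T", "HUB")] + [(f"N{i:02d}", "T") for i in range(25)]
        net = MolecularNetwork.from_edges(edges)
        w = {g: 0.0 for g in net.nodes}
        w["HUB"] = 10.0
        res = find_affected_subnetwork(net, w, {"T"})
        assert "HUB" in res.genes

    def test_equal_weights_prefer_largest_r(self):
        # score k*w/sqrt(k) = w*sqrt(k) grows with k
        edges = [(f"N{i}", f"N{i+1}") for i in range(19)]
        net = MolecularNetwork.from_edges(edges)
        w = {g: 1.0 for g in net.nodes}
        res = find_affected_subnetwork(net, w, {"N0"})
        _, r_max = r_bounds(net, {"N0"})
        assert res.size >= r_max

    def test_zero_weights_minimal_set(self, path_net):
        res = find_affected_subnetwork(path_net, {}, {"A"})
        assert res.normalized_score == 0.0
        assert res.genes == ("A",)

    def test_scan_table_returned(self, path_net):
        res, scan = find_affected_subnetwork(path_net, {"C": 1.0}, {"A"},
                                             return_scan=True)
        assert list(scan.columns) == ["R", "size", "objective",
                                      "normalized_score", "lp_integral"]


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(40))
    def test_exact_matches_brute_force(self, seed):
        net, weights, targets, R = random_instance(seed)
        try:
            bf_set, bf_obj = brute_force_oracle(net, weights, targets, R)
        except InfeasibleModelError:
            return
        model = build_model(net, targets, R, weights=weights)
        exact = solve(model, exact=True)
        relaxed = solve(model, exact=False)
        assert exact.objective == pytest.approx(bf_obj, abs=1e-6)
        assert relaxed.objective >= exact.objective - 1e-7
        # structural invariants at the integral optimum
        assert exact.x.sum() == pytest.approx(R, abs=1e-6)
        res = extract_subnetwork(model, exact)
        assert set(targets) <= set(res.genes)
        sub = net.graph.subgraph(res.genes)
        for comp in nx.connected_components(sub):
            assert comp & set(targets)

    def test_oracle_whole_network(self, path_net):
        sel, obj = brute_force_oracle(path_net, {"A": 1, "B": 2, "C": 3}, {"B"}, 3)
        assert sel == ("A", "B", "C") and obj == 6.0

    def test_oracle_infeasible_flagged(self):
        net = MolecularNetwork.from_edges([("A", "B"), ("C", "D")])
        with pytest.raises(InfeasibleModelError, match="infeasible"):
            brute_force_oracle(net, {}, {"A"}, 3)

    def test_oracle_size_guard(self):
        net = MolecularNetwork.from_edges(
            [(f"N{i}", f"N{i+1}") for i in range(20)])
        with pytest.raises(ValueError):
            brute_force_oracle(net, {}, {"N0"}, 2)


class TestModelResultsFacade:
    def test_fit_matches_functional_path(self, star_net):
        w = {"A": 1.0, "B": 5.0, "C": 1.0, "D": 0.0}
        res = AffectedSubnetworkModel(star_net, w, ["A"]).fit()
        best = find_affected_subnetwork(star_net, w, {"A"})
        assert res.genes == best.genes
        assert res.normalized_score == pytest.approx(best.normalized_score)

    def test_summary_mentions_key_fields(self, star_net):
        res = AffectedSubnetworkModel(star_net, {"B": 2.0}, ["A"]).fit()
        text = res.summary()
        assert "normalized score" in text and "targets" in text
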