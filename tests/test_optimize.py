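import itertools

import numpy as np
import pytest

from overmod import (
    Assignment,
    HardPartition,
    Network,
    SoftPartition,
    classify_connectors,
    classify_nodes,
    hard_modularity,
    qov,
    qov_membership,
    solve_exact,
    solve_multistart,
    strong_interconnectors,
)
from overmod.netio import PartitionError
from overmod.optimize import BudgetExceededError, _SearchState, module_aggregates
from conftest import random_instance


def hard_membership(hp):
    return {i: frozenset({m}) for i, m in hp.assignment.items()}


class TestQov:
    def test_reduces_to_hard_modularity(self, two_triangle):
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        asg = Assignment.from_hard(roles)
        assert qov(net, roles, asg) == pytest.approx(5.0 / 14.0, abs=1e-15)
        assert qov(net, roles, asg) == pytest.approx(hard_modularity(net, hp), abs=1e-15)

    def test_connector_in_both_modules(self, two_triangle):
        # c joins both triangles, d stays in module 2:
        # (3/7 - (7/14)^2) + (4/7 - (10/14)^2) = 5/28 + 3/49
        net, hp = two_triangle
        mem = hard_membership(hp)
        mem["c"] = frozenset({1, 2})
        assert qov_membership(net, mem) == pytest.approx(5 / 28 + 3 / 49, abs=1e-12)

    def test_single_module_zero(self, two_triangle):
        net, _ = two_triangle
        mem = {i: frozenset({1}) for i in net.nodes}
        assert qov_membership(net, mem) == pytest.approx(0.0, abs=1e-15)

    def test_infeasible_rejected(self, two_triangle):
        net, hp = two_triangle
        mem = hard_membership(hp)
        mem["c"] = frozenset()
        with pytest.raises(PartitionError):
            qov_membership(net, mem)

    def test_module_aggregates_loop_once(self):
        net = Network.from_edges([("a", "a", 2.0), ("a", "b", 1.0)])
        agg = module_aggregates(net, {"a": frozenset({1}), "b": frozenset({1})})
        assert agg.W[1] == pytest.approx(3.0)
        assert agg.S[1] == pytest.approx(3.0 + 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_hard_consistency_random(self, seed):
        net, hp, roles = random_instance(seed, n=14, p=0.3)
        asg = Assignment.from_hard(roles)
        assert qov(net, roles, asg) == pytest.approx(
            hard_modularity(net, hp), abs=1e-12
        )


class TestSolveExact:
    def test_two_triangle_optimum_is_hard(self, two_triangle):
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        sp = solve_exact(net, roles, hp)
        assert sp.qov == pytest.approx(5.0 / 14.0, abs=1e-12)
        assert all(len(ms) == 1 for ms in sp.membership.values())
        assert sp.roles["c"] == "intra" and sp.roles["d"] == "intra"

    def test_matches_naive_enumeration(self, two_triangle):
        # independent oracle: enumerate all feasible memberships directly
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        best = -np.inf
        subsets = [frozenset(s) for s in [{1}, {2}, {1, 2}]]
        for mc, md in itertools.product(subsets, subsets):
            mem = hard_membership(hp)
            mem["c"], mem["d"] = mc, md
            best = max(best, qov_membership(net, mem))
        assert solve_exact(net, roles, hp).qov == pytest.approx(best, abs=1e-12)

    def test_bridge_node_between_cliques(self):
        edges = [
            (f"a{i}", f"a{j}", 1.0) for i, j in itertools.combinations(range(4), 2)
        ] + [
            (f"b{i}", f"b{j}", 1.0) for i, j in itertools.combinations(range(4), 2)
        ] + [("v", f"a{i}", 1.0) for i in range(3)] + [("v", f"b{i}", 1.0) for i in range(3)]
        net = Network.from_edges(edges)
        hp = HardPartition(
            {**{f"a{i}": 1 for i in range(4)}, **{f"b{i}": 2 for i in range(4)}, "v": 1}
        )
        roles = classify_nodes(net, hp)
        sp = solve_exact(net, roles, hp)
        # frozen oracle outcome: v's options {1}, {2} and {1,2} tie at
        # Q_ov = 0.319444...; parsimony then lexicographic order keep {1}
        assert sp.membership["v"] == frozenset({1})
        assert sp.qov == pytest.approx(0.3194444444444444, abs=1e-9)
        assert all(sp.membership[f"b{i}"] == frozenset({2}) for i in range(3))
        assert sp.qov >= hard_modularity(net, hp) - 1e-12

    def test_zero_connectors_returns_hard(self):
        net = Network.from_edges([("a", "b", 1), ("c", "d", 1)])
        hp = HardPartition({"a": 1, "b": 1, "c": 2, "d": 2})
        roles = classify_nodes(net, hp)
        sp = solve_exact(net, roles, hp)
        assert sp.qov == pytest.approx(hard_modularity(net, hp), abs=1e-15)
        assert sp.membership == hard_membership(hp)

    def test_budget_refusal(self, two_triangle):
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        with pytest.raises(BudgetExceededError, match="solve_multistart"):
            solve_exact(net, roles, hp, max_vars=3)


class TestSolveMultistart:
    def test_dominates_hard_partition(self, two_triangle):
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        sp = solve_multistart(net, roles, hp, restarts=5, seed=0)
        assert sp.qov >= hard_modularity(net, hp) - 1e-12

    def test_deterministic(self, two_triangle):
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        a = solve_multistart(net, roles, hp, restarts=10, seed=3)
        b = solve_multistart(net, roles, hp, restarts=10, seed=3)
        assert a.membership == b.membership and a.qov == b.qov

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_on_small_instances(self, seed):
        net, hp, roles = random_instance(seed, n=10, p=0.35)
        n_pairs = sum(len(c) for c in roles.candidates.values())
        if n_pairs > 14:
            pytest.skip("instance too large for this unit check")
        exact = solve_exact(net, roles, hp, max_vars=10**6)
        ms = solve_multistart(net, roles, hp, restarts=100, seed=seed)
        assert ms.qov == pytest.approx(exact.qov, abs=1e-9)

    def test_zero_connectors(self):
        net = Network.from_edges([("a", "b", 1), ("c", "d", 1)])
        hp = HardPartition({"a": 1, "b": 1, "c": 2, "d": 2})
        roles = classify_nodes(net, hp)
        sp = solve_multistart(net, roles, hp, restarts=3, seed=0)
        assert sp.qov == pytest.approx(hard_modularity(net, hp), abs=1e-15)


class TestSearchState:
    def test_incremental_matches_full_recompute(self):
        net, hp, roles = random_instance(11, n=20, p=0.25)
        if not roles.candidates:
            pytest.skip("no connectors in instance")
        state = _SearchState(net, roles)
        x = {(i, m): int(m == roles.home[i]) for i, c in roles.candidates.items() for m in c}
        state.reset(x)
        assert state.q == pytest.approx(hard_modularity(net, hp), abs=1e-12)
        rng = np.random.default_rng(0)
        pairs = sorted(state.pairs)
        for _ in range(30):
            i, m = pairs[rng.integers(len(pairs))]
            if state.x[(i, m)] and state.n_mem[i] <= 1:
                continue
            predicted = state.q + state.delta(i, m)
            state.apply(i, m)
            assert state.q == pytest.approx(predicted, abs=1e-12)
            assert state.q == pytest.approx(state._full_q(), abs=1e-9)

    def test_monotone_improvement_during_climb(self):
        net, hp, roles = random_instance(5, n=16, p=0.3)
        if not roles.candidates:
            pytest.skip("no connectors in instance")
        state = _SearchState(net, roles)
        rng = np.random.default_rng(1)
        x = {pair: int(rng.integers(0, 2)) for pair in sorted(
            (i, m) for i, c in roles.candidates.items() for m in c)}
        for i in roles.candidates:
            if not any(x[(i, m)] for m in roles.candidates[i]):
                x[(i, roles.home[i])] = 1
        state.reset(x)
        qs = [state.q]
        while True:
            best_pair, best_d = None, 1e-10
            for pair in state.pairs:
                i, m = pair
                if state.x[pair] and state.n_mem[i] <= 1:
                    continue
                d = state.delta(*pair)
                if d > best_d:
                    best_pair, best_d = pair, d
            if best_pair is None:
                break
            state.apply(*best_pair)
            qs.append(state.q)
        assert all(b > a for a, b in zip(qs, qs[1:]))


class TestIsolatedNodeLemma:
    @pytest.mark.parametrize("seed", range(8))
    def test_foreign_module_addition_decreases_qov(self, seed):
        net, hp, roles = random_instance(seed, n=20, p=0.2)
        iso = sorted(roles.isolated)
        modules = sorted(hp.modules)
        checked = 0
        for i in iso:
            nbr_modules = {hp.assignment[j] for j in net.neighbors(i)} | {hp.assignment[i]}
            for m in modules:
                if m in nbr_modules:
                    continue
                mem = hard_membership(hp)
                base = qov_membership(net, mem)
                mem[i] = frozenset({hp.assignment[i], m})
                assert qov_membership(net, mem) < base
                checked += 1
        if checked == 0:
            pytest.skip("no neighbour-free foreign module in instance")


class TestClassifyConnectors:
    def test_roles(self, two_triangle):
        net, hp = two_triangle
        roles = classify_nodes(net, hp)
        sp = SoftPartition(
            membership={
                "a": frozenset({1}), "b": frozenset({1}), "c": frozenset({1, 2}),
                "d": frozenset({2}), "e": frozenset({2}), "f": frozenset({2}),
            },
            qov=0.0,
        )
        classify_connectors(sp, roles)
        assert sp.roles["c"] == "inter"
        assert sp.roles["d"] == "intra"
        assert sp.roles["a"] == "isolated"
        assert sp.role_counts() == {"isolated": 4, "intra": 1, "inter": 1}


def _sp_with_counts(counts):
    mem = {
        f"n{k:03d}": frozenset(range(1, c + 1)) for k, c in enumerate(counts)
    }
    return SoftPartition(membership=mem, qov=0.0)


class TestStrongInterconnectors:
    def test_threshold(self):
        sp = _sp_with_counts([3, 3, 2, 1])
        assert len(strong_interconnectors(sp, "threshold:3")) == 2

    def test_top10range_with_ties(self):
        counts = [6, 6] + [5] * 10 + [4, 4, 3, 2, 2]
        sp = _sp_with_counts(counts)
        assert len(strong_interconnectors(sp, "top10range")) == 12

    def test_no_interconnectors(self):
        sp = _sp_with_counts([1, 1, 1])
        assert strong_interconnectors(sp, "threshold:3") == set()
        assert strong_interconnectors(sp, "top10range") == set()

    def test_top10range_fallback_under_ten(self):
        sp = _sp_with_counts([3, 2, 2, 1, 1])
        assert len(strong_interconnectors(sp, "top10range")) == 3

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            strong_interconnectors(_sp_with_counts([2]), "bogus")
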