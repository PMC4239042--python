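"""Overlapping-modularity maximisation over binary connector assignments.

Isolated nodes stay frozen in their hard module; each connector may join
any subset of its candidate modules (its own plus the neighbouring ones),
subject to belonging to at least one.  The objective

    Q_ov = sum_m [ W_m / L - (S_m / 2L)^2 ]

is maximised either exactly (exhaustive enumeration, small instances) or
by seeded multi-start steepest-ascent local search over single-entry
flips of the binary membership matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Set, Tuple

import numpy as np

from .netio import HardPartition, Network, PartitionError, SoftPartition
from .partitioning import NodeRoles, hard_modularity

__all__ = [
    "Assignment",
    "ModuleAggregates",
    "BudgetExceededError",
    "qov",
    "solve_exact",
    "solve_multistart",
    "classify_connectors",
    "strong_interconnectors",
]

logger = logging.getLogger(__name__)

FLIP_TOL = 1e-10
_GUARD_INTERVAL = 1000  # full recomputation guard cadence (accepted flips)
_GUARD_DRIFT = 1e-9


class BudgetExceededError(RuntimeError):
    """Exact enumeration refused: instance larger than the configured budget."""


@dataclass(frozen=True)
class Assignment:
    """Binary membership x[(node, module)] over isolated and candidate pairs.

    Isolated entries are implicitly fixed at 1 for the node's hard module;
    only connector candidate pairs are stored explicitly.
    """

    connector_x: Mapping[Tuple[str, int], int]
    roles: NodeRoles

    def membership(self) -> Dict[str, FrozenSet[int]]:
        mem: Dict[str, Set[int]] = {}
        for m, nodes in self.roles.isolated_by_module.items():
            for i in nodes:
                mem[i] = {m}
        for (i, m), x in self.connector_x.items():
            if x:
                mem.setdefault(i, set()).add(m)
        return {i: frozenset(ms) for i, ms in mem.items()}

    def validate(self) -> None:
        counts: Dict[str, int] = {i: 0 for i in self.roles.candidates}
        for (i, m), x in self.connector_x.items():
            if m not in self.roles.candidates[i]:
                raise PartitionError(f"({i}, {m}) is not a candidate pair")
            counts[i] += int(bool(x))
        infeasible = [i for i, c in counts.items() if c == 0]
        if infeasible:
            raise PartitionError(
                f"connectors with zero memberships: {sorted(infeasible)[:5]}"
            )

    @classmethod
    def from_hard(cls, roles: NodeRoles) -> "Assignment":
        x = {
            (i, m): int(m == roles.home[i])
            for i, cands in roles.candidates.items()
            for m in cands
        }
        return cls(connector_x=x, roles=roles)


@dataclass(frozen=True)
class ModuleAggregates:
    """Per-module strength sums S_m and internal edge weights W_m."""

    S: Mapping[int, float]
    W: Mapping[int, float]


def module_aggregates(net: Network, membership: Mapping[str, FrozenSet[int]]) -> ModuleAggregates:
    S: Dict[int, float] = {}
    W: Dict[int, float] = {}
    for i, mods in membership.items():
        s_i = net.strength(i)
        for m in mods:
            S[m] = S.get(m, 0.0) + s_i
    for u, v, w in net.edges():
        for m in membership[u]:
            if m in membership[v]:
                W[m] = W.get(m, 0.0) + w
    return ModuleAggregates(S=S, W=W)


def qov(net: Network, roles: NodeRoles, asg: Assignment) -> float:
    """Overlapping modularity of a feasible assignment."""
    asg.validate()
    return qov_membership(net, asg.membership())


def qov_membership(net: Network, membership: Mapping[str, FrozenSet[int]]) -> float:
    """Q_ov evaluated directly on a node -> module-set map."""
    for i in net.nodes:
        if not membership.get(i):
            raise PartitionError(f"node {i!r} has no module membership")
    L = net.total_weight
    agg = module_aggregates(net, membership)
    modules = set(agg.S) | set(agg.W)
    return sum(
        agg.W.get(m, 0.0) / L - (agg.S.get(m, 0.0) / (2.0 * L)) ** 2 for m in modules
    )


# ---------------------------------------------------------------------------
# exact solver


def solve_exact(
    net: Network,
    roles: NodeRoles,
    hp: HardPartition,
    max_vars: int = 4096,
) -> SoftPartition:
    """Globally optimal assignment by exhaustive enumeration.

    Refuses when the number of feasible combinations (the product over
    connectors of 2^|candidates| - 1) exceeds ``max_vars``.  Ties are
    broken by fewest total memberships, then lexicographically smallest
    membership sets over sorted node ids.
    """
    connectors = sorted(roles.candidates)
    n_combos = 1
    for i in connectors:
        n_combos *= 2 ** len(roles.candidates[i]) - 1
        if n_combos > max_vars:
            raise BudgetExceededError(
                f"{n_combos}+ feasible assignments exceed budget {max_vars}; "
                "use solve_multistart instead"
            )

    base = {
        i: frozenset({m})
        for m, nodes in roles.isolated_by_module.items()
        for i in nodes
    }
    per_node_choices: List[List[FrozenSet[int]]] = []
    for i in connectors:
        cands = sorted(roles.candidates[i])
        subsets = [
            frozenset(c)
            for r in range(1, len(cands) + 1)
            for c in itertools.combinations(cands, r)
        ]
        subsets.sort(key=lambda s: (len(s), tuple(sorted(s))))
        per_node_choices.append(subsets)

    best_q = -np.inf
    best_key = None
    best_membership = None
    for choice in itertools.product(*per_node_choices):
        membership = dict(base)
        for i, mods in zip(connectors, choice):
            membership[i] = mods
        q = qov_membership(net, membership)
        key = (
            sum(len(mods) for mods in choice),
            tuple(tuple(sorted(mods)) for mods in choice),
        )
        if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and key < best_key):
            best_q, best_key, best_membership = q, key, membership

    if best_membership is None:  # zero connectors
        best_membership = base
        best_q = hard_modularity(net, hp)
    sp = SoftPartition(membership=dict(best_membership), qov=float(best_q))
    return classify_connectors(sp, roles)


# ---------------------------------------------------------------------------
# multi-start local search


class _SearchState:
    """Incrementally maintained S_m, W_m and per-pair in-module weights.

    ``w_in[(i, m)]`` is the total weight from connector i to current
    members of m (neighbours only, the self-loop handled separately), so a
    flip's objective change is O(1) and applying a flip is O(deg).
    """

    def __init__(self, net: Network, roles: NodeRoles):
        self.net = net
        self.roles = roles
        self.L = net.total_weight
        self.s = net.strengths()
        self.pairs: List[Tuple[str, int]] = sorted(
            (i, m) for i, cands in roles.candidates.items() for m in cands
        )
        # static per-connector neighbour lists restricted to candidate modules
        self.nbrs: Dict[str, List[Tuple[str, float]]] = {
            i: [(j, w) for j, w in net.adj[i].items() if j != i]
            for i in roles.candidates
        }
        self.loop = {i: net.loop_weight(i) for i in roles.candidates}
        # base aggregates from frozen isolated nodes
        self.base_S: Dict[int, float] = {m: 0.0 for m in roles.isolated_by_module}
        self.base_W: Dict[int, float] = {m: 0.0 for m in roles.isolated_by_module}
        iso_home = {}
        for m, nodes in roles.isolated_by_module.items():
            for i in nodes:
                iso_home[i] = m
                self.base_S[m] += self.s[i]
        for u, v, w in net.edges():
            if u in iso_home and v in iso_home and iso_home[u] == iso_home[v]:
                self.base_W[iso_home[u]] += w
        self.iso_home = iso_home

    def reset(self, x: Dict[Tuple[str, int], int]) -> None:
        self.x = x
        self.n_mem = {i: 0 for i in self.roles.candidates}
        self.S = dict(self.base_S)
        self.W = dict(self.base_W)
        self.w_in = {}
        members: Dict[int, Set[str]] = {
            m: set(nodes) for m, nodes in self.roles.isolated_by_module.items()
        }
        for (i, m), xi in x.items():
            if xi:
                members.setdefault(m, set()).add(i)
                self.n_mem[i] += 1
        for (i, m), xi in x.items():
            self.w_in[(i, m)] = sum(
                wij for j, wij in self.nbrs[i] if j in members.get(m, ())
            )
            if xi:
                self.S[m] = self.S.get(m, 0.0) + self.s[i]
        # W from scratch: connector-involved edges internal to each module
        for m, mem in members.items():
            w_m = self.base_W.get(m, 0.0)
            for i in mem:
                if i in self.roles.candidates:  # connector
                    w_m += self.loop[i]
                    for j, wij in self.nbrs[i]:
                        if j in mem and (j not in self.roles.candidates or j < i):
                            w_m += wij
            self.W[m] = w_m
        self.q = self._full_q()
        self.flips_since_guard = 0

    def _full_q(self) -> float:
        mods = set(self.S) | set(self.W)
        return sum(
            self.W.get(m, 0.0) / self.L - (self.S.get(m, 0.0) / (2.0 * self.L)) ** 2
            for m in mods
        )

    def delta(self, i: str, m: int) -> float:
        """Objective change of flipping x[(i, m)]."""
        s_i = self.s[i]
        w = self.w_in[(i, m)] + self.loop[i]
        S_m = self.S.get(m, 0.0)
        L = self.L
        if self.x[(i, m)]:
            return -w / L + (2.0 * S_m * s_i - s_i * s_i) / (4.0 * L * L)
        return w / L - (2.0 * S_m * s_i + s_i * s_i) / (4.0 * L * L)

    def apply(self, i: str, m: int) -> None:
        d = self.delta(i, m)
        if self.x[(i, m)]:
            self.x[(i, m)] = 0
            self.n_mem[i] -= 1
            self.S[m] -= self.s[i]
            self.W[m] = self.W.get(m, 0.0) - self.w_in[(i, m)] - self.loop[i]
            sign = -1.0
        else:
            self.x[(i, m)] = 1
            self.n_mem[i] += 1
            self.S[m] = self.S.get(m, 0.0) + self.s[i]
            self.W[m] = self.W.get(m, 0.0) + self.w_in[(i, m)] + self.loop[i]
            sign = 1.0
        for j, wij in self.nbrs[i]:
            key = (j, m)
            if key in self.w_in:
                self.w_in[key] += sign * wij
        self.q += d
        self.flips_since_guard += 1
        if self.flips_since_guard >= _GUARD_INTERVAL:
            exact = self._full_q()
            assert abs(exact - self.q) < _GUARD_DRIFT, (
                f"incremental Q_ov drifted by {abs(exact - self.q):.3e}"
            )
            self.q = exact
            self.flips_since_guard = 0

    def hill_climb(self, tol: float = FLIP_TOL) -> float:
        """Steepest ascent over single-entry flips; returns final Q_ov."""
        while True:
            best_pair, best_d = None, tol
            for pair in self.pairs:
                i, m = pair
                if self.x[pair] and self.n_mem[i] <= 1:
                    continue  # removal would violate the >=1-membership constraint
                d = self.delta(i, m)
                if d > best_d:
                    best_pair, best_d = pair, d
            if best_pair is None:
                return self.q
            logger.debug("flip %s delta=%.3e", best_pair, best_d)
            self.apply(*best_pair)


def solve_multistart(
    net: Network,
    roles: NodeRoles,
    hp: HardPartition,
    restarts: int = 100,
    seed: int = 0,
    tol: float = FLIP_TOL,
) -> SoftPartition:
    """Best-of-restarts randomised local search.

    Each restart draws every candidate entry uniformly from {0, 1},
    repairs all-zero connectors by activating their hard module, then
    hill-climbs with steepest-ascent single-entry flips.  Restart r draws
    from a stream derived from (seed, r), so increasing ``restarts``
    extends rather than reshuffles the sequence.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    state = _SearchState(net, roles)
    best_q = -np.inf
    best_x = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        draws = rng.integers(0, 2, size=len(state.pairs))
        x = {pair: int(d) for pair, d in zip(state.pairs, draws)}
        # repair: a connector with no membership re-enters its hard module
        active: Dict[str, int] = {i: 0 for i in roles.candidates}
        for (i, m), xi in x.items():
            active[i] += xi
        for i, count in active.items():
            if count == 0:
                x[(i, roles.home[i])] = 1
        state.reset(x)
        q = state.hill_climb(tol=tol)
        logger.info("restart %d: Q_ov=%.10f", r, q)
        if q > best_q + tol:
            best_q = q
            best_x = dict(state.x)

    if best_x is None:  # zero connectors: hard partition is the only solution
        asg = Assignment.from_hard(roles)
        sp = SoftPartition(membership=asg.membership(), qov=hard_modularity(net, hp))
        return classify_connectors(sp, roles)

    asg = Assignment(connector_x=best_x, roles=roles)
    sp = SoftPartition(membership=asg.membership(), qov=float(best_q))
    return classify_connectors(sp, roles)


# ---------------------------------------------------------------------------
# connector classification


def classify_connectors(sp: SoftPartition, roles: NodeRoles) -> SoftPartition:
    """Label every node isolated, intra or inter in place and return sp."""
    iso = roles.isolated
    for i, mods in sp.membership.items():
        if i in iso:
            sp.roles[i] = "isolated"
        elif len(mods) >= 2:
            sp.roles[i] = "inter"
        else:
            sp.roles[i] = "intra"
    sp.validate()
    return sp


def strong_interconnectors(sp: SoftPartition, rule: str = "threshold:3") -> Set[str]:
    """Select the strongest inter-connectors.

    ``threshold:k`` keeps nodes with at least k memberships;
    ``top10range`` keeps every node with at least as many memberships as
    the 10th most multi-clustered node (ties included).  With fewer than
    10 inter-connectors the latter falls back to all of them.
    """
    counts = {i: len(ms) for i, ms in sp.membership.items() if len(ms) >= 2}
    if rule.startswith("threshold:"):
        k = int(rule.split(":", 1)[1])
        return {i for i, ms in sp.membership.items() if len(ms) >= k}
    if rule == "top10range":
        if not counts:
            return set()
        if len(counts) < 10:
            logger.warning(
                "top10range: only %d inter-connectors; returning all", len(counts)
            )
            return set(counts)
        tenth = sorted(counts.values(), reverse=True)[9]
        return {i for i, c in counts.items() if c >= tenth}
    raise ValueError(f"unknown strong-interconnector rule {rule!r}")
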