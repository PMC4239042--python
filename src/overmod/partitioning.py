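"""Hard-partition utilities: node classification, modularity, a convenience
greedy optimiser and set similarity.

The convenience optimiser stands in for any external hard-partition method;
downstream stages accept any externally produced partition file equally.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, Mapping, Set

from .netio import HardPartition, Network, PartitionError

__all__ = [
    "NodeRoles",
    "classify_nodes",
    "hard_modularity",
    "greedy_hard_partition",
    "jaccard",
]


@dataclass(frozen=True)
class NodeRoles:
    """Per-module isolated/connector sets plus connector candidate modules.

    ``isolated_by_module[m]`` are the nodes of module m whose every
    neighbour (self excluded) also lies in m; ``connectors_by_module[m]``
    contains both m's own connectors and outside nodes with a neighbour in
    m.  ``candidates[i]`` is the set of modules connector i may join: its
    hard module plus every foreign module holding at least one neighbour.
    """

    isolated_by_module: Mapping[int, FrozenSet[str]]
    connectors_by_module: Mapping[int, FrozenSet[str]]
    candidates: Mapping[str, FrozenSet[int]]
    home: Mapping[str, int]

    @property
    def connectors(self) -> Set[str]:
        return set(self.candidates)

    @property
    def isolated(self) -> Set[str]:
        out: Set[str] = set()
        for nodes in self.isolated_by_module.values():
            out |= nodes
        return out


def classify_nodes(net: Network, hp: HardPartition) -> NodeRoles:
    """Split nodes into isolated and connector sets per module.

    A node is isolated iff all its neighbours (self-loops never count)
    lie in its own hard module; otherwise it is a connector with candidate
    modules = its own module plus every neighbouring foreign module.
    """
    hp.validate_cover(net)
    home = {i: hp.assignment[i] for i in net.nodes}
    isolated: Dict[int, set] = {m: set() for m in hp.modules}
    connectors: Dict[int, set] = {m: set() for m in hp.modules}
    candidates: Dict[str, FrozenSet[int]] = {}

    for i in net.nodes:
        h = home[i]
        foreign = {home[j] for j in net.neighbors(i) if home[j] != h}
        if not foreign:
            isolated[h].add(i)
        else:
            cand = frozenset({h} | foreign)
            candidates[i] = cand
            for m in cand:
                connectors[m].add(i)

    return NodeRoles(
        isolated_by_module={m: frozenset(s) for m, s in isolated.items()},
        connectors_by_module={m: frozenset(s) for m, s in connectors.items()},
        candidates=candidates,
        home=home,
    )


def hard_modularity(net: Network, hp: HardPartition) -> float:
    """Modularity of a disjoint partition: sum_m [W_m/L - (S_m/2L)^2]."""
    hp.validate_cover(net)
    L = net.total_weight
    if L <= 0:
        raise PartitionError("network has zero total weight")
    S: Dict[int, float] = {m: 0.0 for m in hp.modules}
    W: Dict[int, float] = {m: 0.0 for m in hp.modules}
    for i in net.nodes:
        S[hp.assignment[i]] += net.strength(i)
    for u, v, w in net.edges():
        if hp.assignment[u] == hp.assignment[v]:
            W[hp.assignment[u]] += w
    return sum(W[m] / L - (S[m] / (2.0 * L)) ** 2 for m in hp.modules)


def jaccard(set_a: Set[str], set_b: Set[str]) -> float:
    """|A n B| / |A u B|; defined as 1 when both sets are empty."""
    if not set_a and not set_b:
        return 1.0
    return len(set_a & set_b) / len(set_a | set_b)


# ---------------------------------------------------------------------------
# greedy hard-partition optimiser (Louvain-style local moving + aggregation)
#
# Convenience only: runs on the loop-free view of the network with the
# textbook doubled-strength convention; the returned partition's quality is
# always re-measured with hard_modularity.  Deterministic given the seed:
# node visit order is shuffled once per pass, ties go to the lowest
# community id.


def greedy_hard_partition(net: Network, seed: int = 0, tol: float = 1e-10) -> HardPartition:
    rng = random.Random(seed)
    nodes = sorted(net.nodes)
    # loop-free adjacency for the optimiser
    adj: Dict[int, Dict[int, float]] = {}
    index = {v: k for k, v in enumerate(nodes)}
    for k, v in enumerate(nodes):
        adj[k] = {
            index[u]: w for u, w in net.adj[v].items() if u != v
        }
    # each super-node carries its internal (already-merged) weight
    internal = [0.0 for _ in nodes]
    membership_stack = []  # per level: list mapping super-node -> community

    m = sum(w for nbrs in adj.values() for w in nbrs.values()) / 2.0
    if m <= 0:
        # edgeless network: every node its own module
        return HardPartition({v: k + 1 for k, v in enumerate(nodes)})

    while True:
        comm = _local_moving(adj, internal, m, rng, tol)
        membership_stack.append(comm)
        n_comms = len(set(comm))
        if n_comms == len(adj):
            break
        adj, internal = _aggregate(adj, internal, comm)

    # flatten levels down to original nodes
    flat = list(range(len(nodes)))
    for comm in membership_stack:
        flat = [comm[c] for c in flat]
    relabel = {c: k + 1 for k, c in enumerate(sorted(set(flat)))}
    return HardPartition({nodes[i]: relabel[flat[i]] for i in range(len(nodes))})


def _local_moving(adj, internal, m, rng, tol):
    n = len(adj)
    comm = list(range(n))
    degree = [sum(adj[v].values()) + 2.0 * internal[v] for v in range(n)]
    s_tot = degree[:]  # community strength sums (degree incl. internal twice)
    size = [1] * n

    order = list(range(n))
    improved = True
    while improved:
        improved = False
        rng.shuffle(order)
        for v in order:
            cv = comm[v]
            k_v = degree[v]
            # weight from v to each neighbouring community
            links: Dict[int, float] = {}
            for u, w in adj[v].items():
                links[comm[u]] = links.get(comm[u], 0.0) + w
            # detach v from its community
            s_tot[cv] -= k_v
            size[cv] -= 1
            k_v_cv = links.get(cv, 0.0)
            base = k_v_cv / m - s_tot[cv] * k_v / (2.0 * m * m)
            # sorted scan + strict improvement => lowest community id wins ties
            best_c, best_gain = cv, 0.0
            for c in sorted(links):
                if c == cv:
                    continue
                gain = links[c] / m - s_tot[c] * k_v / (2.0 * m * m) - base
                if gain > best_gain + tol:
                    best_c, best_gain = c, gain
            comm[v] = best_c
            s_tot[best_c] += k_v
            size[best_c] += 1
            if best_c != cv:
                improved = True
    # compact community labels
    relabel = {c: k for k, c in enumerate(sorted(set(comm)))}
    return [relabel[c] for c in comm]


def _aggregate(adj, internal, comm):
    n_comms = len(set(comm))
    new_adj: Dict[int, Dict[int, float]] = {c: {} for c in range(n_comms)}
    new_internal = [0.0] * n_comms
    for v, nbrs in adj.items():
        cv = comm[v]
        new_internal[cv] += internal[v]
        for u, w in nbrs.items():
            cu = comm[u]
            if cu == cv:
                if u > v:
                    new_internal[cv] += w
            else:
                new_adj[cv][cu] = new_adj[cv].get(cu, 0.0) + w
    return new_adj, new_internal
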