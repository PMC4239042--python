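"""Network, partition and soft-partition I/O.

Text formats only:

* edge list — whitespace-separated ``node1 node2 [weight]`` lines,
  ``#`` comments and blank lines ignored, undirected, duplicate lines
  summed, self-loops permitted;
* hard partition — ``node<TAB>module_id``;
* soft partition — ``node<TAB>comma-joined sorted module ids<TAB>role``
  with the header line ``#node\tmodules\trole``.

Loop accounting convention (isolated here, used package-wide): a self-loop
of weight ``a_ii`` contributes once to the node strength ``s_i`` and once
to the total edge weight ``L``, hence ``sum_i s_i = 2L - sum_i a_ii``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Set, Tuple

import networkx as nx

__all__ = [
    "Network",
    "HardPartition",
    "SoftPartition",
    "NetworkFormatError",
    "PartitionError",
    "read_edgelist",
    "read_partition",
    "write_partition",
    "read_soft_partition",
    "write_soft_partition",
    "main_component",
]

ROLES = ("isolated", "intra", "inter")


class NetworkFormatError(ValueError):
    """Raised on malformed or invalid network input."""


class PartitionError(ValueError):
    """Raised when a partition does not cover a network consistently."""


@dataclass(frozen=True)
class Network:
    """Undirected weighted graph with optional self-loops.

    ``adj`` is a symmetric dict-of-dicts; a self-loop is stored once as
    ``adj[i][i]``.  Strengths and the total weight follow the
    loop-counted-once convention documented in the module docstring.
    """

    adj: Mapping[str, Mapping[str, float]]

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str, float]]) -> "Network":
        """Build a network from ``(u, v, w)`` triples, summing duplicates."""
        adj: Dict[str, Dict[str, float]] = {}
        for u, v, w in edges:
            if w <= 0:
                raise NetworkFormatError(
                    f"non-positive edge weight {w!r} on edge ({u}, {v})"
                )
            adj.setdefault(u, {})
            adj.setdefault(v, {})
            adj[u][v] = adj[u].get(v, 0.0) + float(w)
            if u != v:
                adj[v][u] = adj[v].get(u, 0.0) + float(w)
        return cls(adj)

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> Set[str]:
        return set(self.adj)

    @property
    def n_nodes(self) -> int:
        return len(self.adj)

    def __contains__(self, node: str) -> bool:
        return node in self.adj

    def weight(self, u: str, v: str) -> float:
        return self.adj.get(u, {}).get(v, 0.0)

    def neighbors(self, node: str) -> Iterator[str]:
        """Neighbours of ``node`` excluding the node itself."""
        for v in self.adj[node]:
            if v != node:
                yield v

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        """Each unordered edge once, loops as ``(i, i, a_ii)``."""
        for u, nbrs in self.adj.items():
            for v, w in nbrs.items():
                if u <= v:
                    yield u, v, w

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def strength(self, node: str) -> float:
        """s_i = sum_j a_ij, the self-loop counted once."""
        return sum(self.adj[node].values())

    def strengths(self) -> Dict[str, float]:
        return {i: self.strength(i) for i in self.adj}

    @property
    def total_weight(self) -> float:
        """L = sum of all edge weights, each loop counted once."""
        return sum(w for _, _, w in self.edges())

    def loop_weight(self, node: str) -> float:
        return self.adj[node].get(node, 0.0)

    # -- derived views -----------------------------------------------------

    def subgraph(self, keep: Set[str]) -> "Network":
        adj = {
            u: {v: w for v, w in nbrs.items() if v in keep}
            for u, nbrs in self.adj.items()
            if u in keep
        }
        return Network(adj)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adj)
        g.add_weighted_edges_from(self.edges())
        return g


@dataclass(frozen=True)
class HardPartition:
    """Disjoint, exhaustive node -> module assignment."""

    assignment: Mapping[str, int]

    @property
    def modules(self) -> Set[int]:
        return set(self.assignment.values())

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def members(self, module: int) -> Set[str]:
        return {i for i, m in self.assignment.items() if m == module}

    def module_of(self, node: str) -> int:
        return self.assignment[node]

    def validate_cover(self, net: Network) -> None:
        missing = net.nodes - set(self.assignment)
        if missing:
            raise PartitionError(
                f"partition does not cover {len(missing)} node(s), "
                f"e.g. {sorted(missing)[:5]}"
            )


@dataclass
class SoftPartition:
    """Node -> non-empty module-set map plus objective value and roles."""

    membership: Dict[str, FrozenSet[int]]
    qov: float
    roles: Dict[str, str] = field(default_factory=dict)

    def multi_clustered(self) -> Set[str]:
        return {i for i, ms in self.membership.items() if len(ms) >= 2}

    def role_counts(self) -> Dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for r in self.roles.values():
            counts[r] += 1
        return counts

    def validate(self) -> None:
        for node, ms in self.membership.items():
            if not ms:
                raise PartitionError(f"node {node!r} has no module membership")
            role = self.roles.get(node)
            if role == "inter" and len(ms) < 2:
                raise PartitionError(f"node {node!r} marked inter with one module")
            if role in ("isolated", "intra") and len(ms) != 1:
                raise PartitionError(f"node {node!r} marked {role} with {len(ms)} modules")


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: str) -> Iterator[Tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edgelist(path: str, weighted: bool = False) -> Network:
    """Parse a whitespace-separated edge list into a :class:`Network`.

    Duplicate ``(i, j)``/``(j, i)`` lines collapse by summing their
    weights; loop lines ``(i, i)`` are accepted.
    """
    edges = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if weighted:
            if len(fields) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 'node node weight', got {line!r}"
                )
            u, v, ws = fields
            try:
                w = float(ws)
            except ValueError as exc:
                raise NetworkFormatError(
                    f"{path}:{lineno}: weight {ws!r} is not a number"
                ) from exc
        else:
            if len(fields) == 3:
                # tolerate a weight column when the caller asked for
                # unweighted parsing only if it is exactly 1
                u, v, ws = fields
                if ws not in ("1", "1.0"):
                    raise NetworkFormatError(
                        f"{path}:{lineno}: weight column present; pass weighted=True"
                    )
            elif len(fields) == 2:
                u, v = fields
            else:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            w = 1.0
        if w <= 0:
            raise NetworkFormatError(
                f"{path}:{lineno}: non-positive weight {w}"
            )
        edges.append((u, v, w))
    if not edges:
        raise NetworkFormatError(f"{path}: no edges found")
    return Network.from_edges(edges)


def main_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties are broken by the lexicographically smallest member node.
    """
    if not net.adj:
        raise NetworkFormatError("empty network has no main component")
    comps = [set(c) for c in nx.connected_components(net.to_networkx())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return net.subgraph(comps[0])


def read_partition(path: str) -> HardPartition:
    assignment: Dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise PartitionError(
                f"{path}:{lineno}: expected 'node module_id', got {line!r}"
            )
        node, ms = fields
        try:
            module = int(ms)
        except ValueError as exc:
            raise PartitionError(
                f"{path}:{lineno}: module id {ms!r} is not an integer"
            ) from exc
        if node in assignment and assignment[node] != module:
            raise PartitionError(
                f"{path}:{lineno}: node {node!r} listed twice with different modules"
            )
        assignment[node] = module
    if not assignment:
        raise PartitionError(f"{path}: empty partition")
    return HardPartition(assignment)


def write_partition(hp: HardPartition, path: str, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for node in sorted(hp.assignment):
            fh.write(f"{node}\t{hp.assignment[node]}\n")


def write_soft_partition(sp: SoftPartition, path: str, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"# qov\t{sp.qov!r}\n")
        fh.write("#node\tmodules\trole\n")
        for node in sorted(sp.membership):
            mods = ",".join(str(m) for m in sorted(sp.membership[node]))
            role = sp.roles.get(node, "intra")
            fh.write(f"{node}\t{mods}\t{role}\n")


def read_soft_partition(path: str) -> SoftPartition:
    membership: Dict[str, FrozenSet[int]] = {}
    roles: Dict[str, str] = {}
    qov = float("nan")
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# qov\t"):
                qov = float(line.split("\t", 1)[1])
                continue
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise PartitionError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            node, mods, role = fields
            if role not in ROLES:
                raise PartitionError(f"{path}:{lineno}: unknown role {role!r}")
            membership[node] = frozenset(int(m) for m in mods.split(","))
            roles[node] = role
    sp = SoftPartition(membership=membership, qov=qov, roles=roles)
    sp.validate()
    return sp
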