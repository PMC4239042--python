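"""Planted overlapping-community benchmark generator and recovery scoring.

A simplified planted-partition generator with near-uniform degrees stands
in for degree/size power-law benchmark generators: nodes split evenly
across modules, a chosen set of O_n nodes receives O_m memberships, every
node targets ``avg_degree`` with an expected fraction 1-mu of its edges
to co-members (nodes sharing at least one module) and mu to
non-co-members.  Stubs are paired at random with rejection of loops,
duplicates and (for the between-module stubs) co-member pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .netio import Network, main_component
from .optimize import solve_multistart
from .partitioning import classify_nodes, greedy_hard_partition, jaccard

__all__ = [
    "BenchmarkTruth",
    "generate",
    "recovery_jaccard",
    "benchmark_suite",
    "write_truth",
    "read_truth",
]

_PAIRING_ROUNDS = 8  # reshuffle-and-retry rounds for colliding stubs


@dataclass(frozen=True)
class BenchmarkTruth:
    """Planted memberships plus the generating parameters."""

    membership: Mapping[str, FrozenSet[int]]
    n: int
    avg_degree: float
    n_modules: int
    O_n: int
    O_m: int
    mu: float
    seed: int

    @property
    def overlapping_nodes(self) -> Set[str]:
        return {i for i, ms in self.membership.items() if len(ms) >= 2}

    def restrict(self, keep: Set[str]) -> "BenchmarkTruth":
        return BenchmarkTruth(
            membership={i: ms for i, ms in self.membership.items() if i in keep},
            n=self.n,
            avg_degree=self.avg_degree,
            n_modules=self.n_modules,
            O_n=self.O_n,
            O_m=self.O_m,
            mu=self.mu,
            seed=self.seed,
        )


def _round_counts(targets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic rounding preserving the expected total."""
    floors = np.floor(targets)
    return (floors + (rng.random(len(targets)) < targets - floors)).astype(int)


def _pair_stubs(
    stubs: List[str],
    rng: np.random.Generator,
    edges: Set[Tuple[str, str]],
    allowed,
) -> None:
    """Randomly match stubs into new simple edges; colliding stubs get
    reshuffled a few rounds, stragglers are dropped."""
    pool = stubs
    for _ in range(_PAIRING_ROUNDS):
        if len(pool) < 2:
            return
        rng.shuffle(pool)
        leftovers: List[str] = []
        for a, b in zip(pool[0::2], pool[1::2]):
            key = (a, b) if a < b else (b, a)
            if a == b or key in edges or not allowed(a, b):
                leftovers.extend((a, b))
            else:
                edges.add(key)
        if len(pool) % 2:
            leftovers.append(pool[-1])
        pool = leftovers


def generate(
    n: int = 500,
    avg_degree: float = 10.0,
    n_modules: int = 10,
    O_n: int = 75,
    O_m: int = 4,
    mu: float = 0.05,
    seed: int = 0,
    connected_only: bool = True,
) -> Tuple[Network, BenchmarkTruth]:
    """Generate one benchmark network with planted overlap.

    Returns the network (its main component when ``connected_only``, the
    truth restricted accordingly) and the ground truth.  Fully
    deterministic given ``seed``.
    """
    if not 0 <= mu < 1:
        raise ValueError("mu must be in [0, 1)")
    if O_m > n_modules:
        raise ValueError("O_m cannot exceed n_modules")
    if O_n > n:
        raise ValueError("O_n cannot exceed n")
    if avg_degree >= n / n_modules and mu == 0:
        raise ValueError("internal degree target exceeds module size")

    rng = np.random.default_rng([seed])
    width = len(str(n - 1))
    names = [f"n{idx:0{width}d}" for idx in range(n)]
    membership: Dict[str, Set[int]] = {
        names[idx]: {idx % n_modules + 1} for idx in range(n)
    }
    overlap_idx = rng.choice(n, size=O_n, replace=False)
    for idx in sorted(overlap_idx):
        node = names[idx]
        others = [m for m in range(1, n_modules + 1) if m not in membership[node]]
        extra = rng.choice(len(others), size=O_m - 1, replace=False)
        membership[node] |= {others[e] for e in extra}

    mem_frozen = {i: frozenset(ms) for i, ms in membership.items()}
    by_module: Dict[int, List[str]] = {m: [] for m in range(1, n_modules + 1)}
    for i in sorted(mem_frozen):
        for m in mem_frozen[i]:
            by_module[m].append(i)

    edges: Set[Tuple[str, str]] = set()

    # within-module stubs: (1-mu)·k per node, split evenly across memberships
    internal_target = avg_degree * (1.0 - mu)
    for m in range(1, n_modules + 1):
        members = by_module[m]
        targets = np.array([internal_target / len(mem_frozen[i]) for i in members])
        counts = _round_counts(targets, rng)
        stubs = [i for i, c in zip(members, counts) for _ in range(c)]
        _pair_stubs(stubs, rng, edges, allowed=lambda a, b: True)

    # between-module stubs: mu·k per node, endpoints must share no module
    ext_counts = _round_counts(np.full(n, avg_degree * mu), rng)
    stubs = [names[idx] for idx, c in enumerate(ext_counts) for _ in range(c)]
    _pair_stubs(
        stubs, rng, edges, allowed=lambda a, b: not (mem_frozen[a] & mem_frozen[b])
    )

    net = Network.from_edges((u, v, 1.0) for u, v in sorted(edges))
    truth = BenchmarkTruth(
        membership=mem_frozen,
        n=n,
        avg_degree=avg_degree,
        n_modules=n_modules,
        O_n=O_n,
        O_m=O_m,
        mu=mu,
        seed=seed,
    )
    if connected_only:
        net = main_component(net)
        truth = truth.restrict(net.nodes)
    return net, truth


def realized_mixing(net: Network, truth: BenchmarkTruth) -> float:
    """Fraction of edges whose endpoints share no planted module."""
    between = total = 0
    for u, v, _ in net.edges():
        if u == v:
            continue
        total += 1
        if not (truth.membership[u] & truth.membership[v]):
            between += 1
    return between / total if total else 0.0


def recovery_jaccard(predicted_multi: Set[str], truth: BenchmarkTruth) -> float:
    """Jaccard between predicted and planted multi-clustered node sets."""
    return jaccard(set(predicted_multi), truth.overlapping_nodes)


def benchmark_suite(
    param_grid: Sequence[Dict],
    replicates: int = 10,
    restarts: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Full recovery pipeline over a parameter grid.

    Per cell and replicate: generate, detect a hard partition with the
    built-in greedy optimiser, classify nodes, convert with the
    multi-start solver, and score inter-connectors against the planted
    overlapping nodes.
    """
    rows = []
    for cell_idx, params in enumerate(param_grid):
        values = []
        for rep in range(replicates):
            rep_seed = seed * 100003 + cell_idx * 1009 + rep
            try:
                net, truth = generate(seed=rep_seed, **params)
                hp = greedy_hard_partition(net, seed=rep_seed)
                roles = classify_nodes(net, hp)
                sp = solve_multistart(
                    net, roles, hp, restarts=restarts, seed=rep_seed
                )
                predicted = {i for i, r in sp.roles.items() if r == "inter"}
                values.append(recovery_jaccard(predicted, truth))
            except Exception as exc:  # annotate failures with the grid cell
                raise RuntimeError(
                    f"benchmark cell {params} replicate {rep} failed"
                ) from exc
        rows.append(
            {
                **params,
                "replicates": replicates,
                "mean_jaccard": float(np.mean(values)),
                "std_jaccard": float(np.std(values)),
            }
        )
    return pd.DataFrame(rows)


def write_truth(truth: BenchmarkTruth, path: str, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for node in sorted(truth.membership):
            mods = ",".join(str(m) for m in sorted(truth.membership[node]))
            fh.write(f"{node}\t{mods}\n")


def read_truth(path: str, **params) -> Dict[str, FrozenSet[int]]:
    """Read an externally produced community-membership file
    (node<TAB>comma-joined modules)."""
    membership: Dict[str, FrozenSet[int]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            node, mods = line.split("\t")
            membership[node] = frozenset(int(m) for m in mods.split(","))
    return membership
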