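"""Node-level topological measures for connector characterisation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import networkx as nx
import pandas as pd

from .netio import HardPartition, Network, SoftPartition

__all__ = ["NodeProfile", "participation_coefficient", "module_link_counts", "node_profiles"]


@dataclass(frozen=True)
class NodeProfile:
    node: str
    module: int
    role: str
    degree: float
    participation: float
    inter_modular_degree: int


def module_link_counts(
    net: Network, hp: HardPartition, node: str, weighted: bool = False
) -> Dict[int, float]:
    """k_{i,m}: links (or weight) from ``node`` into each module.

    A self-loop counts once toward the node's own module.
    """
    counts: Dict[int, float] = {}
    for j, w in net.adj[node].items():
        if j == node:
            m = hp.assignment[node]
        else:
            m = hp.assignment[j]
        counts[m] = counts.get(m, 0.0) + (w if weighted else 1.0)
    return counts


def participation_coefficient(
    net: Network, hp: HardPartition, node: str, weighted: bool = False
) -> float:
    """P_i = 1 - sum_m (k_{i,m} / k_i)^2 on the hard partition."""
    counts = module_link_counts(net, hp, node, weighted=weighted)
    k = sum(counts.values())
    if k == 0:
        raise ValueError(f"participation coefficient undefined for degree-0 node {node!r}")
    return 1.0 - sum((km / k) ** 2 for km in counts.values())


def node_profiles(
    net: Network,
    hp: HardPartition,
    sp: Optional[SoftPartition] = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """One row per node: role, degree, participation, inter-modular degree
    and library-computed betweenness/eigenvector centrality."""
    g = net.to_networkx()
    betweenness = nx.betweenness_centrality(g, weight="weight" if weighted else None)
    try:
        eigenvector = nx.eigenvector_centrality_numpy(
            g, weight="weight" if weighted else None
        )
    except (nx.NetworkXException, TypeError):
        eigenvector = {i: float("nan") for i in net.nodes}

    rows = []
    for i in sorted(net.nodes):
        counts = module_link_counts(net, hp, i, weighted=weighted)
        k = sum(counts.values())
        h = hp.assignment[i]
        foreign = sum(1 for m in counts if m != h)
        part = 1.0 - sum((km / k) ** 2 for km in counts.values()) if k > 0 else float("nan")
        role = sp.roles.get(i, "") if sp is not None else ""
        n_mods = len(sp.membership.get(i, ())) if sp is not None else 1
        rows.append(
            {
                "node": i,
                "module": h,
                "role": role,
                "degree": k,
                "participation": part,
                "inter_modular_degree": foreign,
                "n_soft_modules": n_mods,
                "betweenness": betweenness[i],
                "eigenvector": eigenvector[i],
            }
        )
    return pd.DataFrame(rows)
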