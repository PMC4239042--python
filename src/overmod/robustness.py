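"""Monte-Carlo node-removal simulation.

For each node class, nodes of that class are deleted one at a time in a
seeded uniform random order; after every removal the size of the largest
connected component relative to the initial main-component size is
recorded.  Curves are per-step means over independent runs.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .netio import Network

__all__ = ["RemovalCurve", "removal_simulation"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RemovalCurve:
    node_class: str
    n_removed: Sequence[int]  # 0 .. class size
    sigma: Sequence[float]  # mean relative largest-component size
    n_runs: int


def _largest_component_size(adj: Mapping[str, Sequence[str]], removed: set) -> int:
    best = 0
    seen = set(removed)
    for start in adj:
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        best = max(best, size)
    return best


def removal_simulation(
    net: Network,
    classes: Mapping[str, str],
    n_runs: int = 100,
    seed: int = 0,
) -> Dict[str, RemovalCurve]:
    """Run the removal experiment for every class label in ``classes``.

    ``classes`` maps node -> class label; unlabeled nodes are never
    removed.  Empty classes are skipped with a warning.  sigma's
    denominator is the initial largest-component size, fixed per run.
    """
    adj: Dict[str, List[str]] = {
        i: [j for j in net.neighbors(i)] for i in net.nodes
    }
    n0 = _largest_component_size(adj, set())
    if n0 == 0:
        raise ValueError("network has no nodes")

    by_class: Dict[str, List[str]] = {}
    for node, label in classes.items():
        by_class.setdefault(label, []).append(node)

    curves: Dict[str, RemovalCurve] = {}
    for label in sorted(by_class):
        members = sorted(by_class[label])
        if not members:
            logger.warning("class %r is empty; skipped", label)
            continue
        total = np.zeros(len(members) + 1)
        for run in range(n_runs):
            # crc32 keeps the stream stable across processes (unlike hash())
            rng = np.random.default_rng([seed, run, zlib.crc32(label.encode())])
            order = list(members)
            rng.shuffle(order)
            removed: set = set()
            total[0] += 1.0
            for step, node in enumerate(order, start=1):
                removed.add(node)
                total[step] += _largest_component_size(adj, removed) / n0
        sigma = total / n_runs
        curves[label] = RemovalCurve(
            node_class=label,
            n_removed=list(range(len(members) + 1)),
            sigma=sigma.tolist(),
            n_runs=n_runs,
        )
    return curves
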