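import networkx as nx
import pytest

from overmod import HardPartition, Network, classify_nodes, greedy_hard_partition

TWO_TRIANGLE_EDGES = [
    ("a", "b", 1.0),
    ("a", "c", 1.0),
    ("b", "c", 1.0),
    ("d", "e", 1.0),
    ("d", "f", 1.0),
    ("e", "f", 1.0),
    ("c", "d", 1.0),
]


@pytest.fixture
def two_triangle():
    """Two triangles {a,b,c} and {d,e,f} bridged by the edge c-d."""
    net = Network.from_edges(TWO_TRIANGLE_EDGES)
    hp = HardPartition({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})
    return net, hp


def random_network(seed: int, n: int = 12, p: float = 0.3) -> Network:
    """Seeded loop-free Erdos-Renyi network with string node ids."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    if g.number_of_edges() == 0:
        g.add_edge(0, 1)
    return Network.from_edges((f"v{u:02d}", f"v{v:02d}", 1.0) for u, v in g.edges())


def random_instance(seed: int, n: int = 12, p: float = 0.3):
    """(net, hp, roles) with the hard partition from the built-in optimiser,
    run per connected component so the partition covers every node."""
    net = random_network(seed, n=n, p=p)
    g = net.to_networkx()
    assignment = {}
    offset = 0
    for comp in sorted(nx.connected_components(g), key=min):
        sub = net.subgraph(set(comp))
        if sub.total_weight == 0:
            for node in comp:
                offset += 1
                assignment[node] = offset
            continue
        hp_c = greedy_hard_partition(sub, seed=seed)
        for node, m in hp_c.assignment.items():
            assignment[node] = m + offset
        offset += hp_c.n_modules
    hp = HardPartition(assignment)
    return net, hp, classify_nodes(net, hp)


def textbook_modularity(net: Network, hp: HardPartition) -> float:
    """Independent oracle: Q = (1/2L) sum_ij [a_ij - s_i s_j / 2L] d(c_i, c_j)
    over ordered pairs of a loop-free network."""
    L = net.total_weight
    nodes = sorted(net.nodes)
    s = {i: net.strength(i) for i in nodes}
    q = 0.0
    for i in nodes:
        for j in nodes:
            if hp.assignment[i] == hp.assignment[j]:
                q += net.weight(i, j) - s[i] * s[j] / (2.0 * L)
    return q / (2.0 * L)
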