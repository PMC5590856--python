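"""Seeded generators for desk-scale fixture networks.

The method assumes interaction networks with low-dimensional geometric
structure shaped by duplication-divergence evolution. Two generators
emulate exactly that: a random geometric graph (points uniform in the unit
hypercube, edge iff within a connection radius) and a forward
duplication-divergence growth simulation. A small hand-analysed toy
network exercises every distance band of the evolutionary models.

Generators are deterministic for a fixed seed and write/read standard TSV
edge lists via :mod:`evogeo.network`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import PPINetwork


@dataclass(frozen=True)
class SyntheticSpec:
    kind: str = "geometric"        # geometric | dup_div | toy
    n: int = 500
    geo_dim: int = 3
    # Default radius gives a realized mean degree of ~8 at the default
    # n=500, geo_dim=3 once boundary effects are accounted for (the
    # interior-point formula of radius_for_mean_degree under-shoots).
    radius: float = 0.1665
    retain_p: float = 0.4
    parent_p: float = 0.3
    neo_p: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for p in (self.retain_p, self.parent_p, self.neo_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _node_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def radius_for_mean_degree(mean_degree: float, n: int, dim: int) -> float:
    """Connection radius giving the target interior-point mean degree.

    For points uniform in the unit hypercube the expected degree of an
    interior point is n·V_ball(r), V_ball the dim-dimensional ball volume;
    boundary effects make the realized mean slightly smaller.
    """
    v_unit = math.pi ** (dim / 2.0) / math.gamma(dim / 2.0 + 1.0)
    return (mean_degree / (n * v_unit)) ** (1.0 / dim)


def random_geometric_network(
    spec: SyntheticSpec,
) -> tuple[PPINetwork, np.ndarray]:
    """Random geometric graph plus its latent coordinates.

    n points uniform in the unit hypercube of ``geo_dim`` dimensions; an
    edge joins every pair at Euclidean distance <= ``radius``.
    """
    if spec.radius < 0:
        raise ValueError("radius must be nonnegative")
    g = nx.random_geometric_graph(spec.n, spec.radius, dim=spec.geo_dim,
                                  seed=int(spec.seed))
    ids = _node_ids("g", spec.n)
    pairs = [(ids[a], ids[b]) for a, b in g.edges()]
    net = PPINetwork.from_id_pairs(pairs, extra_nodes=ids)
    coords = np.array([g.nodes[i]["pos"] for i in range(spec.n)])
    return net, coords


def simulate_duplication_divergence(spec: SyntheticSpec) -> PPINetwork:
    """Forward duplication-divergence growth from a triangle seed graph.

    Each step duplicates a uniformly chosen node; the duplicate retains
    each parent edge with probability ``retain_p``, links back to the
    parent with probability ``parent_p``, and with probability ``neo_p``
    gains one neofunctionalization edge to a node chosen proportional to
    degree (the scale-free flavour). Duplicates that end up isolated are
    discarded and the step repeated, so the returned network has exactly
    ``n`` nodes.
    """
    rng = np.random.default_rng(spec.seed)
    adj: list[set[int]] = [{1, 2}, {0, 2}, {0, 1}]
    while len(adj) < spec.n:
        parent = int(rng.integers(len(adj)))
        new_edges: set[int] = set()
        for nb in adj[parent]:
            if rng.random() < spec.retain_p:
                new_edges.add(nb)
        if rng.random() < spec.parent_p:
            new_edges.add(parent)
        if rng.random() < spec.neo_p:
            deg = np.array([len(a) for a in adj], dtype=float)
            target = int(rng.choice(len(adj), p=deg / deg.sum()))
            new_edges.add(target)
        if not new_edges:
            continue
        new = len(adj)
        adj.append(new_edges)
        for nb in new_edges:
            adj[nb].add(new)
    ids = _node_ids("d", spec.n)
    pairs = [(ids[i], ids[j]) for i in range(spec.n) for j in adj[i] if i < j]
    return PPINetwork.from_id_pairs(pairs, extra_nodes=ids)


def toy_fixture() -> dict:
    """Fixed 6-node worked example with hand-computed intermediates.

    Nodes A-E form the maximum connected component (a 4-edge path A-B-C-D-E
    closed by the chord A-C); node F is isolated. Taking the path as the
    training tree, the component exhibits a duplication-band pair
    (SP = 2), and a pair beyond the duplication band (SP = 4) reachable
    only by neofunctionalization. Returns the network, the path MST, its
    shortest-path matrix, MST degrees, and the per-pair collapse
    probabilities of all three models at the default rates
    (alpha = 0.3, beta = 0.15).
    """
    ids = ("A", "B", "C", "D", "E", "F")
    edges = frozenset({(0, 1), (1, 2), (2, 3), (3, 4), (0, 2)})
    net = PPINetwork(ids, edges)
    mst = frozenset({(0, 1), (1, 2), (2, 3), (3, 4)})  # the path A-B-C-D-E
    sp = np.array([[0, 1, 2, 3, 4],
                   [1, 0, 1, 2, 3],
                   [2, 1, 0, 1, 2],
                   [3, 2, 1, 0, 1],
                   [4, 3, 2, 1, 0]], dtype=float)
    deg = np.array([1, 2, 2, 2, 1])      # path degrees; Δ(MST) = 2
    # Hand-computed collapse probabilities for each unordered non-tree pair.
    daneosf = {(0, 2): 0.3, (1, 3): 0.3, (2, 4): 0.3,   # SP = 2 band
               (0, 3): 0.3, (1, 4): 0.3,                # SP = 3 band
               (0, 4): (1 * 1 / 4) ** 4}                # SP = 4: (deg/Δ²)^SP
    lpa = {(0, 2): 0.5 * 2 / 4, (1, 3): 0.5 * 4 / 4, (2, 4): 0.5 * 2 / 4,
           (0, 3): 0.5 * 2 / 4, (1, 4): 0.5 * 2 / 4, (0, 4): 0.5 * 1 / 4}
    rm = {p: 0.15 for p in daneosf}
    return {"network": net, "component_ids": ids[:5], "mst": mst,
            "sp": sp, "deg": deg, "max_deg": 2,
            "probabilities": {"daneosf": daneosf, "lpa": lpa, "rm": rm}}
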