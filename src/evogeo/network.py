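"""Interaction-network container, file parsing, components, MST and splits.

A protein-protein interaction (PPI) network is an undirected simple graph:
no self-loops, no parallel edges, adjacency a_ij = 1 iff proteins i and j
interact. Only the maximum connected component is embedded downstream, and
a seeded minimum spanning tree of that component serves as the training
sub-network; the remaining edges are held out for testing.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


class FormatError(ValueError):
    """Malformed interaction file."""


def _canon(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected simple graph with a stable, lexicographic node indexing.

    Parameters
    ----------
    node_ids : tuple of str
        Protein identifiers sorted lexicographically; index positions in
        this tuple are the node indices used everywhere else.
    edges : frozenset of (int, int)
        Unordered index pairs stored with i < j.
    """

    node_ids: tuple[str, ...]
    edges: frozenset  # of Edge

    def __post_init__(self) -> None:
        if list(self.node_ids) != sorted(self.node_ids):
            raise ValueError("node_ids must be lexicographically sorted")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on index {i}")
            if not (0 <= i < j < len(self.node_ids)):
                raise ValueError(f"edge ({i},{j}) out of range or unordered")

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m_edges(self) -> int:
        return len(self.edges)

    @classmethod
    def from_id_pairs(cls, pairs: Iterable[tuple[str, str]],
                      extra_nodes: Iterable[str] = ()) -> "PPINetwork":
        """Build from identifier pairs, dropping self-loops and duplicates."""
        pairs = list(pairs)
        ids = sorted({x for p in pairs for x in p} | set(extra_nodes))
        index = {v: k for k, v in enumerate(ids)}
        edges: set[Edge] = set()
        n_self = n_dup = 0
        for a, b in pairs:
            if a == b:
                n_self += 1
                continue
            e = _canon(index[a], index[b])
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
        if n_self or n_dup:
            logger.info("dropped %d self-loops, collapsed %d duplicates",
                        n_self, n_dup)
        return cls(tuple(ids), frozenset(edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency matrix (a_ii = 0)."""
        a = np.zeros((self.n, self.n), dtype=np.int8)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1
        return a

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def edge_id_pairs(self) -> list[tuple[str, str]]:
        return [(self.node_ids[i], self.node_ids[j])
                for i, j in sorted(self.edges)]


@dataclass(frozen=True)
class SplitResult:
    """Training MST edges, held-out test edges and candidate-pair count."""

    trn_edges: frozenset
    tst_edges: frozenset
    n_candidates: int


def parse_edge_list(path: str | Path, dialect: str = "tsv") -> PPINetwork:
    """Parse an interaction file into a :class:`PPINetwork`.

    ``tsv``: two whitespace/tab-separated identifier columns; lines starting
    with ``#`` are ignored.  ``mitab``: tab-separated, interactor identifiers
    taken verbatim from columns 1 and 2 (no namespace resolution).
    """
    if dialect not in ("tsv", "mitab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    pairs: list[tuple[str, str]] = []
    n_lines = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        n_lines += 1
        cols = line.split("\t") if dialect == "mitab" else line.split()
        if len(cols) < 2:
            raise FormatError(f"line {lineno}: expected >=2 columns")
        pairs.append((cols[0].strip(), cols[1].strip()))
    if not pairs:
        raise FormatError(f"{path}: no interactions found")
    logger.info("read %d interaction lines from %s", n_lines, path)
    return PPINetwork.from_id_pairs(pairs)


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    """Write the network back out as a two-column TSV edge list."""
    with open(path, "w") as fh:
        for a, b in net.edge_id_pairs():
            fh.write(f"{a}\t{b}\n")


def max_connected_component(net: PPINetwork) -> PPINetwork:
    """Induced subgraph on the largest connected node set, re-indexed.

    Ties in component size are broken by the smallest lexicographic node
    identifier contained in the component.
    """
    if net.n == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net.to_networkx()))
    biggest = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == biggest),
               key=lambda c: min(net.node_ids[i] for i in c))
    keep = sorted(best, key=lambda i: net.node_ids[i])
    remap = {old: new for new, old in enumerate(keep)}
    edges = frozenset(_canon(remap[i], remap[j]) for i, j in net.edges
                      if i in remap and j in remap)
    return PPINetwork(tuple(net.node_ids[i] for i in keep), edges)


def is_connected(net: PPINetwork) -> bool:
    return net.n > 0 and nx.is_connected(net.to_networkx())


def minimum_spanning_tree(net: PPINetwork, seed: int) -> frozenset:
    """Seeded Prim spanning tree of a connected unit-weight network.

    All edges carry weight 1, so every spanning tree is minimal and the MST
    is not unique; tie-breaking uses a seeded random priority per frontier
    edge so that distinct seeds explore distinct trees while a fixed seed is
    fully reproducible.
    """
    if not is_connected(net):
        raise ValueError("network is disconnected; extract the maximum "
                         "connected component first")
    rng = np.random.default_rng(seed)
    adj = net.neighbors()
    start = int(rng.integers(net.n))
    visited = [False] * net.n
    visited[start] = True
    heap: list[tuple[float, int, int]] = []
    for v in adj[start]:
        heapq.heappush(heap, (rng.random(), start, v))
    tree: set[Edge] = set()
    while len(tree) < net.n - 1:
        _, u, v = heapq.heappop(heap)
        if visited[v]:
            continue
        visited[v] = True
        tree.add(_canon(u, v))
        for w in adj[v]:
            if not visited[w]:
                heapq.heappush(heap, (rng.random(), v, w))
    return frozenset(tree)


def _is_spanning_tree(net: PPINetwork, mst: frozenset) -> bool:
    if len(mst) != net.n - 1:
        return False
    g = nx.Graph()
    g.add_nodes_from(range(net.n))
    g.add_edges_from(mst)
    return nx.is_connected(g)


def split_train_test(net: PPINetwork, mst: frozenset) -> SplitResult:
    """Split edges into the MST training set and the held-out test set.

    The candidate universe for prediction is every unordered non-MST pair,
    so ``n_candidates = n(n-1)/2 - (n-1)``.
    """
    if not mst <= net.edges:
        raise ValueError("MST edges are not a subset of the network edges")
    if not _is_spanning_tree(net, mst):
        raise ValueError("edge set is not a spanning tree of the network")
    tst = frozenset(net.edges - mst)
    n_candidates = net.n * (net.n - 1) // 2 - len(mst)
    return SplitResult(frozenset(mst), tst, n_candidates)


def subnetwork(net: PPINetwork, edges: frozenset) -> PPINetwork:
    """Network on the same nodes restricted to the given edge set."""
    return PPINetwork(net.node_ids, frozenset(edges))


def split_manifest(net: PPINetwork, split: SplitResult, seed: int) -> str:
    return json.dumps({"n": net.n, "trn": len(split.trn_edges),
                       "tst": len(split.tst_edges),
                       "candidates": split.n_candidates, "seed": seed})
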