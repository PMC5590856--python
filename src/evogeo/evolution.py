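"""Evolutionary distances on the MST training sub-network.

The training MST is "evolved" backwards in time: for each unordered node
pair not already adjacent in the tree, the pair is collapsed to distance 1
with a model-specific probability, reflecting a hypothesised evolutionary
relation (gene duplication/divergence, degree-driven neofunctionalization,
linear preferential attachment, or undirected random mutation). Otherwise
the pair keeps its tree shortest-path distance. Three models are provided,
all defined on the static MST (degrees, maximum degree and shortest paths
are frozen; edges accrued during sampling never feed back into the
probabilities):

``daneosf`` (duplication and scale-free neofunctionalization)
    p = 1 if SP(i,j) = 1; p = alpha if SP(i,j) in {2, 3};
    p = (deg(i)·deg(j) / Δ(MST)²)^SP(i,j) if SP(i,j) > 3.

``lpa`` (linear preferential attachment)
    p = 1 if SP = 1; p = ½·deg(i)·deg(j)/Δ(MST)² otherwise.

``rm`` (random mutation)
    p = 1 if SP = 1; p = beta otherwise.

Because deg ≤ Δ(MST), every probability lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator

from .network import PPINetwork, subnetwork

MODELS = ("daneosf", "lpa", "rm")


def _sparse_adj(net: PPINetwork) -> csr_matrix:
    if net.m_edges == 0:
        return csr_matrix((net.n, net.n), dtype=np.int8)
    ij = np.array(sorted(net.edges), dtype=np.intp)
    rows = np.concatenate([ij[:, 0], ij[:, 1]])
    cols = np.concatenate([ij[:, 1], ij[:, 0]])
    data = np.ones(rows.shape, dtype=np.int8)
    return csr_matrix((data, (rows, cols)), shape=(net.n, net.n))


def all_pairs_shortest_path(net: PPINetwork) -> np.ndarray:
    """Unweighted all-pairs shortest-path matrix (BFS per source).

    Raises on disconnected input: an infinite distance cannot be embedded.
    """
    adj = _sparse_adj(net)
    if net.n > 1:
        ncomp, _ = connected_components(adj, directed=False)
        if ncomp != 1:
            raise ValueError("network is disconnected")
    return shortest_path(adj, method="D", unweighted=True, directed=False)


@dataclass(frozen=True)
class MSTContext:
    """Frozen view of the training MST: shortest paths, degrees, Δ(MST)."""

    sp: np.ndarray
    deg: np.ndarray
    max_deg: int

    @classmethod
    def from_mst(cls, net_mst: PPINetwork) -> "MSTContext":
        sp = all_pairs_shortest_path(net_mst)
        deg = np.zeros(net_mst.n, dtype=np.int64)
        for i, j in net_mst.edges:
            deg[i] += 1
            deg[j] += 1
        return cls(sp=sp, deg=deg, max_deg=int(deg.max()))


@dataclass(frozen=True)
class EvoModelParams:
    """Model selection and rates; alpha is the duplication-band probability,
    beta the random-mutation probability."""

    model: str = "daneosf"
    alpha: float = 0.3
    beta: float = 0.15
    mode: str = "evolved_graph"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; pick from {MODELS}")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.mode not in ("evolved_graph", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")


def probability_matrix(ctx: MSTContext, params: EvoModelParams) -> np.ndarray:
    """Collapse-to-distance-1 probability for every ordered pair (diag 0)."""
    sp = ctx.sp
    deg = ctx.deg.astype(float)
    ratio = np.outer(deg, deg) / float(ctx.max_deg) ** 2
    p = np.zeros_like(sp)
    if params.model == "daneosf":
        p[(sp >= 2) & (sp <= 3)] = params.alpha
        far = sp > 3
        p[far] = ratio[far] ** sp[far]
    elif params.model == "lpa":
        p[sp > 1] = 0.5 * ratio[sp > 1]
    else:  # rm
        p[sp > 1] = params.beta
    p[sp == 1] = 1.0
    np.fill_diagonal(p, 0.0)
    return p


def edge_probability(i: int, j: int, ctx: MSTContext,
                     params: EvoModelParams) -> float:
    """Probability that pair (i, j) is collapsed to distance 1."""
    if i == j:
        raise ValueError("edge probability is defined for distinct nodes")
    sp = ctx.sp[i, j]
    if sp == 1:
        return 1.0
    if params.model == "daneosf":
        if sp <= 3:
            return params.alpha
        ratio = ctx.deg[i] * ctx.deg[j] / ctx.max_deg ** 2
        return float(ratio ** sp)
    if params.model == "lpa":
        return float(0.5 * ctx.deg[i] * ctx.deg[j] / ctx.max_deg ** 2)
    return params.beta


def _sample_added_edges(net_mst: PPINetwork, ctx: MSTContext,
                        params: EvoModelParams) -> frozenset:
    """One Bernoulli per unordered non-adjacent pair, mirrored symmetrically."""
    rng = np.random.default_rng(params.seed)
    p = probability_matrix(ctx, params)
    iu, ju = np.triu_indices(net_mst.n, k=1)
    nonadj = ctx.sp[iu, ju] > 1
    iu, ju = iu[nonadj], ju[nonadj]
    hit = rng.random(iu.shape[0]) < p[iu, ju]
    return frozenset(zip(iu[hit].tolist(), ju[hit].tolist()))


def sample_evolved_network(net_mst: PPINetwork, ctx: MSTContext,
                           params: EvoModelParams) -> PPINetwork:
    """Evolved training sub-network: the MST plus sampled evolutionary edges."""
    added = _sample_added_edges(net_mst, ctx, params)
    return subnetwork(net_mst, frozenset(net_mst.edges | added))


def evolutionary_distance_matrix(
    net_mst: PPINetwork, ctx: MSTContext, params: EvoModelParams
) -> tuple[np.ndarray, PPINetwork]:
    """Evolved distance matrix plus the evolved network.

    ``evolved_graph`` mode recomputes all-pairs shortest paths on the
    evolved network, so an added edge can also shorten third-party
    distances. ``literal`` mode sets each sampled pair to exactly 1 and
    keeps the MST shortest path otherwise — the branch values of the model
    definitions taken verbatim.
    """
    evolved = sample_evolved_network(net_mst, ctx, params)
    if params.mode == "evolved_graph":
        d = all_pairs_shortest_path(evolved)
    else:
        d = ctx.sp.copy()
        for i, j in evolved.edges:
            d[i, j] = d[j, i] = 1.0
    return d, evolved


def evolved_edge_origins(net_mst: PPINetwork, evolved: PPINetwork,
                         ctx: MSTContext) -> list[tuple[str, str, str]]:
    """Per-edge origin labels for export: mst, duplication (SP 2-3 band) or
    neofunctionalization-or-model (anything farther)."""
    rows = []
    for i, j in sorted(evolved.edges):
        if (i, j) in net_mst.edges:
            origin = "mst"
        elif ctx.sp[i, j] <= 3:
            origin = "duplication"
        else:
            origin = "neofunctionalization-or-model"
        rows.append((evolved.node_ids[i], evolved.node_ids[j], origin))
    return rows


class EvolutionaryDistance(BaseEstimator):
    """Transformer from a training MST to an evolved distance matrix.

    Parameters
    ----------
    model : {"daneosf", "lpa", "rm"}
    alpha : float, default 0.3
        Duplication-band collapse probability of the daneosf model.
    beta : float, default 0.15
        Collapse probability of the random-mutation model.
    mode : {"evolved_graph", "literal"}, default "evolved_graph"
        Whether distances are recomputed on the evolved graph or taken as
        the literal branch values.
    random_state : int, default 0

    Attributes
    ----------
    context_ : MSTContext
    distance_matrix_ : ndarray of shape (n, n)
    evolved_network_ : PPINetwork
    """

    def __init__(self, model: str = "daneosf", alpha: float = 0.3,
                 beta: float = 0.15, mode: str = "evolved_graph",
                 random_state: int = 0):
        self.model = model
        self.alpha = alpha
        self.beta = beta
        self.mode = mode
        self.random_state = random_state

    def _params(self) -> EvoModelParams:
        return EvoModelParams(model=self.model, alpha=self.alpha,
                              beta=self.beta, mode=self.mode,
                              seed=self.random_state)

    def fit(self, net_mst: PPINetwork, y=None) -> "EvolutionaryDistance":
        self.context_ = MSTContext.from_mst(net_mst)
        self.distance_matrix_, self.evolved_network_ = \
            evolutionary_distance_matrix(net_mst, self.context_, self._params())
        return self

    def transform(self, net_mst: PPINetwork = None) -> np.ndarray:
        return self.distance_matrix_

    def fit_transform(self, net_mst: PPINetwork, y=None) -> np.ndarray:
        return self.fit(net_mst).transform()
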