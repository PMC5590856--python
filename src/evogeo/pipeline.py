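"""End-to-end evolutionary-distance-embedding (EDE) prediction.

The pipeline: maximum connected component -> seeded unit-weight MST
(training sub-network) -> evolved evolutionary-distance matrix (or the raw
MST shortest-path matrix for the minimum-curvilinearity SP baseline) ->
geometric embedding -> Gaussian-mixture density model -> Bayesian
confidence score for every candidate pair -> ROC / PR evaluation against
the held-out edges.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import evaluation, network, scoring
from .embedding import ClassicalMDS, NonCenteredSVD, pairwise_euclidean
from .evolution import (EvolutionaryDistance, MSTContext,
                        all_pairs_shortest_path)
from .network import PPINetwork, SplitResult

MODEL_CHOICES = ("daneosf", "lpa", "rm", "sp_baseline")


class EDEPredictor(BaseEstimator):
    """Link predictor by evolutionary-distance geometric embedding.

    Parameters
    ----------
    model : {"daneosf", "lpa", "rm", "sp_baseline"}, default "daneosf"
        Evolutionary model, or the minimum-curvilinearity baseline that
        embeds the raw MST shortest-path matrix.
    mode : {"evolved_graph", "literal"}, default "evolved_graph"
        How evolved distances are realized (ignored for sp_baseline).
    embed : {"mds", "ncsvd"}, default "mds"
    n_components : int, default 5
        Embedding dimension.
    alpha, beta : float
        Model rates (duplication band / random mutation).
    n_mixture : int, default 3
        Gaussian components per density.
    nonedge_sample : int, default 100_000
        Non-edge pairs sampled for the non-edge density.
    p_edge : float or None
        Edge prior; defaults to the training-graph density.
    random_state : int, default 0
        Drives the MST draw, the evolutionary sampling and the density
        fit; a fixed value makes the whole fit bit-reproducible.

    Attributes
    ----------
    component_ : PPINetwork
        Maximum connected component actually fitted.
    split_ : SplitResult
    context_ : MSTContext
    distance_matrix_ : ndarray
    evolved_edges_ : frozenset
    embedding_ : ndarray of shape (n, n_components)
    density_model_ : scoring.DensityModel
    mst_hash_ : str
        SHA-1 of the sorted MST edge list (provenance / pairing check).
    """

    def __init__(self, model: str = "daneosf", mode: str = "evolved_graph",
                 embed: str = "mds", n_components: int = 5,
                 alpha: float = 0.3, beta: float = 0.15, n_mixture: int = 3,
                 nonedge_sample: int = 100_000, p_edge: float | None = None,
                 random_state: int = 0):
        self.model = model
        self.mode = mode
        self.embed = embed
        self.n_components = n_components
        self.alpha = alpha
        self.beta = beta
        self.n_mixture = n_mixture
        self.nonedge_sample = nonedge_sample
        self.p_edge = p_edge
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def fit(self, X: PPINetwork, y=None, mst: frozenset | None = None
            ) -> "EDEPredictor":
        """Fit on an interaction network (a PPINetwork).

        ``mst`` forces a specific training tree, used to pair model
        comparisons on identical splits; by default a tree is drawn with
        ``random_state``.
        """
        if self.model not in MODEL_CHOICES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.embed not in ("mds", "ncsvd"):
            raise ValueError(f"unknown embedding backend {self.embed!r}")
        comp = network.max_connected_component(X)
        self.component_ = comp
        if mst is None:
            mst = network.minimum_spanning_tree(comp, seed=self.random_state)
        self.split_ = network.split_train_test(comp, mst)
        mst_net = network.subnetwork(comp, self.split_.trn_edges)
        self.context_ = MSTContext.from_mst(mst_net)
        if self.model == "sp_baseline":
            self.distance_matrix_ = self.context_.sp
            self.evolved_edges_ = frozenset(self.split_.trn_edges)
        else:
            evo = EvolutionaryDistance(
                model=self.model, alpha=self.alpha, beta=self.beta,
                mode=self.mode, random_state=self.random_state + 1)
            self.distance_matrix_ = evo.fit_transform(mst_net)
            self.evolved_edges_ = frozenset(evo.evolved_network_.edges)
        backend = (ClassicalMDS if self.embed == "mds"
                   else NonCenteredSVD)(n_components=self.n_components)
        self.embedding_ = backend.fit_transform(self.distance_matrix_)
        self.spectrum_ = backend.spectrum_
        self.density_model_ = scoring.fit_density_model(
            self.embedding_, self.split_, self.evolved_edges_,
            k=self.n_mixture, nonedge_sample=self.nonedge_sample,
            seed=self.random_state + 2, p_edge=self.p_edge)
        digest = hashlib.sha1(
            repr(sorted(self.split_.trn_edges)).encode()).hexdigest()
        self.mst_hash_ = digest
        return self

    # -- prediction ------------------------------------------------------

    def candidate_pairs(self, include_training: bool = False) -> np.ndarray:
        """Unordered pairs to score: all non-MST pairs, or all pairs."""
        n = self.component_.n
        iu, ju = np.triu_indices(n, k=1)
        if include_training:
            return np.column_stack([iu, ju])
        trn = self.split_.trn_edges
        mask = np.fromiter(((i, j) not in trn
                            for i, j in zip(iu.tolist(), ju.tolist())),
                           dtype=bool, count=iu.size)
        return np.column_stack([iu[mask], ju[mask]])

    def predict_proba(self, pairs: np.ndarray | None = None) -> np.ndarray:
        """Confidence score S in [0, 1] for each pair (default: candidates)."""
        if pairs is None:
            pairs = self.candidate_pairs()
        d = pairwise_euclidean(self.embedding_, pairs)
        return scoring.confidence_score(self.density_model_, d)

    def score_table(self, pairs: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy table of node ids, Euclidean distance and confidence."""
        if pairs is None:
            pairs = self.candidate_pairs()
        d = pairwise_euclidean(self.embedding_, pairs)
        s = scoring.confidence_score(self.density_model_, d)
        ids = self.component_.node_ids
        return pd.DataFrame({
            "node_i": [ids[i] for i in pairs[:, 0]],
            "node_j": [ids[j] for j in pairs[:, 1]],
            "euclidean_dist": d,
            "confidence": s,
        })

    def evaluate(self, mode: str = "cross_validation") -> evaluation.EvalResult:
        """Rank candidates and score against held-out (or all) edges."""
        whole = mode == "whole_network"
        pairs = self.candidate_pairs(include_training=whole)
        s = self.predict_proba(pairs)
        pos = (self.component_.edges if whole else self.split_.tst_edges)
        y = np.fromiter(((int(i), int(j)) in pos for i, j in pairs),
                        dtype=bool, count=pairs.shape[0])
        return evaluation.evaluate_ranking(y, s, mode=mode)


# -- repeated-run orchestration -----------------------------------------


@dataclass
class RunConfig:
    """Configuration of a repeated-run experiment."""

    edges: str | Path | None = None
    dialect: str = "tsv"
    models: tuple[str, ...] = ("daneosf", "sp_baseline")
    mode: str = "evolved_graph"
    embed: str = "mds"
    dim: int = 5
    alpha: float = 0.3
    beta: float = 0.15
    k: int = 3
    nonedge_sample: int = 100_000
    seed: int = 0
    repeats: int = 15
    eval_mode: str = "cross_validation"
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for m in self.models:
            if m not in MODEL_CHOICES:
                raise ValueError(f"unknown model {m!r}")


def run_ede(cfg: RunConfig, net: PPINetwork | None = None) -> dict:
    """Run the full pipeline ``cfg.repeats`` times per configured model.

    Repeat r uses seed ``cfg.seed + r`` for its MST draw, and every model
    within a repeat is fitted on that same tree (true pairing), verified by
    the logged MST hashes. Returns per-repeat AUCs, mean +/- sd summaries
    and paired t-tests between every model pair; optionally writes score
    tables, metrics JSON and curve TSVs to ``cfg.out_dir``.
    """
    if net is None:
        if cfg.edges is None:
            raise ValueError("either a network or an edge-list path is needed")
        net = network.parse_edge_list(cfg.edges, dialect=cfg.dialect)
    comp = network.max_connected_component(net)
    out = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    aucs: dict[str, list[float]] = {m: [] for m in cfg.models}
    aucprs: dict[str, list[float]] = {m: [] for m in cfg.models}
    mst_hashes: list[str] = []
    for r in range(cfg.repeats):
        seed_r = cfg.seed + r
        mst = network.minimum_spanning_tree(comp, seed=seed_r)
        hashes = set()
        for m in cfg.models:
            pred = EDEPredictor(
                model=m, mode=cfg.mode, embed=cfg.embed,
                n_components=cfg.dim, alpha=cfg.alpha, beta=cfg.beta,
                n_mixture=cfg.k, nonedge_sample=cfg.nonedge_sample,
                random_state=seed_r).fit(comp, mst=mst)
            res = pred.evaluate(mode=cfg.eval_mode)
            aucs[m].append(res.auc_roc)
            aucprs[m].append(res.auc_pr)
            hashes.add(pred.mst_hash_)
            if out is not None:
                tag = f"{m}_r{r}"
                pred.score_table().to_csv(out / f"scores_{tag}.tsv",
                                          sep="\t", index=False)
                np.savetxt(out / f"roc_{tag}.tsv", res.roc_points,
                           delimiter="\t", header="fpr\ttpr", comments="")
                np.savetxt(out / f"pr_{tag}.tsv", res.pr_points,
                           delimiter="\t", header="recall\tprecision",
                           comments="")
        assert len(hashes) == 1, "models of one repeat must share the MST"
        mst_hashes.append(hashes.pop())

    summary = {m: {"auc_mean": float(np.mean(aucs[m])),
                   "auc_sd": float(np.std(aucs[m], ddof=1))
                   if cfg.repeats > 1 else 0.0,
                   "aucpr_mean": float(np.mean(aucprs[m])),
                   "aucs": aucs[m]}
               for m in cfg.models}
    ttests = {}
    if cfg.repeats >= 2:
        for i, ma in enumerate(cfg.models):
            for mb in cfg.models[i + 1:]:
                t, p = evaluation.paired_t_test(aucs[ma], aucs[mb])
                ttests[f"{ma}_vs_{mb}"] = {"t": t, "p": p}
    result = {"config": {k: (str(v) if isinstance(v, Path) else v)
                         for k, v in vars(cfg).items()},
              "n": comp.n, "summary": summary, "paired_t": ttests,
              "mst_hashes": mst_hashes}
    if out is not None:
        (out / "metrics.json").write_text(json.dumps(result, indent=2,
                                                     default=str))
    return result
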