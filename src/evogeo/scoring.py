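"""Confidence scoring of candidate pairs from embedded distances.

Two one-dimensional Gaussian-mixture densities are fitted by EM: one on
Euclidean distances of training (MST) edges, p(dist|edge), and one on a
seeded uniform sample of pairs outside the evolved training network,
p(dist|nonedge). With class priors p(edge) and p(nonedge) = 1 - p(edge),
Bayes' rule gives posteriors whose shared p(dist) denominator cancels in
the confidence score

    S = p(dist|edge)·p(edge) /
        (p(dist|edge)·p(edge) + p(dist|nonedge)·p(nonedge)),

so the evidence term is never computed. If both mixture densities
underflow to zero the score is the uninformative 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin

from .embedding import EmbeddingResult, pairwise_euclidean
from .network import PPINetwork, SplitResult

_VAR_FLOOR = 1e-6


class GaussianMixture1D(BaseEstimator, DensityMixin):
    """One-dimensional Gaussian mixture fitted by EM.

    Initialization places the component means at evenly spread sample
    quantiles with a common pooled variance; means are nudged apart by a
    tiny seeded jitter if quantiles coincide. Variances use the
    maximum-likelihood (1/N) convention with a floor of 1e-6 against
    collapse. EM stops when the log-likelihood improves by less than
    ``tol`` or after ``max_iter`` iterations.

    Attributes
    ----------
    weights_, means_, variances_ : ndarray of shape (k,)
    converged_ : bool
    log_likelihoods_ : list of per-iteration total log-likelihoods
    """

    def __init__(self, n_components: int = 3, tol: float = 1e-8,
                 max_iter: int = 500, var_floor: float = _VAR_FLOOR,
                 random_state: int = 0):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.random_state = random_state

    def _log_component_densities(self, x: np.ndarray) -> np.ndarray:
        var = self.variances_[None, :]
        mu = self.means_[None, :]
        return (-0.5 * np.log(2.0 * np.pi * var)
                - 0.5 * (x[:, None] - mu) ** 2 / var)

    def fit(self, X, y=None) -> "GaussianMixture1D":
        x = np.asarray(X, dtype=float).ravel()
        k = self.n_components
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if np.unique(x).size < k:
            raise ValueError(f"need at least {k} distinct sample values")
        rng = np.random.default_rng(self.random_state)
        q = (np.arange(k) + 0.5) / k
        means = np.quantile(x, q)
        if np.unique(means).size < k:
            means = means + rng.normal(0.0, max(x.std(), 1.0) * 1e-3, k)
        var = max(float(x.var()), self.var_floor)
        self.means_ = means
        self.variances_ = np.full(k, var)
        self.weights_ = np.full(k, 1.0 / k)

        n = x.size
        x2 = x * x
        self.log_likelihoods_: list[float] = []
        self.converged_ = False
        prev = -np.inf
        # Component-major (k, N) layout; the M step runs on sufficient
        # statistics (responsibility sums and first/second moments) so the
        # per-iteration cost is a few BLAS matvecs even at N = 1e5.
        for _ in range(self.max_iter):
            var = self.variances_[:, None]
            log_p = (np.log(self.weights_)[:, None]
                     - 0.5 * np.log(2.0 * np.pi * var)
                     - 0.5 * (x[None, :] - self.means_[:, None]) ** 2 / var)
            mx = log_p.max(axis=0)
            e = np.exp(log_p - mx[None, :])
            tot = e.sum(axis=0)
            ll = float(mx.sum() + np.log(tot).sum())
            self.log_likelihoods_.append(ll)
            resp = e / tot[None, :]
            nk = np.maximum(resp.sum(axis=1), 1e-300)
            sx = resp @ x
            sx2 = resp @ x2
            self.weights_ = nk / n
            self.means_ = sx / nk
            self.variances_ = np.maximum(sx2 / nk - self.means_ ** 2,
                                         self.var_floor)
            if ll - prev < self.tol and np.isfinite(prev):
                self.converged_ = True
                break
            prev = ll
        return self

    def score_samples(self, X) -> np.ndarray:
        """Log density of the mixture at each point."""
        x = np.asarray(X, dtype=float).ravel()
        log_p = self._log_component_densities(x) + np.log(self.weights_)
        return logsumexp(log_p, axis=1)

    def pdf(self, X) -> np.ndarray:
        return np.exp(self.score_samples(X))


def fit_gmm_em(samples, k: int = 3, seed: int = 0) -> GaussianMixture1D:
    """Fit a k-component 1-D Gaussian mixture by EM (thin wrapper)."""
    return GaussianMixture1D(n_components=k, random_state=seed).fit(samples)


@dataclass(frozen=True)
class DensityModel:
    """Edge / non-edge mixture densities plus class priors."""

    edge_mix: GaussianMixture1D
    nonedge_mix: GaussianMixture1D
    p_edge: float

    @property
    def p_nonedge(self) -> float:
        return 1.0 - self.p_edge

    def to_dict(self) -> dict:
        def mix(m: GaussianMixture1D) -> dict:
            return {"weights": m.weights_.tolist(),
                    "means": m.means_.tolist(),
                    "variances": m.variances_.tolist()}
        return {"edge_mix": mix(self.edge_mix),
                "nonedge_mix": mix(self.nonedge_mix),
                "p_edge": self.p_edge}


def confidence_score(model: DensityModel, dist) -> np.ndarray | float:
    """Posterior-odds confidence S in [0, 1] for the given distance(s)."""
    d = np.atleast_1d(np.asarray(dist, dtype=float))
    with np.errstate(divide="ignore"):
        log_e = model.edge_mix.score_samples(d) + np.log(model.p_edge)
        log_ne = (model.nonedge_mix.score_samples(d)
                  + np.log(model.p_nonedge))
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        zero_e = np.exp(log_e) == 0.0   # underflow in linear space
        zero_ne = np.exp(log_ne) == 0.0
        s = 1.0 / (1.0 + np.exp(log_ne - log_e))
    s[zero_e & ~zero_ne] = 0.0
    s[~zero_e & zero_ne] = 1.0
    s[zero_e & zero_ne] = 0.5
    if np.isscalar(dist) or np.asarray(dist).ndim == 0:
        return float(s[0])
    return s


def _sample_nonedge_pairs(n: int, excluded: frozenset, count: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Seeded uniform sample (without replacement) of unordered pairs not in
    ``excluded``; returns all such pairs when there are at most ``count``."""
    total = n * (n - 1) // 2 - len(excluded)
    if total <= count:
        iu, ju = np.triu_indices(n, k=1)
        mask = np.fromiter(((i, j) not in excluded
                            for i, j in zip(iu.tolist(), ju.tolist())),
                           dtype=bool, count=iu.size)
        return np.column_stack([iu[mask], ju[mask]])
    chosen: set[tuple[int, int]] = set()
    out = np.empty((count, 2), dtype=np.intp)
    got = 0
    while got < count:
        draw = rng.integers(0, n, size=(2 * (count - got) + 16, 2))
        for a, b in draw:
            if a == b:
                continue
            e = (int(a), int(b)) if a < b else (int(b), int(a))
            if e in excluded or e in chosen:
                continue
            chosen.add(e)
            out[got] = e
            got += 1
            if got == count:
                break
    return out


def fit_density_model(emb: EmbeddingResult | np.ndarray, split: SplitResult,
                      evolved_edges: frozenset, k: int = 3,
                      nonedge_sample: int = 100_000, seed: int = 0,
                      p_edge: float | None = None) -> DensityModel:
    """Fit edge / non-edge distance densities and class priors.

    The edge mixture is trained on Euclidean distances of the MST training
    edges only; the non-edge mixture on a seeded uniform sample of pairs
    outside the evolved training network. The edge prior defaults to the
    training-graph density 2(n-1)/(n(n-1)).
    """
    if nonedge_sample < k:
        raise ValueError("nonedge_sample must be at least k")
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    trn = np.array(sorted(split.trn_edges), dtype=np.intp)
    edge_d = pairwise_euclidean(coords, trn)
    nonedge_pairs = _sample_nonedge_pairs(n, evolved_edges, nonedge_sample, rng)
    nonedge_d = pairwise_euclidean(coords, nonedge_pairs)
    edge_mix = fit_gmm_em(edge_d, k=k, seed=seed)
    nonedge_mix = fit_gmm_em(nonedge_d, k=k, seed=seed + 1)
    if p_edge is None:
        p_edge = 2.0 * (n - 1) / (n * (n - 1))
    if not 0.0 < p_edge < 1.0:
        raise ValueError("p_edge must lie strictly between 0 and 1")
    return DensityModel(edge_mix, nonedge_mix, p_edge)


def predict_by_threshold(emb: EmbeddingResult | np.ndarray, epsilon: float,
                         trn_edges: frozenset = frozenset()) -> frozenset:
    """All unordered non-training pairs at Euclidean distance <= epsilon."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = pairwise_euclidean(coords, np.column_stack([iu, ju]))
    hit = d <= epsilon
    return frozenset((int(i), int(j))
                     for i, j in zip(iu[hit].tolist(), ju[hit].tolist())
                     if (i, j) not in trn_edges)
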