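"""Geometric embedding of a distance matrix.

Two backends are provided. Classical multidimensional scaling (MDS; Isomap
when the input is a graph-geodesic matrix) double-centers the entrywise
squared distances, A = -½·J·D²·J with J = I - n⁻¹·11', and takes the top-m
eigenpairs of A, giving coordinates X = E_m·Λ_m^{1/2}. Graph distances are
generally not exactly Euclidean-realizable, so negative retained
eigenvalues are clamped to zero (their coordinate column is zero), the
standard classical-MDS convention. The non-centered SVD backend decomposes
D itself, X = U_m·Σ_m^{1/2}, the minimum-curvilinearity-style variant.

Both backends fix each coordinate column's sign by making its
largest-magnitude entry positive, so the embedding of a fixed matrix is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class EmbeddingResult:
    """Coordinates plus the retained spectrum of the decomposition."""

    coords: np.ndarray           # (n, m)
    spectrum: np.ndarray         # m retained eigen- or singular values
    backend: str                 # "mds" | "ncsvd"

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


def _check_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=_SYM_TOL):
        raise ValueError("distance matrix must be symmetric")
    return d


def double_center(d: np.ndarray) -> np.ndarray:
    """Gram matrix A = -½·J·D²·J of the squared-distance matrix.

    Row and column sums of the result are zero to numerical tolerance.
    """
    d = _check_distance_matrix(d)
    if not np.allclose(np.diag(d), 0.0, atol=_SYM_TOL):
        raise ValueError("distance matrix must have a zero diagonal")
    d2 = d ** 2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    a = -0.5 * (d2 - row - col + grand)
    return 0.5 * (a + a.T)  # kill round-off asymmetry


def _fix_signs(x: np.ndarray) -> np.ndarray:
    for c in range(x.shape[1]):
        col = x[:, c]
        if col.any():
            k = int(np.argmax(np.abs(col)))
            if col[k] < 0:
                x[:, c] = -col
    return x


def embed_mds(d: np.ndarray, m: int = 5) -> EmbeddingResult:
    """Classical MDS embedding into m dimensions.

    Eigenpairs are ranked by algebraic eigenvalue; negative retained
    eigenvalues contribute zero coordinate columns.
    """
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if not 1 <= m <= max(n - 1, 1):
        raise ValueError(f"dimension m={m} out of range for n={n}")
    a = double_center(d)
    vals, vecs = linalg.eigh(a)            # ascending
    order = np.argsort(vals)[::-1][:m]
    lam = vals[order]
    e = vecs[:, order]
    coords = e * np.sqrt(np.clip(lam, 0.0, None))
    return EmbeddingResult(_fix_signs(coords), lam, "mds")


def embed_ncsvd(d: np.ndarray, m: int = 5) -> EmbeddingResult:
    """Non-centered SVD embedding: X = U_m·Σ_m^{1/2} of D itself."""
    d = _check_distance_matrix(d)
    n = d.shape[0]
    if not 1 <= m <= max(n - 1, 1):
        raise ValueError(f"dimension m={m} out of range for n={n}")
    u, s, _ = linalg.svd(d)
    coords = u[:, :m] * np.sqrt(s[:m])
    return EmbeddingResult(_fix_signs(coords), s[:m].copy(), "ncsvd")


def pairwise_euclidean(emb: EmbeddingResult | np.ndarray,
                       pairs: np.ndarray) -> np.ndarray:
    """Euclidean distances between the given index pairs of the embedding."""
    coords = emb.coords if isinstance(emb, EmbeddingResult) else np.asarray(emb)
    pairs = np.asarray(pairs, dtype=np.intp)
    if pairs.size == 0:
        return np.zeros(0)
    if pairs.min() < 0 or pairs.max() >= coords.shape[0]:
        raise IndexError("pair index out of range")
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.sqrt((diff * diff).sum(axis=1))


class _BaseEmbedding(BaseEstimator, TransformerMixin):
    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    _backend = "mds"

    def fit(self, X: np.ndarray, y=None):
        fn = embed_mds if self._backend == "mds" else embed_ncsvd
        res = fn(X, self.n_components)
        self.embedding_ = res.coords
        self.spectrum_ = res.spectrum
        self.result_ = res
        return self

    def transform(self, X: np.ndarray = None) -> np.ndarray:
        return self.embedding_

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).embedding_


class ClassicalMDS(_BaseEmbedding):
    """Classical (Torgerson) MDS on a precomputed distance matrix.

    Equivalent to Isomap when the matrix holds graph geodesics. Default
    target dimension is 5.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
    spectrum_ : ndarray
        Retained eigenvalues in descending order (possibly negative).
    """

    _backend = "mds"


class NonCenteredSVD(_BaseEmbedding):
    """Non-centered SVD embedding of the raw distance matrix.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
    spectrum_ : ndarray
        Retained singular values in non-increasing order.
    """

    _backend = "ncsvd"
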