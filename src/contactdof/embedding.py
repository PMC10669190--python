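"""Low-dimensional conformation projections of contact DOFs.

Per-frame binary contact vectors are treated as raw coordinates of
conformation space and projected onto collective degrees of freedom by PCA
(covariance scaling, implemented here via SVD of the centered data matrix)
or by UMAP (delegated to umap-learn behind a stable, seeded interface).

PCA component signs are fixed by convention: the largest-magnitude loading
of each component is made positive, so projections are reproducible across
runs and BLAS backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "EmbeddingResult",
    "ContactPCA",
    "ContactUMAP",
    "pca_embed",
    "nonlinear_embed",
    "joint_embed",
]


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates plus, for PCA, the spectral bookkeeping."""

    coordinates: np.ndarray          # (F, k)
    method: str
    params: dict = field(default_factory=dict)
    components: Optional[np.ndarray] = None        # (k, D) loadings
    explained_variance: Optional[np.ndarray] = None
    total_variance: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


def _validate_matrix(X: np.ndarray) -> np.ndarray:
    try:
        X = np.asarray(X, dtype=float)
    except ValueError as err:
        raise ValueError("inconsistent contact-vector lengths") from err
    if X.ndim != 2:
        raise ValueError(
            "expected a 2-D (frames x DOFs) matrix; got inconsistent "
            "vector lengths or a single vector"
        )
    if X.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    return X


class ContactPCA(TransformerMixin, BaseEstimator):
    """PCA of contact-DOF vectors on the covariance (not correlation) scale.

    Fitted attributes
    -----------------
    components_ : (k, D) orthonormal loading vectors over contact DOFs
    explained_variance_ : per-component variance (denominator n - 1),
        non-increasing
    total_variance_ : sum of per-DOF variances of the centered data; equals
        the sum of all D eigenvalues
    mean_ : (D,) per-DOF mean removed before decomposition
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None) -> "ContactPCA":
        X = _validate_matrix(X)
        n, d = X.shape
        if not (1 <= self.n_components <= d):
            raise ValueError(f"n_components must be in [1, {d}]")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # SVD route; the covariance-eigendecomposition equivalent is kept as
        # an independent oracle in the test suite
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2 / (n - 1)
        comps = vt
        # sign convention: largest-|loading| entry positive
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
        k = self.n_components
        self.components_ = comps[:k]
        self.explained_variance_ = var[:k]
        self.singular_values_ = s[:k]
        self.all_eigenvalues_ = var
        self.total_variance_ = float(Xc.var(axis=0, ddof=1).sum())
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} DOFs, fitted on {self.n_features_in_}"
            )
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Y) -> np.ndarray:
        return np.asarray(Y, float) @ self.components_ + self.mean_

    def result(self, X) -> EmbeddingResult:
        return EmbeddingResult(
            coordinates=self.transform(X),
            method="pca",
            params={"n_components": self.n_components},
            components=self.components_,
            explained_variance=self.explained_variance_,
            total_variance=self.total_variance_,
        )


class ContactUMAP(TransformerMixin, BaseEstimator):
    """Seeded UMAP of contact-DOF vectors (delegated to umap-learn).

    Defaults (15 neighbors, min_dist 0.1, seed 42) are recorded in every
    result.  Degenerate input in which all frames share one contact vector
    is short-circuited to the all-zero embedding with a warning, since the
    manifold backend has no meaningful neighborhood graph to optimize.
    """

    def __init__(self, n_components: int = 2, n_neighbors: int = 15,
                 min_dist: float = 0.1, random_state: int = 42):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.random_state = random_state

    def fit_transform(self, X, y=None) -> np.ndarray:
        X = _validate_matrix(X)
        if X.shape[0] <= self.n_neighbors:
            raise ValueError(
                f"need more than n_neighbors={self.n_neighbors} frames, "
                f"got {X.shape[0]}"
            )
        if np.allclose(X, X[0]):
            warnings.warn(
                "all contact vectors are identical; returning a degenerate "
                "all-zero embedding", RuntimeWarning, stacklevel=2)
            self.embedding_ = np.zeros((X.shape[0], self.n_components))
            return self.embedding_
        import umap  # deferred: numba compilation is expensive at import

        self._reducer_ = umap.UMAP(
            n_components=self.n_components, n_neighbors=self.n_neighbors,
            min_dist=self.min_dist, random_state=self.random_state,
        )
        self.embedding_ = np.asarray(self._reducer_.fit_transform(X), float)
        return self.embedding_

    def fit(self, X, y=None) -> "ContactUMAP":
        self.fit_transform(X)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "_reducer_"):
            raise RuntimeError("ContactUMAP must be fitted first")
        return np.asarray(self._reducer_.transform(np.asarray(X, float)), float)

    def result(self) -> EmbeddingResult:
        return EmbeddingResult(
            coordinates=self.embedding_,
            method="umap",
            params={
                "n_components": self.n_components,
                "n_neighbors": self.n_neighbors,
                "min_dist": self.min_dist,
                "random_state": self.random_state,
            },
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def pca_embed(vectors: np.ndarray, k: int = 2) -> EmbeddingResult:
    """Project contact vectors onto the top-k principal components."""
    est = ContactPCA(n_components=k).fit(vectors)
    return est.result(np.asarray(vectors, float))


def nonlinear_embed(vectors: np.ndarray, k: int = 2,
                    n_neighbors: int = 15, min_dist: float = 0.1,
                    random_state: int = 42) -> EmbeddingResult:
    """Seeded UMAP projection of contact vectors."""
    est = ContactUMAP(n_components=k, n_neighbors=n_neighbors,
                      min_dist=min_dist, random_state=random_state)
    est.fit_transform(vectors)
    return est.result()


def joint_embed(named_vectors: dict[str, np.ndarray], method: str = "pca",
                k: int = 2, **params) -> dict[str, EmbeddingResult]:
    """One embedding fitted on pooled frames; per-ensemble projections.

    All vector matrices must share dimensionality.  Projections of every
    named ensemble live in the same collective-coordinate system, which is
    what makes cross-system comparisons meaningful.
    """
    if not named_vectors:
        raise ValueError("no ensembles given")
    mats = {name: _validate_matrix(v) for name, v in named_vectors.items()}
    dims = {m.shape[1] for m in mats.values()}
    if len(dims) > 1:
        raise ValueError(f"contact-vector dimensionality differs: {sorted(dims)}")
    pooled = np.vstack(list(mats.values()))

    out: dict[str, EmbeddingResult] = {}
    if method == "pca":
        est = ContactPCA(n_components=k, **params).fit(pooled)
        for name, m in mats.items():
            res = est.result(m)
            res.params["pooled_frames"] = pooled.shape[0]
            out[name] = res
    elif method == "umap":
        est = ContactUMAP(n_components=k, **params)
        emb = est.fit_transform(pooled)
        ofs = 0
        for name, m in mats.items():
            res = EmbeddingResult(coordinates=emb[ofs:ofs + m.shape[0]],
                                  method="umap", params=dict(est.get_params()))
            res.params["pooled_frames"] = pooled.shape[0]
            out[name] = res
            ofs += m.shape[0]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return out
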