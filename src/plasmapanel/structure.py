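"""Unsupervised structure: dissimilarity matrices, classical MDS and PCA.

Replicate runs (or protein profiles) are embedded with classical Torgerson
scaling: square the dissimilarities, double-center, eigendecompose, and scale
the leading eigenvectors by the square roots of the positive eigenvalues.  On
a Euclidean dissimilarity matrix this is exactly PCA of the underlying
configuration, which the :func:`pca_check` Procrustes comparison exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .quantio import CONDITIONS, QuantMatrix

_SUPPORTED_METRICS = ("euclidean", "correlation", "cityblock", "cosine")


@dataclass
class DissimilarityMatrix:
    """Square symmetric non-negative dissimilarities with labels."""

    labels: list[str]
    D: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("D must be square and match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("D must be symmetric")
        if (self.D < -1e-12).any():
            raise ValueError("D must be non-negative")
        self.D = np.maximum((self.D + self.D.T) / 2.0, 0.0)
        np.fill_diagonal(self.D, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class Embedding:
    """Low-dimensional coordinates plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    dims_kept: int
    negative_mass: float = 0.0
    info: dict = field(default_factory=dict)


def _profiles(m: QuantMatrix, proteins=None, log_scale: bool = True) -> pd.DataFrame:
    """Run x protein profiles; proteins with any missing value are dropped."""
    vals = m.values if (m.scale == "log" or not log_scale) else None
    if vals is None:
        linear = m.linear_values()
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(linear.where(linear > 0))
    if proteins is not None:
        absent = [p for p in proteins if p not in vals.index]
        if absent:
            raise KeyError(f"proteins absent from matrix: {absent}")
        vals = vals.loc[list(proteins)]
    return vals.dropna(axis=0).T  # runs x proteins


def condition_dissimilarity(m: QuantMatrix, proteins=None,
                            metric: str = "euclidean") -> DissimilarityMatrix:
    """Pairwise distances between replicate runs over a protein subset
    (default: Euclidean on log-normalized values)."""
    if metric not in _SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    X = _profiles(m, proteins)
    D = squareform(pdist(X.to_numpy(dtype=float), metric=metric))
    return DissimilarityMatrix(list(X.index), D, metric)


def _correlation_distance(P: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; rows with zero variance get distance 1
    to everything (no linear association is defensible for a flat profile)."""
    C = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(C, axis=1)
    n = P.shape[0]
    D = np.ones((n, n))
    ok = norms > 0
    if ok.any():
        U = C[ok] / norms[ok, None]
        D[np.ix_(ok, ok)] = 1.0 - U @ U.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def protein_dissimilarity(m: QuantMatrix, proteins=None, metric: str = "correlation",
                          standardize: bool = True) -> DissimilarityMatrix:
    """Distances between protein profiles over the five condition means.

    Profiles are per-protein z-scored across the condition means by default so
    that the stage response, not absolute abundance, drives the distances.
    """
    if metric not in _SUPPORTED_METRICS:
        raise ValueError(f"unsupported metric {metric!r}")
    X = _profiles(m, proteins)  # runs x proteins
    conds = m.meta.loc[X.index, "condition"]
    means = X.groupby(conds, sort=False).mean().reindex([c for c in CONDITIONS
                                                         if c in set(conds)])
    P = means.T.to_numpy(dtype=float)  # proteins x conditions
    labels = list(means.columns)
    if standardize:
        mu = P.mean(axis=1, keepdims=True)
        sd = P.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        P = (P - mu) / sd
    if metric == "correlation":
        D = _correlation_distance(P)
    else:
        D = squareform(pdist(P, metric=metric))
    return DissimilarityMatrix(labels, D, metric)


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) multidimensional scaling.

    Parameters
    ----------
    n_components : number of embedding dimensions requested (default 3, the
        number of dimensions plotted downstream).

    Attributes
    ----------
    embedding_ : item x dimension coordinates.
    eigenvalues_ : full spectrum of the double-centered matrix, descending.
    negative_mass_ : |sum of negative eigenvalues| / sum of |eigenvalues|;
        non-zero for non-Euclidean dissimilarities (those axes are truncated).
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, D: DissimilarityMatrix | np.ndarray, y=None):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if isinstance(D, DissimilarityMatrix):
            labels, M = D.labels, D.D
        else:
            M = np.asarray(D, dtype=float)
            labels = [str(i) for i in range(M.shape[0])]
        n = M.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (M ** 2) @ J
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        tol = max(abs(w[0]), 1.0) * 1e-12 if n else 0.0
        pos = w > tol
        if not pos.any():
            raise ValueError("degenerate dissimilarity: no positive eigenvalues")
        neg_mass = float(-w[w < -tol].sum() / np.abs(w).sum()) if (w < -tol).any() else 0.0
        k = int(min(self.n_components, pos.sum()))
        coords = V[:, :k] * np.sqrt(w[:k])
        # deterministic sign: largest-|coordinate| entry of each axis positive
        for j in range(k):
            i = int(np.argmax(np.abs(coords[:, j])))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        self.eigenvalues_ = w
        self.negative_mass_ = neg_mass
        self.dims_kept_ = k
        self.embedding_ = pd.DataFrame(coords, index=labels,
                                       columns=[f"dim{i + 1}" for i in range(k)])
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_.to_numpy()

    def to_embedding(self) -> Embedding:
        check_is_fitted(self, "embedding_")
        return Embedding(self.embedding_, self.eigenvalues_, self.dims_kept_,
                         self.negative_mass_)


def classical_mds(D: DissimilarityMatrix, dims: int = 3) -> Embedding:
    """Functional wrapper over :class:`ClassicalMDS`."""
    return ClassicalMDS(n_components=dims).fit(D).to_embedding()


def pca_check(m: QuantMatrix, proteins=None, n_components: int = 3) -> Embedding:
    """PCA of centered run profiles; verifies the Euclidean-MDS configuration.

    The eigenvalues are scaled by (n - 1) so they match the Torgerson spectrum
    of the Euclidean dissimilarity matrix of the same profiles.
    """
    X = _profiles(m, proteins)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 runs")
    k = min(n_components, n - 1, X.shape[1])
    pca = PCA(n_components=k, random_state=0)
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    coords = pd.DataFrame(scores, index=list(X.index),
                          columns=[f"dim{i + 1}" for i in range(k)])
    eig = pca.explained_variance_ * (n - 1)
    return Embedding(coords, np.asarray(eig), k,
                     info={"explained_variance_ratio": pca.explained_variance_ratio_.tolist()})


def procrustes_disparity(a: Embedding | pd.DataFrame | np.ndarray,
                         b: Embedding | pd.DataFrame | np.ndarray) -> float:
    """Procrustes disparity (scipy convention: sum of squared residuals after
    optimal translation/rotation/scaling of standardized configurations)."""
    from scipy.spatial import procrustes

    def coords(x):
        if isinstance(x, Embedding):
            x = x.coordinates
        if isinstance(x, pd.DataFrame):
            x = x.to_numpy()
        return np.asarray(x, dtype=float)

    A, B = coords(a), coords(b)
    k = min(A.shape[1], B.shape[1])
    _, _, disparity = procrustes(A[:, :k], B[:, :k])
    return float(disparity)
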