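"""Unsupervised differentiation of the two classes.

Each spectrum is standardized (mean 0, unit population SD), pairwise
cosine affinities form the graph, and normalized spectral clustering with
k = 2 partitions the spectra. Agreement with the true labels is measured
by the Matthews correlation coefficient and the density-form confusion
matrix; cluster indices carry no class meaning, so the label orientation
maximizing the MCC is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, InvalidConfigError, ShapeError

__all__ = [
    "AffinityMatrix",
    "ConfusionMatrix",
    "standardize_spectrum",
    "standardize_rows",
    "cosine_affinity",
    "spectral_clustering",
    "mcc",
    "evaluate_clustering",
]


def standardize_spectrum(x: np.ndarray) -> np.ndarray:
    """(x - mean) / SD with the population SD, so the output SD is exactly 1."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("cannot standardize a constant spectrum")
    return (x - x.mean()) / sd


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise standardization of an N x p matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError(
            f"constant spectrum at row {int(np.flatnonzero(sd.ravel() == 0)[0])}"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sd


@dataclass
class AffinityMatrix:
    """Symmetric cosine-affinity matrix with unit diagonal."""

    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.ndim != 2 or self.kappa.shape[0] != self.kappa.shape[1]:
            raise ShapeError("affinity matrix must be square")


def cosine_affinity(X: np.ndarray) -> AffinityMatrix:
    """kappa(x, y) = <x, y> / sqrt(<x, x><y, y>) for all row pairs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError(
            f"zero-norm spectrum at row {int(np.flatnonzero(norms == 0)[0])}"
        )
    K = (X / norms[:, None]) @ (X / norms[:, None]).T
    np.fill_diagonal(K, 1.0)
    return AffinityMatrix(np.clip((K + K.T) / 2, -1.0, 1.0))


def spectral_clustering(
    affinity: AffinityMatrix | np.ndarray,
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> np.ndarray:
    """Normalized spectral clustering on a cosine-affinity graph.

    Negative affinities are clipped to zero, the symmetric normalized
    Laplacian L = I - D^{-1/2} K D^{-1/2} is formed, the k eigenvectors of
    smallest eigenvalue embed the spectra, and seeded k-means (``n_init``
    restarts) labels them. A graph with more than k near-zero Laplacian
    eigenvalues (extra connected components, or an affinity with no
    structure) triggers a degeneracy warning but still returns a partition.
    """
    K = affinity.kappa if isinstance(affinity, AffinityMatrix) else np.asarray(affinity, dtype=float)
    n = K.shape[0]
    if k != 2:
        raise InvalidConfigError("only k=2 clustering is supported")
    if n < k:
        raise InvalidConfigError(f"need at least {k} spectra, got {n}")
    W = np.clip(K, 0.0, None)
    deg = W.sum(axis=1)
    if np.any(deg == 0):
        warnings.warn("isolated vertices in the affinity graph", stacklevel=2)
        deg = np.where(deg == 0, 1.0, deg)
    dinv = 1.0 / np.sqrt(deg)
    L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    n_check = min(n - 1, k)
    vals, vecs = eigh(L, subset_by_index=[0, n_check])
    # more than k (near-)connected components, or an embedding that is not
    # uniquely determined (no eigengap after the k-th eigenvalue)
    degenerate = np.sum(vals < 1e-10) > k or (
        n_check == k and vals[k] - vals[k - 1] < 1e-8
    )
    if degenerate:
        warnings.warn(
            "degenerate affinity structure: the 2-way split may be seed-dependent",
            stacklevel=2,
        )
    embedding = vecs[:, :k]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(embedding)


@dataclass
class ConfusionMatrix:
    """Counts n_ij: true label i, predicted label j."""

    n00: int
    n01: int
    n10: int
    n11: int

    def __post_init__(self) -> None:
        if min(self.n00, self.n01, self.n10, self.n11) < 0:
            raise InvalidConfigError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, true: np.ndarray, pred: np.ndarray) -> "ConfusionMatrix":
        true = np.asarray(true, dtype=int)
        pred = np.asarray(pred, dtype=int)
        if true.shape != pred.shape:
            raise ShapeError("true and predicted labels must have equal length")
        return cls(
            n00=int(np.sum((true == 0) & (pred == 0))),
            n01=int(np.sum((true == 0) & (pred == 1))),
            n10=int(np.sum((true == 1) & (pred == 0))),
            n11=int(np.sum((true == 1) & (pred == 1))),
        )

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n10 + self.n11

    @property
    def densities(self) -> np.ndarray:
        """2x2 matrix of cell counts divided by N (rows: true 0/1)."""
        return np.array([[self.n00, self.n01], [self.n10, self.n11]]) / self.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    (n00*n11 - n01*n10) / sqrt((n00+n10)(n00+n01)(n11+n10)(n11+n01));
    by convention 0 when any marginal factor vanishes (e.g. everything
    predicted into one cluster).
    """
    num = cm.n00 * cm.n11 - cm.n01 * cm.n10
    factors = (
        (cm.n00 + cm.n10)
        * (cm.n00 + cm.n01)
        * (cm.n11 + cm.n10)
        * (cm.n11 + cm.n01)
    )
    if factors == 0:
        return 0.0
    return float(num / np.sqrt(factors))


def evaluate_clustering(pred: np.ndarray, true: np.ndarray) -> tuple[ConfusionMatrix, float]:
    """Best-orientation agreement between a 2-way partition and the labels.

    Cluster indices are arbitrary, so both labelings of the two clusters
    are scored and the orientation with the larger MCC is reported.
    """
    pred = np.asarray(pred, dtype=int)
    true = np.asarray(true, dtype=int)
    if pred.shape != true.shape:
        raise ShapeError("predicted and true labels must have equal length")
    cm_a = ConfusionMatrix.from_labels(true, pred)
    cm_b = ConfusionMatrix.from_labels(true, 1 - pred)
    if mcc(cm_a) >= mcc(cm_b):
        return cm_a, mcc(cm_a)
    return cm_b, mcc(cm_b)
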