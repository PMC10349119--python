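"""The four non-neural classifiers and the shared evaluation harness.

* LRA  — logistic regression on the global mean intensity of the region.
* L2D  — tau-weighted nearest-mean rule on squared l2 distances to the two
  class-average spectra: predict class 1 iff tau*d1 <= (1-tau)*d2.
* LRP  — logistic regression on average-pooled features over
  non-overlapping, non-equispaced wavenumber sub-domains, with permutation
  importance for interpretability.
* PCA  — logistic regression on the leading principal-component scores.

All models are scored by ten-fold stratified cross-validated ROC-AUC with
the standard error of the mean over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .dataset import SpectralDataset
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidConfigError,
    ShapeError,
    UndefinedAUCError,
)

__all__ = [
    "ClassMeans",
    "L2DModel",
    "LogisticModel",
    "PoolingScheme",
    "PCAModel",
    "CVResult",
    "ImportanceScores",
    "class_means",
    "l2_distance_sq",
    "l2d_margin",
    "l2d_classify",
    "fit_l2d",
    "global_mean_feature",
    "average_pooling",
    "default_pooling_scheme",
    "fit_logistic",
    "fit_pca",
    "project",
    "classify_threshold",
    "roc_auc",
    "cross_validate",
    "permutation_importance",
    "LRAClassifier",
    "L2DClassifier",
    "PoolingLogisticClassifier",
    "PCALogisticClassifier",
]


# ---------------------------------------------------------------------------
# class means and the tau-weighted l2 rule


@dataclass
class ClassMeans:
    """Average spectra of the two samples: h1 (label 1), h2 (label 0)."""

    h1: np.ndarray
    h2: np.ndarray

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=float)
        self.h2 = np.asarray(self.h2, dtype=float)
        if self.h1.shape != self.h2.shape:
            raise ShapeError("h1 and h2 must have equal length")
        if not (np.isfinite(self.h1).all() and np.isfinite(self.h2).all()):
            raise DegenerateInputError("class means must be finite")


def class_means(train: SpectralDataset) -> ClassMeans:
    """Columnwise mean spectrum of each label group of the training set."""
    m1 = train.labels == 1
    m0 = train.labels == 0
    if not m1.any() or not m0.any():
        raise InsufficientDataError("both labels must be present to form class means")
    return ClassMeans(h1=train.intensities[m1].mean(axis=0), h2=train.intensities[m0].mean(axis=0))


def l2_distance_sq(x: np.ndarray, h: np.ndarray) -> np.ndarray | float:
    """Squared l2 distance sum_s |x_s - h_s|^2 (no square root).

    ``x`` may be a single spectrum or an (N, p) matrix; ``h`` a length-p
    vector.
    """
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if x.shape[-1] != h.shape[-1]:
        raise ShapeError(f"length mismatch: {x.shape[-1]} vs {h.shape[-1]}")
    d = ((x - h) ** 2).sum(axis=-1)
    return float(d) if d.ndim == 0 else d


@dataclass
class L2DModel:
    """Fitted tau-weighted nearest-mean rule."""

    means: ClassMeans
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise InvalidConfigError(f"tau must lie in [0, 1], got {self.tau}")


def l2d_margin(x: np.ndarray, model: L2DModel) -> np.ndarray | float:
    """Decision margin (1-tau)*d2 - tau*d1; positive means class 1."""
    d1 = l2_distance_sq(x, model.means.h1)
    d2 = l2_distance_sq(x, model.means.h2)
    return (1.0 - model.tau) * d2 - model.tau * d1


def l2d_classify(x: np.ndarray, model: L2DModel) -> np.ndarray | int:
    """Predict 1 iff tau*d1 <= (1-tau)*d2 (ties to class 1)."""
    m = np.asarray(l2d_margin(x, model))
    out = (m >= 0).astype(int)
    return int(out) if out.ndim == 0 else out


def _tie_break_toward_half(grid: np.ndarray, objective: np.ndarray) -> float:
    best = objective.max()
    candidates = grid[np.isclose(objective, best, rtol=0, atol=1e-12)]
    return float(candidates[np.argmin(np.abs(candidates - 0.5))])


def fit_l2d(
    train: SpectralDataset,
    tau_grid: np.ndarray | None = None,
    inner_folds: int = 10,
    seed: int = 0,
) -> L2DModel:
    """Select tau on a grid by inner stratified CV AUC of the margin score.

    Ties are broken toward tau = 0.5 (the plain nearest-centroid rule).
    """
    grid = np.linspace(0, 1, 51) if tau_grid is None else np.asarray(tau_grid, dtype=float)
    if grid.size == 0:
        raise InvalidConfigError("tau grid must be non-empty")
    if grid.min() < 0 or grid.max() > 1:
        raise InvalidConfigError("tau grid must lie in [0, 1]")
    if grid.size == 1:
        return L2DModel(means=class_means(train), tau=float(grid[0]))
    n_folds = min(inner_folds, int(np.bincount(train.labels, minlength=2).min()))
    if n_folds < 2:
        return L2DModel(means=class_means(train), tau=0.5)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((n_folds, grid.size))
    for f, (tr, te) in enumerate(skf.split(train.intensities, train.labels)):
        means = class_means(train.subset_rows(tr))
        d1 = l2_distance_sq(train.intensities[te], means.h1)
        d2 = l2_distance_sq(train.intensities[te], means.h2)
        y = train.labels[te]
        for j, tau in enumerate(grid):
            scores[f, j] = roc_auc((1 - tau) * d2 - tau * d1, y)
    tau = _tie_break_toward_half(grid, scores.mean(axis=0))
    return L2DModel(means=class_means(train), tau=tau)


# ---------------------------------------------------------------------------
# pooled / global features and logistic regression


def global_mean_feature(x: np.ndarray) -> np.ndarray | float:
    """Mean intensity over the selected region (the LRA predictor)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InvalidConfigError("cannot average an empty spectrum")
    m = x.mean(axis=-1)
    return float(m) if m.ndim == 0 else m


@dataclass(frozen=True)
class PoolingScheme:
    """Non-overlapping, non-equispaced wavenumber sub-domains.

    ``boundaries`` are the m+1 strictly increasing cut points of m bins;
    bin i is [b_i, b_{i+1}), with the last bin closed on the right.
    """

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size < 2 or not np.all(np.diff(b) > 0):
            raise InvalidConfigError("boundaries must be >= 2 strictly increasing cut points")

    @property
    def n_features(self) -> int:
        return len(self.boundaries) - 1

    def bin_indices(self, wavenumbers: np.ndarray) -> list[np.ndarray]:
        b = np.asarray(self.boundaries)
        bins = []
        for i in range(self.n_features):
            if i == self.n_features - 1:
                mask = (wavenumbers >= b[i]) & (wavenumbers <= b[i + 1])
            else:
                mask = (wavenumbers >= b[i]) & (wavenumbers < b[i + 1])
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                raise InvalidConfigError(
                    f"pooling sub-domain [{b[i]}, {b[i + 1]}] contains no axis point"
                )
            bins.append(idx)
        return bins

    def centers(self) -> np.ndarray:
        b = np.asarray(self.boundaries)
        return (b[:-1] + b[1:]) / 2


#: Default schemes: 4 features in LW, 3 in HW, aligned with the named
#: sub-bands 480-548, 2701-3200 and 3200-3399 cm^-1.
DEFAULT_POOLING = {
    "LW": PoolingScheme((125.25, 234.0, 360.0, 480.0, 549.27)),
    "HW": PoolingScheme((2303.16, 2700.0, 3200.0, 3399.83)),
}


def default_pooling_scheme(region_name: str) -> PoolingScheme:
    try:
        return DEFAULT_POOLING[region_name.upper()]
    except KeyError as exc:
        raise InvalidConfigError(f"no default pooling scheme for region {region_name!r}") from exc


def average_pooling(x: np.ndarray, scheme: PoolingScheme, wavenumbers: np.ndarray) -> np.ndarray:
    """Mean intensity per sub-domain, ordered by wavenumber.

    Accepts a single spectrum (returns (m,)) or an (N, p) matrix
    (returns (N, m)).
    """
    x = np.asarray(x, dtype=float)
    bins = scheme.bin_indices(np.asarray(wavenumbers))
    feats = [x[..., idx].mean(axis=-1) for idx in bins]
    return np.stack(feats, axis=-1)


@dataclass
class LogisticModel:
    """L2-penalized logistic regression Pr(W=1|z) = sigmoid(b0 + b.z)."""

    beta0: float
    betas: np.ndarray
    shrinkage: float = 1.0
    threshold: float = 0.5
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if not (np.isfinite(self.beta0) and np.isfinite(self.betas).all()):
            raise DegenerateInputError("logistic coefficients must be finite")
        if not 0.0 <= self.threshold <= 1.0:
            raise InvalidConfigError("threshold must lie in [0, 1]")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(features, dtype=float))
        if self.feature_means is not None:
            z = (z - self.feature_means) / self.feature_scales
        eta = self.beta0 + z @ self.betas
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return classify_threshold(self.predict_proba(features), self.threshold)


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    shrinkage: float = 1.0,
    standardize: bool = True,
) -> LogisticModel:
    """Fit the L2-penalized logistic regression (penalty weight = shrinkage).

    The intercept is not penalized. Features are standardized internally
    (the returned model applies the same transform at prediction time) so
    the penalty acts on comparable scales.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and np.asarray(labels).size > 1:
        X = X.T
    y = np.asarray(labels, dtype=int)
    if not np.isfinite(X).all():
        raise DegenerateInputError("features must be finite")
    if len(set(y.tolist())) < 2:
        raise InsufficientDataError("both labels must be present")
    if shrinkage <= 0:
        raise InvalidConfigError("shrinkage must be > 0")
    means = scales = None
    if standardize:
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)
        X = (X - means) / scales
    clf = LogisticRegression(C=1.0 / shrinkage, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    return LogisticModel(
        beta0=float(clf.intercept_[0]),
        betas=clf.coef_[0],
        shrinkage=shrinkage,
        feature_means=means,
        feature_scales=scales,
    )


def classify_threshold(probs: np.ndarray, lam: float) -> np.ndarray:
    """Predict 1 iff Pr(W=1) >= lambda."""
    if not 0.0 <= lam <= 1.0:
        raise InvalidConfigError(f"lambda must lie in [0, 1], got {lam}")
    p = np.asarray(probs, dtype=float)
    return (p >= lam).astype(int)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Principal components of the column-centered intensity matrix.

    ``loadings`` is p x m with orthonormal columns v_1..v_m (eigenvectors
    of Y^T Y by descending eigenvalue); ``variances`` are the component
    variances; ``proportions`` the per-component shares of the total
    columnwise variance.
    """

    loadings: np.ndarray
    variances: np.ndarray
    column_means: np.ndarray
    total_variance: float

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    @property
    def proportions(self) -> np.ndarray:
        return self.variances / self.total_variance

    @property
    def cumulative_proportions(self) -> np.ndarray:
        return np.cumsum(self.proportions)

    @property
    def standard_deviations(self) -> np.ndarray:
        return np.sqrt(self.variances)


def fit_pca(data: SpectralDataset | np.ndarray, m_policy: int | float | None = None) -> PCAModel:
    """PCA by eigendecomposition of the covariance of column-centered data.

    ``m_policy``: an int keeps that many components; a float in (0, 1]
    keeps the smallest m whose cumulative proportion of variance reaches
    the threshold, capped at 5; ``None`` uses the default policy
    (cumulative variance >= 0.999, capped at 5).
    """
    X = data.intensities if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 spectra")
    column_means = X.mean(axis=0)
    Y = X - column_means
    total = float((Y**2).sum() / (n - 1))
    if total == 0:
        raise DegenerateInputError("zero-variance data")
    # SVD of Y gives the eigenvectors of Y^T Y without forming the p x p matrix
    _, s, vt = np.linalg.svd(Y, full_matrices=False)
    variances = s**2 / (n - 1)
    loadings = vt.T
    # fix each eigenvector's sign: largest-magnitude loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    if m_policy is None:
        m_policy = 0.999
    if isinstance(m_policy, float):
        if not 0 < m_policy <= 1:
            raise InvalidConfigError("fractional m_policy must lie in (0, 1]")
        cum = np.cumsum(variances) / total
        m = int(np.searchsorted(cum, m_policy - 1e-12) + 1)
        m = min(m, 5, variances.size)
    else:
        m = int(m_policy)
        if not 1 <= m <= variances.size:
            raise InvalidConfigError(f"m must lie in [1, {variances.size}]")
    return PCAModel(
        loadings=loadings[:, :m],
        variances=variances[:m],
        column_means=column_means,
        total_variance=total,
    )


def project(data: SpectralDataset | np.ndarray, model: PCAModel) -> np.ndarray:
    """Component scores z = (X - column_means) @ loadings."""
    X = data.intensities if isinstance(data, SpectralDataset) else np.asarray(data, dtype=float)
    X = np.atleast_2d(X)
    if X.shape[1] != model.column_means.shape[0]:
        raise ShapeError(
            f"{X.shape[1]} columns but the model was fitted on {model.column_means.shape[0]}"
        )
    return (X - model.column_means) @ model.loadings


# ---------------------------------------------------------------------------
# ROC-AUC and cross-validation


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney ROC-AUC: P(random positive outranks random negative),
    ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ShapeError("scores and labels must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("ROC-AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class CVResult:
    """Per-fold ROC-AUCs with their mean and standard error."""

    fold_aucs: np.ndarray

    def __post_init__(self) -> None:
        self.fold_aucs = np.asarray(self.fold_aucs, dtype=float)

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def sem(self) -> float:
        if self.fold_aucs.size < 2:
            return 0.0
        return float(self.fold_aucs.std(ddof=1) / np.sqrt(self.fold_aucs.size))


def cross_validate(model_factory, ds: SpectralDataset, k: int = 10, seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validated ROC-AUC.

    ``model_factory()`` must return an estimator with ``fit(ds)`` and
    ``scores(ds) -> array`` (higher = more class-1-like). Folds are a
    random label-stratified partition; every spectrum is tested exactly
    once.
    """
    if k > ds.n_spectra:
        raise InvalidConfigError(f"k={k} folds exceed {ds.n_spectra} spectra")
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(ds.intensities, ds.labels):
        model = model_factory()
        model.fit(ds.subset_rows(tr))
        aucs.append(roc_auc(model.scores(ds.subset_rows(te)), ds.labels[te]))
    return CVResult(np.array(aucs))


# ---------------------------------------------------------------------------
# permutation importance


@dataclass
class ImportanceScores:
    """Per-feature AUC drop under column shuffling."""

    scores: np.ndarray
    dispersions: np.ndarray
    n_permutations: int
    baseline_auc: float


def permutation_importance(
    score_fn,
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 30,
    seed: int = 0,
) -> ImportanceScores:
    """AUC(original) minus the mean AUC after shuffling each feature column.

    ``score_fn(features) -> scores`` evaluates the fitted model; each of
    the m columns is independently permuted ``n_perm`` times while the
    others stay untouched.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    base = roc_auc(np.asarray(score_fn(X), dtype=float).ravel(), y)
    m = X.shape[1]
    drops = np.zeros((m, n_perm))
    for j in range(m):
        for r in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j, r] = base - roc_auc(np.asarray(score_fn(Xp), dtype=float).ravel(), y)
    return ImportanceScores(
        scores=drops.mean(axis=1),
        dispersions=drops.std(axis=1, ddof=1) if n_perm > 1 else np.zeros(m),
        n_permutations=n_perm,
        baseline_auc=base,
    )


# ---------------------------------------------------------------------------
# estimator wrappers sharing the fit/scores protocol


class LRAClassifier:
    """Logistic regression on the global mean intensity."""

    def __init__(self, shrinkage: float = 1.0):
        self.shrinkage = shrinkage
        self.model: LogisticModel | None = None

    def fit(self, ds: SpectralDataset) -> "LRAClassifier":
        feats = global_mean_feature(ds.intensities)[:, None]
        self.model = fit_logistic(feats, ds.labels, self.shrinkage)
        return self

    def scores(self, ds: SpectralDataset) -> np.ndarray:
        return self.model.predict_proba(global_mean_feature(ds.intensities)[:, None])


class L2DClassifier:
    """tau-weighted nearest-mean rule with inner-CV tau selection."""

    def __init__(self, tau_grid: np.ndarray | None = None, inner_folds: int = 10, seed: int = 0):
        self.tau_grid = tau_grid
        self.inner_folds = inner_folds
        self.seed = seed
        self.model: L2DModel | None = None

    def fit(self, ds: SpectralDataset) -> "L2DClassifier":
        self.model = fit_l2d(ds, self.tau_grid, self.inner_folds, self.seed)
        return self

    def scores(self, ds: SpectralDataset) -> np.ndarray:
        return np.asarray(l2d_margin(ds.intensities, self.model), dtype=float)

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        return l2d_classify(ds.intensities, self.model)


class PoolingLogisticClassifier:
    """Logistic regression on average-pooled sub-domain means (LRP)."""

    def __init__(self, scheme: PoolingScheme, shrinkage: float = 1.0):
        self.scheme = scheme
        self.shrinkage = shrinkage
        self.model: LogisticModel | None = None

    def featurize(self, ds: SpectralDataset) -> np.ndarray:
        return average_pooling(ds.intensities, self.scheme, ds.wavenumbers)

    def fit(self, ds: SpectralDataset) -> "PoolingLogisticClassifier":
        self.model = fit_logistic(self.featurize(ds), ds.labels, self.shrinkage)
        return self

    def scores(self, ds: SpectralDataset) -> np.ndarray:
        return self.model.predict_proba(self.featurize(ds))

    def feature_scores(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(features)


class PCALogisticClassifier:
    """Logistic regression on the leading principal-component scores."""

    def __init__(self, m_policy: int | float | None = None, shrinkage: float = 1.0,
                 lambda_grid: np.ndarray | None = None):
        self.m_policy = m_policy
        self.shrinkage = shrinkage
        self.lambda_grid = lambda_grid
        self.pca: PCAModel | None = None
        self.model: LogisticModel | None = None

    def fit(self, ds: SpectralDataset) -> "PCALogisticClassifier":
        self.pca = fit_pca(ds, self.m_policy)
        z = project(ds, self.pca)
        self.model = fit_logistic(z, ds.labels, self.shrinkage)
        if self.lambda_grid is not None:
            # AUC is threshold-invariant, so every lambda ties; the
            # tie-break keeps the grid value closest to 0.5.
            probs = self.model.predict_proba(z)
            objective = np.array([roc_auc(probs, ds.labels)] * self.lambda_grid.size)
            self.model.threshold = _tie_break_toward_half(
                np.asarray(self.lambda_grid, dtype=float), objective
            )
        return self

    def scores(self, ds: SpectralDataset) -> np.ndarray:
        return self.model.predict_proba(project(ds, self.pca))

    def predict(self, ds: SpectralDataset) -> np.ndarray:
        return classify_threshold(self.scores(ds), self.model.threshold)
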