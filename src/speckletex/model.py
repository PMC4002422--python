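"""Class modeling and classification.

Each image class (e.g. control vs treated) is represented by a Gaussian
mixture fitted by EM; the component count is chosen by AIC over a candidate
list.  A new image is assigned to the class whose nearest mixture component is
closest in Mahalanobis distance; accuracy is assessed by leave-one-subset-out
cross-validation, where subsets are imaging sessions rather than single
images, so correlated acquisition conditions never straddle the train/test
split.

The mixture fitting itself stands on scikit-learn's EM implementation; AIC
bookkeeping, distances, classification and the CV loop are defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.mixture import GaussianMixture

from .types import ValidationError

__all__ = [
    "GaussianMixtureClass",
    "ClassificationResult",
    "CrossValidationReport",
    "fit_class_gmm",
    "mahalanobis",
    "cross_cluster_distance",
    "classify",
    "cross_validate",
    "pairwise_class_distances",
]

RIDGE_FRACTION = 1e-6  # covariance ridge: eps = RIDGE_FRACTION * trace / dim
EM_RESTARTS = 5


@dataclass
class GaussianMixtureClass:
    k: int
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, dim)
    covariances: np.ndarray  # (k, dim, dim), ridge-regularized, PD
    log_likelihood: float  # total ln L over the training rows
    aic: float
    n_parameters: int
    feature_names: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        expect = _n_params(self.k, self.means.shape[1])
        if self.n_parameters != expect:
            raise ValidationError("stored parameter count inconsistent with k and dim")

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class ClassificationResult:
    assigned_class: str
    distances: Dict[str, float]
    margin: float  # runner-up distance minus winning distance (0 if one class)


@dataclass
class CrossValidationReport:
    per_fold: Dict[str, Tuple[int, int]]  # subset id -> (n_correct, n_total)
    overall_accuracy: float
    confusion: pd.DataFrame  # true label x assigned label counts
    warnings: List[str] = field(default_factory=list)


def _n_params(k: int, dim: int) -> int:
    """Free parameters of a full-covariance mixture: means + covs + weights."""
    return k * (dim + dim * (dim + 1) // 2) + (k - 1)


def _ridge(X: np.ndarray) -> float:
    tr = float(X.var(axis=0, ddof=1).sum()) if X.shape[0] > 1 else float(np.var(X))
    dim = X.shape[1]
    return max(RIDGE_FRACTION * tr / max(dim, 1), 1e-12)


def fit_class_gmm(
    X: np.ndarray,
    k_candidates: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
    feature_names: Sequence[str] = (),
    penalty: str = "full",
) -> GaussianMixtureClass:
    """EM fit per candidate component count; keep the minimum-AIC model.

    ``penalty="full"`` counts every free mixture parameter in the AIC penalty;
    ``penalty="subpopulations"`` penalizes by the component count alone (a
    deliberately under-counting variant kept behind this switch).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError("X must be a nonempty 2D array")
    if penalty not in ("full", "subpopulations"):
        raise ValidationError(f"unknown penalty {penalty!r}")
    dim = X.shape[1]
    reg = _ridge(X)
    best: Optional[GaussianMixtureClass] = None
    last_err: Optional[Exception] = None
    for k in k_candidates:
        if k < 1 or k > X.shape[0]:
            continue
        if k == 1:
            # closed form: EM with one component is the sample mean/covariance
            mu = X.mean(axis=0, keepdims=True)
            C = np.cov(X.T, ddof=0) if X.shape[0] > 1 else np.zeros((dim, dim))
            C = np.atleast_2d(C) + reg * np.eye(dim)
            sign, logdet = np.linalg.slogdet(C)
            Xi = X - mu
            sol = np.linalg.solve(C, Xi.T)
            quad = float(np.einsum("ij,ji->", Xi, sol))
            logL = -0.5 * (X.shape[0] * (dim * np.log(2 * np.pi) + logdet) + quad)
            p = _n_params(1, dim)
            pen = p if penalty == "full" else 1
            cand = GaussianMixtureClass(
                k=1,
                weights=np.ones(1),
                means=mu,
                covariances=C[None],
                log_likelihood=logL,
                aic=2.0 * pen - 2.0 * logL,
                n_parameters=p,
                feature_names=tuple(feature_names),
            )
            if best is None or cand.aic < best.aic:
                best = cand
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type="full",
                    reg_covar=reg,
                    n_init=EM_RESTARTS,
                    random_state=seed,
                    max_iter=300,
                )
                gm.fit(X)
        except Exception as exc:  # EM failure for this k; try the next
            last_err = exc
            continue
        logL = float(gm.score(X)) * X.shape[0]
        p = _n_params(k, dim)
        pen = p if penalty == "full" else k
        aic = 2.0 * pen - 2.0 * logL
        cand = GaussianMixtureClass(
            k=k,
            weights=gm.weights_.copy(),
            means=gm.means_.copy(),
            covariances=gm.covariances_.copy(),
            log_likelihood=logL,
            aic=aic,
            n_parameters=p,
            feature_names=tuple(feature_names),
        )
        if best is None or cand.aic < best.aic:
            best = cand
    if best is None:
        raise ValidationError(f"EM failed for every candidate k: {last_err}")
    return best


def mahalanobis(x: np.ndarray, y: np.ndarray, S: np.ndarray) -> float:
    """sqrt((x - y)^T S^-1 (x - y)) via Cholesky; S must be positive definite."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    S = np.asarray(S, dtype=float)
    try:
        c, low = linalg.cho_factor(S, check_finite=False)
    except linalg.LinAlgError as exc:
        raise ValidationError(
            "covariance is singular; regularize upstream before computing distances"
        ) from exc
    d = x - y
    sol = linalg.cho_solve((c, low), d, check_finite=False)
    return float(np.sqrt(max(float(d @ sol), 0.0)))


def cross_cluster_distance(
    mean1: np.ndarray, cov1: np.ndarray, mean2: np.ndarray, cov2: np.ndarray
) -> float:
    """Symmetrized between-cluster distance: mean of the two one-sided
    Mahalanobis distances (under each cluster's own covariance)."""
    d1 = mahalanobis(mean1, mean2, cov1)
    d2 = mahalanobis(mean1, mean2, cov2)
    return 0.5 * (d1 + d2)


def _class_distance(x: np.ndarray, cls: GaussianMixtureClass) -> float:
    """Distance from a point to a class: min over its mixture components."""
    return min(
        mahalanobis(x, cls.means[j], cls.covariances[j]) for j in range(cls.k)
    )


def _class_distances_batch(X: np.ndarray, cls: GaussianMixtureClass) -> np.ndarray:
    """Min-over-components Mahalanobis distances for many points at once."""
    out = np.full(X.shape[0], np.inf)
    for j in range(cls.k):
        try:
            c, low = linalg.cho_factor(cls.covariances[j], check_finite=False)
        except linalg.LinAlgError as exc:
            raise ValidationError(
                "covariance is singular; regularize upstream before computing distances"
            ) from exc
        d = X - cls.means[j][None]
        sol = linalg.cho_solve((c, low), d.T, check_finite=False)
        q = np.einsum("ij,ji->i", d, sol)
        out = np.minimum(out, np.sqrt(np.maximum(q, 0.0)))
    return out


def classify(x: np.ndarray, classes: Dict[str, GaussianMixtureClass]) -> ClassificationResult:
    if not classes:
        raise ValidationError("classes map is empty")
    dists = {label: _class_distance(np.asarray(x, float), cls) for label, cls in classes.items()}
    ordered = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))  # lexicographic tie-break
    assigned, dmin = ordered[0]
    margin = (ordered[1][1] - dmin) if len(ordered) > 1 else 0.0
    return ClassificationResult(assigned_class=assigned, distances=dists, margin=margin)


def cross_validate(
    M: pd.DataFrame,
    feature_names: Sequence[str],
    k_candidates: Sequence[int] = (1, 2, 3, 4),
    seed: int = 0,
    standardize: bool = True,
) -> CrossValidationReport:
    """Leave-one-subset-out CV over the ``subset_id`` column of a feature frame.

    Each fold fits one mixture per class on all remaining subsets and
    classifies the held-out subset's rows.  Features are optionally
    standardized using training-fold statistics only.
    """
    for col in ("label", "subset_id"):
        if col not in M.columns:
            raise ValidationError(f"feature frame lacks required column {col!r}")
    subsets = sorted(M["subset_id"].unique())
    if len(subsets) < 2:
        raise ValidationError("need >= 2 subsets for leave-one-subset-out CV")
    labels = sorted(M["label"].unique())
    feature_names = list(feature_names)
    per_fold: Dict[str, Tuple[int, int]] = {}
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    warns: List[str] = []
    for held in subsets:
        train = M[M["subset_id"] != held]
        test = M[M["subset_id"] == held]
        if set(train["label"].unique()) != set(labels):
            warns.append(f"fold {held!r} skipped: training set lacks a class")
            continue
        Xtr_all = train[feature_names].to_numpy(float)
        if standardize:
            mu = Xtr_all.mean(axis=0)
            sd = Xtr_all.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu, sd = 0.0, 1.0
        classes = {}
        for lab in labels:
            Xtr = (train.loc[train["label"] == lab, feature_names].to_numpy(float) - mu) / sd
            classes[lab] = fit_class_gmm(
                Xtr, k_candidates, seed=seed, feature_names=feature_names
            )
        Xte = (test[feature_names].to_numpy(float) - mu) / sd
        dmat = np.column_stack([_class_distances_batch(Xte, classes[lab]) for lab in labels])
        assigned = [labels[i] for i in dmat.argmin(axis=1)]  # labels sorted => lexicographic ties
        n_correct = 0
        for true_lab, got in zip(test["label"], assigned):
            conf.loc[true_lab, got] += 1
            n_correct += int(got == true_lab)
        per_fold[held] = (n_correct, len(test))
    if not per_fold:
        raise ValidationError("every CV fold was degenerate")
    total_c = sum(c for c, _ in per_fold.values())
    total_n = sum(n for _, n in per_fold.values())
    return CrossValidationReport(
        per_fold=per_fold,
        overall_accuracy=total_c / total_n,
        confusion=conf,
        warnings=warns,
    )


def pairwise_class_distances(
    X: np.ndarray,
    labels: Sequence[str],
    ridge_fraction: float = 1e-3,
    metric: str = "per_class",
) -> np.ndarray:
    """Pairwise distance matrix for embedding: within-class pairs use a class
    covariance metric; cross-class pairs use the symmetrized two-sided
    Mahalanobis distance.

    ``metric="per_class"`` whitens each class by its own sample covariance —
    faithful to the classifier's geometry but ill-conditioned when class
    sizes are small relative to the feature count.  ``metric="pooled"`` uses
    the pooled within-class scatter for every class, which keeps the
    embedding geometry stable at small n (all classes then share one metric,
    and the symmetrized cross-class distance reduces to plain Mahalanobis).
    A heavier ridge than the classifier's is used in both modes.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, dim = X.shape
    if metric not in ("per_class", "pooled"):
        raise ValidationError(f"unknown metric {metric!r}")
    covs: Dict[str, np.ndarray] = {}
    uniq = np.unique(labels)
    if metric == "pooled":
        scatter = np.zeros((dim, dim))
        for lab in uniq:
            sub = X[labels == lab]
            if sub.shape[0] > 1:
                scatter += np.cov(sub.T) * (sub.shape[0] - 1)
        denom = max(n - len(uniq), 1)
        C = np.atleast_2d(scatter / denom)
        eps = max(ridge_fraction * float(np.trace(C)) / dim, 1e-10)
        C = C + eps * np.eye(dim)
        covs = {lab: C for lab in uniq}
    else:
        for lab in uniq:
            sub = X[labels == lab]
            C = np.cov(sub.T) if sub.shape[0] > 1 else np.eye(dim)
            C = np.atleast_2d(C)
            eps = max(ridge_fraction * float(np.trace(C)) / dim, 1e-10)
            covs[lab] = C + eps * np.eye(dim)
    inv = {lab: np.linalg.inv(C) for lab, C in covs.items()}

    def _d(i: int, j: int) -> float:
        d = X[i] - X[j]
        li, lj = labels[i], labels[j]
        if li == lj:
            return float(np.sqrt(max(d @ inv[li] @ d, 0.0)))
        d1 = np.sqrt(max(d @ inv[li] @ d, 0.0))
        d2 = np.sqrt(max(d @ inv[lj] @ d, 0.0))
        return float(0.5 * (d1 + d2))

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _d(i, j)
    return D
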