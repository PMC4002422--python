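"""Sequential forward feature search with a Bernoulli-error BIC stopping rule.

Features are added greedily, each step keeping the feature that minimizes the
leave-one-subset-out classification error on the training data.  After each
addition the feature-set size k is scored by the Bayesian Information
Criterion for a Bernoulli error model:

    BIC(k) = -2 * [ m ln p + (n - m) ln (1 - p) ] + k ln n

with n validation decisions, m errors, p = m/n clamped away from {0, 1}
(where the log-likelihood would diverge).  The minimum-BIC prefix of the
greedy ranking is the selected set.  Run per outer fold, the per-fold sets
are combined by union — a deliberately inclusive rule for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import model
from .types import ValidationError

__all__ = [
    "FeatureSelectionResult",
    "bernoulli_bic",
    "sequential_forward_search",
    "union_over_folds",
    "select_features_nested",
]


@dataclass
class FeatureSelectionResult:
    ranked_features: List[str]  # greedy selection order
    error_curve: List[float]  # inner-CV error after each addition
    bic_curve: List[float]  # BIC(k) for k = 1..len(ranked)
    selected_set: List[str]  # minimum-BIC prefix
    per_fold_sets: Dict[str, List[str]] = field(default_factory=dict)
    union_set: List[str] = field(default_factory=list)


def bernoulli_bic(error_rate: float, k: int, n_val: int, n_mode: str = "samples") -> float:
    """BIC of a k-feature model under the Bernoulli error likelihood.

    ``n_mode="samples"`` (default) uses the number of validation decisions as
    BIC's n; ``n_mode="features"`` substitutes k itself — a literal variant
    kept behind this switch for comparison.
    """
    if n_val < 1:
        raise ValidationError("n_val must be >= 1")
    lo = 1.0 / (2.0 * n_val)
    p = min(max(error_rate, lo), 1.0 - lo)
    loglik = n_val * (p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
    n_pen = n_val if n_mode == "samples" else max(k, 2)
    return float(-2.0 * loglik + k * np.log(n_pen))


def _default_scorer(M: pd.DataFrame, feats: Sequence[str], seed: int) -> Tuple[float, int]:
    """Inner-CV classification error of a feature subset; returns (error, n)."""
    rep = model.cross_validate(M, feats, k_candidates=(1,), seed=seed)
    n = sum(nt for _, nt in rep.per_fold.values())
    return 1.0 - rep.overall_accuracy, n


def sequential_forward_search(
    M: pd.DataFrame,
    scorer: Optional[Callable[[pd.DataFrame, Sequence[str]], Tuple[float, int]]] = None,
    max_features: int = 15,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> FeatureSelectionResult:
    """Greedy forward search over the feature columns of ``M``.

    ``scorer(M, feats) -> (error_rate, n_decisions)`` defaults to
    leave-one-subset-out classification error with single-Gaussian class
    models.  Ties in the greedy step go to the lower registry index.
    """
    if feature_names is None:
        feature_names = [c for c in M.columns if c not in ("label", "subset_id", "timepoint")]
    feature_names = list(feature_names)
    if max_features > len(feature_names):
        max_features = len(feature_names)
    if scorer is None:
        scorer = lambda Mf, feats: _default_scorer(Mf, feats, seed)  # noqa: E731
    selected: List[str] = []
    remaining = list(feature_names)
    err_curve: List[float] = []
    bic_curve: List[float] = []
    n_val_seen = 0
    while remaining and len(selected) < max_features:
        best_feat, best_err, best_n = None, np.inf, 0
        for f in remaining:  # registry order => ties keep the lower index
            err, n = scorer(M, selected + [f])
            if err < best_err - 1e-12:
                best_feat, best_err, best_n = f, err, n
        if best_feat is None:
            break
        selected.append(best_feat)
        remaining.remove(best_feat)
        err_curve.append(best_err)
        n_val_seen = best_n
        bic_curve.append(bernoulli_bic(best_err, len(selected), best_n))
    if not selected:
        raise ValidationError("forward search selected no features (degenerate scorer)")
    k_opt = int(np.argmin(bic_curve)) + 1
    return FeatureSelectionResult(
        ranked_features=selected,
        error_curve=err_curve,
        bic_curve=bic_curve,
        selected_set=selected[:k_opt],
    )


def union_over_folds(per_fold_sets: Dict[str, List[str]]) -> List[str]:
    """Union of per-fold selections, ordered by earliest selection step then name."""
    if not per_fold_sets:
        raise ValidationError("need at least one fold")
    first_step: Dict[str, int] = {}
    for feats in per_fold_sets.values():
        for step, f in enumerate(feats):
            if f not in first_step or step < first_step[f]:
                first_step[f] = step
    return sorted(first_step, key=lambda f: (first_step[f], f))


def select_features_nested(
    M: pd.DataFrame,
    max_features: int = 15,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> FeatureSelectionResult:
    """Nested selection over outer subsets.

    For each outer held-out subset, forward search runs on the remaining
    training subsets only (the held-out rows never influence the ranking);
    the per-fold selected sets are combined by union.
    """
    subsets = sorted(M["subset_id"].unique())
    if len(subsets) < 3:
        raise ValidationError("nested selection needs >= 3 subsets")
    per_fold: Dict[str, List[str]] = {}
    ranked_ref: Optional[FeatureSelectionResult] = None
    for held in subsets:
        train = M[M["subset_id"] != held]
        res = sequential_forward_search(
            train, max_features=max_features, seed=seed, feature_names=feature_names
        )
        per_fold[held] = res.selected_set
        if ranked_ref is None:
            ranked_ref = res
    assert ranked_ref is not None
    union = union_over_folds(per_fold)
    return FeatureSelectionResult(
        ranked_features=ranked_ref.ranked_features,
        error_curve=ranked_ref.error_curve,
        bic_curve=ranked_ref.bic_curve,
        selected_set=ranked_ref.selected_set,
        per_fold_sets=per_fold,
        union_set=union,
    )
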