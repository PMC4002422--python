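"""Gaussian-mixture class models, Mahalanobis distances and subset-wise
cross-validation."""

import numpy as np
import pandas as pd
import pytest

from speckletex.model import (
    classify,
    cross_cluster_distance,
    cross_validate,
    fit_class_gmm,
    mahalanobis,
    pairwise_class_distances,
)
from speckletex.types import ValidationError


def make_frame(X, labels, subsets):
    cols = [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = labels
    df["subset_id"] = subsets
    return df, cols


# ------------------------------------------------------------- mahalanobis


def test_mahalanobis_closed_forms():
    assert mahalanobis([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0
    assert mahalanobis([3.0, 4.0], [0.0, 0.0], np.eye(2)) == pytest.approx(5.0)
    assert mahalanobis([2.0, 0.0], [0.0, 0.0], np.diag([4.0, 1.0])) == pytest.approx(1.0)


def test_mahalanobis_matches_direct_quadratic_form_on_random_triples():
    rng = np.random.default_rng(0)
    for _ in range(200):
        dim = rng.integers(2, 6)
        A = rng.standard_normal((dim, dim))
        S = A @ A.T + 0.5 * np.eye(dim)
        x = rng.standard_normal(dim)
        y = rng.standard_normal(dim)
        direct = np.sqrt((x - y) @ np.linalg.inv(S) @ (x - y))
        assert mahalanobis(x, y, S) == pytest.approx(direct, rel=1e-10)


def test_mahalanobis_is_a_metric_for_fixed_covariance():
    rng = np.random.default_rng(1)
    A = rng.standard_normal((3, 3))
    S = A @ A.T + np.eye(3)
    for _ in range(100):
        x, y, z = rng.standard_normal((3, 3))
        dxy = mahalanobis(x, y, S)
        assert dxy == pytest.approx(mahalanobis(y, x, S), rel=1e-12)
        assert dxy <= mahalanobis(x, z, S) + mahalanobis(z, y, S) + 1e-12


def test_mahalanobis_rejects_singular_covariance():
    with pytest.raises(ValidationError, match="singular"):
        mahalanobis([1.0, 0.0], [0.0, 0.0], np.zeros((2, 2)))


def test_distances_are_affine_invariant():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 4))
    A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
    S = np.cov(X.T) + 0.1 * np.eye(4)
    x, y = X[0], X[1]
    d0 = mahalanobis(x, y, S)
    d1 = mahalanobis(A @ x, A @ y, A @ S @ A.T)
    assert d1 == pytest.approx(d0, rel=1e-8)


# ------------------------------------------------------------- eq-3 distance


def test_cross_cluster_distance_examples():
    assert cross_cluster_distance(np.zeros(2), np.eye(2), np.zeros(2), np.eye(2)) == 0.0
    S = np.diag([2.0, 3.0])
    d = cross_cluster_distance(np.zeros(2), S, np.array([1.0, 1.0]), S)
    assert d == pytest.approx(mahalanobis([0, 0], [1, 1], S))
    got = cross_cluster_distance(
        np.zeros(2), np.diag([4.0, 1.0]), np.array([2.0, 0.0]), np.eye(2)
    )
    assert got == pytest.approx(1.5)  # mean of 1 and 2


# ------------------------------------------------------------- mixture fitting


def test_aic_prefers_one_component_for_a_single_gaussian():
    # AIC is mildly liberal, so allow occasional overfits at small trial count;
    # the tighter large-trial bound lives in the acceptance suite
    hits = 0
    for s in range(20):
        X = np.random.default_rng(s).standard_normal((500, 2))
        hits += fit_class_gmm(X, (1, 2, 3, 4), seed=s).k == 1
    assert hits >= 15


def test_aic_recovers_two_well_separated_components():
    hits = 0
    for s in range(20):
        rng = np.random.default_rng(1000 + s)
        X = np.vstack([rng.standard_normal((250, 2)), rng.standard_normal((250, 2)) + 10])
        hits += fit_class_gmm(X, (1, 2, 3, 4), seed=s).k == 2
    assert hits >= 15


def test_duplicate_points_yield_ridge_covariance():
    X = np.tile([2.0, -1.0], (20, 1))
    m = fit_class_gmm(X, (1,), seed=0)
    assert np.allclose(m.means[0], [2.0, -1.0])
    assert np.allclose(m.covariances[0], m.covariances[0][0, 0] * np.eye(2))
    assert m.covariances[0][0, 0] > 0


def test_aic_penalty_is_monotone_in_parameter_count():
    # equal log-likelihood => the larger parameter count never wins
    X = np.random.default_rng(3).standard_normal((100, 2))
    m1 = fit_class_gmm(X, (1,), seed=0)
    p2 = m1.n_parameters + 6  # one more component's worth
    aic2_same_logL = 2 * p2 - 2 * m1.log_likelihood
    assert m1.aic < aic2_same_logL


def test_k1_closed_form_matches_em():
    X = np.random.default_rng(4).standard_normal((200, 3)) * [1.0, 2.0, 0.5]
    fast = fit_class_gmm(X, (1,), seed=0)
    assert np.allclose(fast.means[0], X.mean(axis=0), atol=1e-9)
    assert fast.log_likelihood == pytest.approx(
        -0.5 * (200 * (3 * np.log(2 * np.pi) + np.linalg.slogdet(fast.covariances[0])[1])
                + sum((x - fast.means[0]) @ np.linalg.inv(fast.covariances[0]) @ (x - fast.means[0]) for x in X)),
        rel=1e-8,
    )


# ------------------------------------------------------------- classification


def test_point_at_a_component_mean_is_assigned_there():
    rng = np.random.default_rng(5)
    A = fit_class_gmm(rng.standard_normal((50, 2)), (1,), seed=0)
    B = fit_class_gmm(rng.standard_normal((50, 2)) + 100, (1,), seed=0)
    res = classify(A.means[0], {"a": A, "b": B})
    assert res.assigned_class == "a"
    assert res.distances["a"] == pytest.approx(0.0, abs=1e-9)
    assert res.margin > 0


def test_well_separated_draws_classify_to_their_generator():
    rng = np.random.default_rng(6)
    A = fit_class_gmm(rng.standard_normal((200, 2)), (1,), seed=0)
    B = fit_class_gmm(rng.standard_normal((200, 2)) + 5, (1,), seed=0)
    test_pts = np.vstack([rng.standard_normal((100, 2)), rng.standard_normal((100, 2)) + 5])
    truth = ["a"] * 100 + ["b"] * 100
    got = [classify(x, {"a": A, "b": B}).assigned_class for x in test_pts]
    acc = np.mean([g == t for g, t in zip(got, truth)])
    assert acc >= 0.99


def test_equidistant_point_breaks_ties_lexicographically():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((50, 2))
    A = fit_class_gmm(X - [3, 0], (1,), seed=0)
    B = fit_class_gmm(X + [3, 0], (1,), seed=0)
    # force exact symmetry
    B.means[0] = -A.means[0]
    B.covariances[0] = A.covariances[0].copy()
    res = classify(np.zeros(2), {"b": B, "a": A})
    assert res.assigned_class == "a"
    with pytest.raises(ValidationError):
        classify(np.zeros(2), {})


# ------------------------------------------------------------- cross-validation


def test_separable_classes_cross_validate_perfectly():
    rng = np.random.default_rng(8)
    n = 60
    X = np.vstack([rng.standard_normal((n, 3)), rng.standard_normal((n, 3)) + 20])
    labels = ["a"] * n + ["b"] * n
    subsets = [f"s{i % 6}" for i in range(n)] * 2
    df, cols = make_frame(X, labels, subsets)
    rep = cross_validate(df, cols, k_candidates=(1,), seed=0)
    assert rep.overall_accuracy == 1.0
    assert sum(n for _, n in rep.per_fold.values()) == 2 * n


def test_identical_distributions_cross_validate_at_chance():
    rng = np.random.default_rng(9)
    n = 100
    X = rng.standard_normal((2 * n, 3))
    labels = ["a"] * n + ["b"] * n
    subsets = [f"s{i % 4}" for i in range(n)] * 2
    df, cols = make_frame(X, labels, subsets)
    rep = cross_validate(df, cols, k_candidates=(1,), seed=0)
    assert abs(rep.overall_accuracy - 0.5) < 0.1


def test_label_shuffled_data_stays_within_binomial_chance_bounds():
    rng = np.random.default_rng(10)
    n = 100
    X = np.vstack([rng.standard_normal((n, 3)), rng.standard_normal((n, 3)) + 4])
    labels = np.array(["a"] * n + ["b"] * n)
    rng.shuffle(labels)
    subsets = [f"s{i % 4}" for i in range(2 * n)]
    df, cols = make_frame(X, labels, subsets)
    rep = cross_validate(df, cols, k_candidates=(1,), seed=0)
    # binomial 99% bounds around 0.5 at n=200
    half = 2.576 * np.sqrt(0.25 / (2 * n))
    assert 0.5 - half - 0.02 <= rep.overall_accuracy <= 0.5 + half + 0.02


def test_fold_missing_a_class_is_skipped_with_warning():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((30, 2))
    labels = ["a"] * 10 + ["b"] * 20
    subsets = ["s0"] * 10 + ["s1"] * 10 + ["s2"] * 10  # s1+s2 hold all of b
    df, cols = make_frame(X, labels, subsets)
    rep = cross_validate(df, cols, k_candidates=(1,), seed=0)
    assert any("lacks a class" in w for w in rep.warnings)
    assert "s0" not in rep.per_fold  # training for s0 would lack class a


def test_cross_validate_requires_multiple_subsets():
    df, cols = make_frame(np.zeros((4, 2)), ["a", "a", "b", "b"], ["s0"] * 4)
    with pytest.raises(ValidationError):
        cross_validate(df, cols)


# ------------------------------------------------------------- embedding metric


def test_pooled_metric_reduces_to_shared_mahalanobis():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((20, 3))
    labels = ["a"] * 10 + ["b"] * 10
    D = pairwise_class_distances(X, labels, metric="pooled")
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
    # symmetrized cross-class distance equals within-metric distance
    # (one shared covariance): check a cross pair against manual computation
    scatter = sum(
        np.cov(X[np.array(labels) == lab].T) * 9 for lab in ("a", "b")
    ) / 18
    eps = 1e-3 * np.trace(scatter) / 3
    S = scatter + eps * np.eye(3)
    manual = mahalanobis(X[0], X[15], S)
    assert D[0, 15] == pytest.approx(manual, rel=1e-8)
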