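"""PCA embedding, best-fit plane and Fisher-discriminant plane."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from fibropanel import (
    best_fit_plane,
    classification_accuracy,
    fisher_direction,
    fisher_plane,
    pca_svd,
)


class TestPcaSvd:
    def test_rank_one_data_puts_all_variance_on_pc1(self):
        t = np.linspace(-1, 1, 40)
        X = np.outer(t, np.array([1.0, -2.0, 0.5, 3.0, 1.0]))
        emb = pca_svd(X, n_components=1)
        assert emb.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_column_pair_matches_closed_form(self):
        # cov of (x, x) has eigenvalues (2*var, 0); loadings equal magnitude
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        X = np.column_stack([x, x])
        emb = pca_svd(X, n_components=1)
        assert emb.eigenvalues[0] == pytest.approx(2 * x.var(ddof=1), rel=1e-10)
        assert emb.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        assert abs(emb.components[0, 0]) == pytest.approx(abs(emb.components[0, 1]))
        assert abs(emb.components[0, 0]) == pytest.approx(1 / np.sqrt(2), rel=1e-10)

    def test_rotation_invariance_of_eigenvalues(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 6)) @ np.diag([3, 2, 1.5, 1, 0.5, 0.2])
        Q = ortho_group.rvs(6, random_state=11)
        e1 = pca_svd(X, n_components=3).eigenvalues
        e2 = pca_svd(X @ Q, n_components=3).eigenvalues
        np.testing.assert_allclose(e1, e2, atol=1e-8)

    def test_axes_orthonormal_eigenvalues_sorted_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 8))
        emb = pca_svd(X, n_components=3)
        np.testing.assert_allclose(emb.components @ emb.components.T, np.eye(3),
                                   atol=1e-8)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-10)
        assert np.all(emb.eigenvalues >= -1e-10)
        total = emb.eigenvalues / emb.eigenvalues.sum()
        assert total.sum() == pytest.approx(1.0, abs=1e-8)

    def test_scores_covariance_is_diagonal_with_eigenvalues(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((80, 5)) * np.array([4, 2, 1, 0.5, 0.25])
        emb = pca_svd(X, n_components=3)
        cov = np.cov(emb.scores, rowvar=False)
        np.testing.assert_allclose(cov, np.diag(emb.eigenvalues[:3]), atol=1e-8)

    def test_missing_entries_rejected(self):
        X = np.ones((10, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            pca_svd(X)

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="rank"):
            pca_svd(X, n_components=3)


class TestBestFitPlane:
    def test_points_on_z_equals_zero(self):
        rng = np.random.default_rng(1)
        P = np.column_stack([rng.standard_normal(30), rng.standard_normal(30),
                             np.zeros(30)])
        fit = best_fit_plane(P)
        assert abs(fit.normal[2]) == pytest.approx(1.0, abs=1e-12)

    def test_centroid_always_on_plane(self):
        rng = np.random.default_rng(2)
        P = rng.standard_normal((25, 3))
        fit = best_fit_plane(P)
        assert (P.mean(axis=0) - fit.point) @ fit.normal == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_plane_within_five_degrees(self):
        rng = np.random.default_rng(3)
        normal = np.array([1.0, 2.0, 2.0]) / 3.0
        basis = np.linalg.svd(normal[None, :])[2][1:]  # span orthogonal to normal
        coords = rng.standard_normal((30, 2)) * [5.0, 3.0]
        P = coords @ basis + 0.2 * rng.standard_normal((30, 1)) * normal
        fit = best_fit_plane(P)
        angle = np.degrees(np.arccos(abs(fit.normal @ normal)))
        assert angle < 5.0

    def test_collinear_points_flagged_degenerate(self):
        P = np.outer(np.arange(5.0), [1.0, 1.0, 1.0])
        assert best_fit_plane(P).degenerate


def fisher_criterion_grid_search(X, labels, n_angles=10_000):
    """Oracle: maximize between/within variance ratio over 2-D directions."""
    lab = np.asarray(labels)
    classes = sorted(pd.unique(lab).tolist())
    X1, X2 = X[lab == classes[0]], X[lab == classes[1]]
    best, best_j = None, -np.inf
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(theta), np.sin(theta)])
        s1, s2 = X1 @ w, X2 @ w
        within = ((s1 - s1.mean()) ** 2).sum() + ((s2 - s2.mean()) ** 2).sum()
        j = (s1.mean() - s2.mean()) ** 2 / within
        if j > best_j:
            best_j, best = j, w
    if (X2.mean(axis=0) - X1.mean(axis=0)) @ best < 0:
        best = -best
    return best


class TestFisherDirection:
    def test_isotropic_classes_give_mean_difference_direction(self):
        rng = np.random.default_rng(21)
        X1 = rng.standard_normal((300, 2))
        X2 = rng.standard_normal((300, 2)) + [3.0, 1.0]
        # force S_w exactly proportional to I by whitening each class
        for X in (X1, X2):
            Xc = X - X.mean(axis=0)
            L = np.linalg.cholesky(np.cov(Xc, rowvar=False))
            X[:] = X.mean(axis=0) + Xc @ np.linalg.inv(L).T
        X = np.vstack([X1, X2])
        lab = np.r_[np.zeros(300), np.ones(300)]
        w = fisher_direction(X, lab, ridge=0.0)
        diff = X2.mean(axis=0) - X1.mean(axis=0)
        np.testing.assert_allclose(w, diff / np.linalg.norm(diff), atol=1e-10)

    def test_matches_grid_search_oracle_on_anisotropic_toy(self):
        rng = np.random.default_rng(33)
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        L = np.linalg.cholesky(cov)
        X1 = rng.standard_normal((60, 2)) @ L.T
        X2 = rng.standard_normal((60, 2)) @ L.T + [2.0, -1.0]
        X = np.vstack([X1, X2])
        lab = np.r_[np.zeros(60), np.ones(60)]
        w = fisher_direction(X, lab, ridge=0.0)
        w_oracle = fisher_criterion_grid_search(X, lab)
        angle = np.degrees(np.arccos(np.clip(abs(w @ w_oracle), 0, 1)))
        assert angle < 0.1

    def test_affine_equivariance_of_discriminant_scores(self):
        rng = np.random.default_rng(44)
        X = rng.standard_normal((80, 3))
        lab = np.r_[np.zeros(40), np.ones(40)]
        X[lab == 1] += [1.0, -0.5, 2.0]
        w = fisher_direction(X, lab, ridge=0.0)
        c = 3.7  # scale one coordinate; mapped-back direction rescales it
        S = np.diag([1.0, c, 1.0])
        w_scaled = fisher_direction(X @ S, lab, ridge=0.0)
        w_back = S @ w_scaled
        w_back /= np.linalg.norm(w_back)
        scores_a = X @ w
        scores_b = X @ w_back
        np.testing.assert_allclose(scores_a, scores_b, atol=1e-8)

    def test_singular_scatter_without_ridge_raises(self):
        X = np.zeros((8, 5))
        X[:, 0] = np.r_[np.zeros(4), np.ones(4)]  # no within-class variance
        lab = np.r_[np.zeros(4), np.ones(4)]
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fisher_direction(X, lab, ridge=0.0)
        w = fisher_direction(X, lab, ridge=1e-3)  # regularized solve succeeds
        assert np.linalg.norm(w) == pytest.approx(1.0)

    def test_one_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError, match="2 classes"):
            fisher_direction(X, np.zeros(10))


class TestFisherPlane:
    def _blobs(self, seed=0, delta=6.0, n=30, p=8):
        rng = np.random.default_rng(seed)
        pre = rng.standard_normal((n, p))
        u = np.zeros(p)
        u[0] = 1.0
        post = rng.standard_normal((n, p)) + delta * u
        healthy = rng.standard_normal(p) * 0.1 + np.full(p, -4.0)
        return pre, post, healthy

    def test_separable_shift_gives_accuracy_one_and_axis_order(self):
        pre, post, healthy = self._blobs(delta=8.0)
        res = fisher_plane(pre, post, healthy)
        assert res.accuracy == 1.0
        assert res.center_post[0] > res.center_pre[0]  # post projects higher on u

    def test_axes_unit_length_and_orthogonal(self):
        pre, post, healthy = self._blobs(seed=5, delta=2.0)
        res = fisher_plane(pre, post, healthy)
        assert np.linalg.norm(res.u) == pytest.approx(1.0, abs=1e-8)
        assert np.linalg.norm(res.v) == pytest.approx(1.0, abs=1e-8)
        assert res.u @ res.v == pytest.approx(0.0, abs=1e-8)

    def test_projected_centers_are_direct_dot_products(self):
        pre, post, healthy = self._blobs(seed=8, delta=3.0)
        res = fisher_plane(pre, post, healthy)
        basis = np.stack([res.u, res.v])
        np.testing.assert_allclose(res.center_pre, basis @ pre.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(res.center_post, basis @ post.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(res.center_healthy, basis @ healthy, atol=1e-10)

    def test_identical_pre_post_accuracy_near_half_under_permutation(self):
        # permutation null: relabeling one cloud cannot beat chance; n >> p
        # keeps the resubstitution optimism term (~p/n) inside the tolerance
        rng = np.random.default_rng(13)
        X = rng.standard_normal((400, 4))
        healthy = np.full(4, -3.0)
        accs = []
        for rep in range(200):
            perm = rng.permutation(400)
            res = fisher_plane(X[perm[:200]], X[perm[200:]], healthy)
            accs.append(res.accuracy)
        assert np.mean(accs) <= 0.55

    def test_degenerate_vertical_axis_raises(self):
        rng = np.random.default_rng(3)
        pre = rng.standard_normal((20, 4))
        post = pre + np.array([5.0, 0, 0, 0])
        # healthy center placed so healthy->pre is parallel to u
        res0 = fisher_plane(pre, post, pre.mean(axis=0) - np.array([1.0, 0, 0, 0]) * 40)
        healthy = pre.mean(axis=0) - res0.u * 10.0
        with pytest.raises(ValueError, match="degenerate"):
            fisher_plane(pre, post, healthy)


class TestClassificationAccuracy:
    def test_perfect_separation(self):
        s = np.r_[np.zeros(5), np.ones(5) + 4]
        lab = np.r_[np.zeros(5), np.ones(5)]
        assert classification_accuracy(s, lab, threshold=2.0) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(10)
        s = rng.standard_normal(400)
        lab = rng.integers(0, 2, 400)
        acc = classification_accuracy(s, lab, threshold=np.median(s))
        assert abs(acc - 0.5) < 4 * 0.5 / np.sqrt(400)

    def test_six_point_hand_count(self):
        # scores 1,2,3,4,5,6; labels a,a,b,a,b,b; threshold 3.5
        # predictions: a,a,a,b,b,b -> correct at positions 1,2,5,6 -> 4/6
        s = np.arange(1.0, 7.0)
        lab = np.array(["a", "a", "b", "a", "b", "b"])
        assert classification_accuracy(s, lab, 3.5) == pytest.approx(4 / 6)

    def test_tie_at_threshold_goes_to_nearer_mean(self):
        s = np.array([0.0, 0.0, 2.0, 4.0])
        lab = np.array([0, 0, 1, 1])
        # threshold exactly on the two zero scores; class-0 mean (0) is nearer
        assert classification_accuracy(s, lab, 0.0) == 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            classification_accuracy(np.arange(4.0), np.zeros(4), 1.0)
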