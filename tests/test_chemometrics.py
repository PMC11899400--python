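"""Latent-variable models against independent oracles and their identities."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from harvestomics import chemometrics as cm
from harvestomics.errors import InvalidArgumentError


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


class TestPCA:
    def test_matches_covariance_eigendecomposition(self, rng):
        # oracle: eigendecomposition of the covariance matrix, up to sign
        for _ in range(5):
            X = rng.normal(size=(6, 4))
            res = cm.fit_pca(X, 3)
            Xc = X - X.mean(axis=0)
            evals, evecs = np.linalg.eigh(Xc.T @ Xc / 1.0)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            assert np.allclose(res.explained_variance, evals[:3] / evals.sum(), atol=1e-10)
            for a in range(3):
                dot = abs(res.loadings[:, a] @ evecs[:, a])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_single_variance_feature_explains_everything(self):
        X = np.zeros((5, 3))
        X[:, 1] = [1, 2, 3, 4, 5]
        res = cm.fit_pca(X, 1)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(5, 3))
        res = cm.fit_pca(X, 3)
        back = res.scores @ res.loadings.T + res.mean
        assert np.allclose(back, X, atol=1e-10)

    def test_scores_orthogonal_and_variance_monotone(self, rng):
        X = rng.normal(size=(8, 5))
        res = cm.fit_pca(X, 4)
        gram = res.scores.T @ res.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        assert (np.diff(res.explained_variance) <= 1e-12).all()

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            cm.fit_pca(rng.normal(size=(4, 3)), 4)


class TestPLSDA:
    def test_separable_two_groups_high_r2y(self, separable_data):
        X, labels = separable_data
        model = cm.fit_plsda(X, labels, 2)
        assert model.r2y >= 0.99

    def test_single_feature_equals_univariate_regression(self):
        # oracle: ordinary least squares of the indicator on the feature
        x = np.array([[0.5], [1.0], [2.0], [4.0], [4.5], [6.0]])
        labels = ["A", "A", "A", "B", "B", "B"]
        model = cm.fit_plsda(x, labels, 1)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        slope, intercept = np.polyfit(x.ravel(), y, 1)
        assert np.allclose(model.predict(x)[:, 1], slope * x.ravel() + intercept, atol=1e-8)

    def test_scores_mutually_orthogonal(self, separable_data):
        X, labels = separable_data
        model = cm.fit_plsda(X, labels, 3)
        gram = model.scores.T @ model.scores
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_matches_sklearn_pls2(self, rng):
        # independent oracle: sklearn NIPALS PLS regression on one-hot labels
        X = rng.normal(size=(10, 6))
        labels = ["A"] * 5 + ["B"] * 5
        model = cm.fit_plsda(X, labels, 2)
        y = np.array([0] * 5 + [1] * 5, dtype=float)
        sk = PLSRegression(n_components=2, scale=False).fit(X, y)
        assert np.allclose(model.predict(X)[:, 1], sk.predict(X).ravel(), atol=1e-8)

    def test_single_group_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            cm.fit_plsda(rng.normal(size=(4, 3)), ["A"] * 4, 1)


class TestOPLSDA:
    def test_zero_orthogonal_reduces_to_one_component_pls(self, rng):
        X = rng.normal(size=(10, 6))
        labels = ["A"] * 5 + ["B"] * 5
        opls = cm.fit_oplsda(X, labels, n_orthogonal=0)
        pls = cm.fit_plsda(X, labels, 1)
        assert np.allclose(opls.predict(X), pls.predict(X), atol=1e-8)

    @pytest.mark.parametrize("k", [1, 2])
    def test_equivalence_with_pls_of_matching_rank(self, rng, k):
        # single-response equivalence: OPLS 1+k == PLS with 1+k components
        X = rng.normal(size=(12, 8))
        X[:, 3] += np.linspace(-3, 3, 12)  # label-orthogonal structure
        labels = ["A", "B"] * 6
        opls = cm.fit_oplsda(X, labels, n_orthogonal=k)
        pls = cm.fit_plsda(X, labels, 1 + k)
        assert np.abs(opls.predict(X) - pls.predict(X)).max() < 1e-6

    def test_predictive_orthogonal_scores_uncorrelated(self, rng):
        X = rng.normal(size=(10, 5))
        labels = ["A"] * 5 + ["B"] * 5
        model = cm.fit_oplsda(X, labels, n_orthogonal=2)
        for a in range(model.n_orthogonal):
            assert model.scores[:, 0] @ model.ortho_scores[:, a] == pytest.approx(0.0, abs=1e-8)

    def test_three_groups_rejected(self, rng):
        with pytest.raises(InvalidArgumentError, match="pairwise"):
            cm.fit_oplsda(rng.normal(size=(6, 3)), ["A", "B", "C"] * 2)

    def test_auto_orthogonal_bounded(self, separable_data):
        X, labels = separable_data
        model = cm.fit_oplsda(X, labels, n_orthogonal="auto")
        assert 0 <= model.n_orthogonal <= 5
        assert model.q2 is not None


class TestVIP:
    def test_single_feature_forced_to_one(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = cm.fit_plsda(x, ["A", "A", "B", "B"], 1)
        assert model.vip[0] == pytest.approx(1.0)

    def test_sum_of_squares_equals_feature_count(self, separable_data):
        X, labels = separable_data
        for model in (cm.fit_plsda(X, labels, 2), cm.fit_oplsda(X, labels, 1)):
            assert (model.vip**2).sum() == pytest.approx(X.shape[1])

    def test_closed_form_three_features_one_component(self):
        # weights (2,1,0)/sqrt(5) -> VIP = sqrt(3) * |w| / ||w||
        model = cm.DAModelResult(
            method="oplsda", classes=["A", "B"],
            weights=np.array([[2.0], [1.0], [0.0]]) / np.sqrt(5),
            scores=np.array([[1.0], [-1.0]]),
            loadings=np.zeros((3, 1)), y_loadings=np.array([[1.0]]),
            x_mean=np.zeros(3), y_mean=np.zeros(1), r2x=0, r2y=1,
        )
        expected = np.sqrt(3) * np.array([2.0, 1.0, 0.0]) / np.sqrt(5)
        assert np.allclose(cm.compute_vip(model), expected, atol=1e-12)


class TestCrossValidation:
    def test_separable_data_high_q2(self, separable_data):
        X, labels = separable_data
        q2 = cm.cross_validate_q2(X, labels, {"method": "oplsda", "n_orthogonal": 0})
        assert q2 >= 0.95

    def test_null_data_mean_q2_nonpositive(self):
        # labels independent of data: held-out predictability ~ none
        rng = np.random.default_rng(99)
        q2s = []
        for _ in range(50):
            X = rng.normal(size=(12, 10))
            labels = ["A"] * 6 + ["B"] * 6
            q2s.append(cm.cross_validate_q2(
                X, labels, {"method": "oplsda", "n_orthogonal": 0},
                seed=int(rng.integers(2**31)),
            ))
        assert np.mean(q2s) <= 0.0

    def test_k_exceeding_samples_rejected(self, separable_data):
        X, labels = separable_data
        with pytest.raises(InvalidArgumentError):
            cm.cross_validate_q2(X, labels, {"method": "plsda", "n_components": 1}, k=13)

    def test_folds_stratified_and_seeded(self):
        labels = ["A"] * 6 + ["B"] * 6
        f1 = cm.stratified_folds(labels, 3, seed=4)
        f2 = cm.stratified_folds(labels, 3, seed=4)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        for fold in f1:
            arr = np.asarray(labels, dtype=object)[fold]
            assert (arr == "A").sum() == 2 and (arr == "B").sum() == 2


class TestPermutationTest:
    def test_minimum_p_is_one_over_nperm_plus_one(self, separable_data):
        X, labels = separable_data
        rec = cm.permutation_test(X, labels, {"method": "oplsda", "n_orthogonal": 0},
                                  n_perm=20, seed=0)
        assert rec.p_q2 >= 1 / 21
        assert rec.p_r2y >= 1 / 21

    def test_separable_data_significant(self, separable_data):
        X, labels = separable_data
        rec = cm.permutation_test(X, labels, {"method": "oplsda", "n_orthogonal": 0},
                                  n_perm=50, seed=1)
        assert rec.p_q2 <= 0.05

    def test_record_shapes_and_defaults(self, separable_data):
        X, labels = separable_data
        rec = cm.permutation_test(X, labels, {"method": "oplsda", "n_orthogonal": 0},
                                  n_perm=5, seed=3)
        assert rec.permuted_q2.shape == (5,)
        assert cm.DEFAULT_N_PERM == 200 and cm.DEFAULT_CV_FOLDS == 7
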