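import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from sklearn.mixture import GaussianMixture

from occfall import (ValidationError, train_autoencoder, train_gmm,
                     train_model, train_ocknn, train_ocsvm, train_ppnn)
from occfall.models import MODEL_KINDS, default_grid

METRIC_PARAMS = {"euclidean": {}, "minkowski": {"p": 3},
                 "chebychev": {}, "cosine": {}}


def _brute_kth_distance(train, query, metric, k):
    name = {"chebychev": "chebyshev"}.get(metric, metric)
    d = cdist(query, train, name, **METRIC_PARAMS[metric])
    return np.sort(d, axis=1)[:, k - 1]


class TestOCKNN:
    @pytest.mark.parametrize("k,query,expected", [
        (1, 5.0, 3.0),   # nearest of {0,1,2}
        (3, 5.0, 5.0),   # farthest of the three
        (1, 2.0, 0.0),   # query equals a training point
    ])
    def test_one_dimensional_examples(self, k, query, expected):
        model = train_ocknn(np.array([[0.0], [1.0], [2.0]]), "euclidean", k)
        assert model.score(np.array([[query]]))[0] == pytest.approx(expected)

    @pytest.mark.parametrize("metric", list(METRIC_PARAMS))
    def test_matches_brute_force(self, metric, rng):
        train = rng.normal(0, 1, (200, 10))
        query = rng.normal(0, 2, (50, 10))
        for k in (5, 10, 50):
            model = train_ocknn(train, metric, k)
            expected = _brute_kth_distance(train, query, metric, k)
            assert np.allclose(model.score(query), expected, atol=1e-10)

    def test_k_beyond_training_size_rejected(self, rng):
        with pytest.raises(ValueError):
            train_ocknn(rng.normal(size=(10, 3)), "euclidean", 11)


class TestGMM:
    def test_single_component_closed_form(self):
        model = train_gmm(np.array([[-1.0], [1.0]]), 1, seed=0)
        # biased MLE: mu=0, sigma^2=1 (+1e-6 variance floor)
        assert model.gm.means_.ravel()[0] == pytest.approx(0.0, abs=1e-9)
        assert model.gm.covariances_.ravel()[0] == pytest.approx(1.0, abs=1e-5)
        expected = 0.5 * np.log(2 * np.pi)   # -log N(0; 0, 1)
        assert model.score(np.array([[0.0]]))[0] == pytest.approx(
            expected, abs=1e-6)

    def test_translation_consistency(self, rng):
        x = rng.normal(0, 1, (80, 4))
        q = rng.normal(0, 1, (20, 4))
        shift = np.array([10.0, -3.0, 0.5, 100.0])
        s1 = train_gmm(x, 3, seed=2).score(q)
        s2 = train_gmm(x + shift, 3, seed=2).score(q + shift)
        assert np.allclose(s1, s2, atol=1e-6)

    def test_em_log_likelihood_monotone(self, rng):
        x = np.vstack([rng.normal(-2, 1, (60, 3)), rng.normal(2, 1, (60, 3))])
        gm = GaussianMixture(n_components=3, covariance_type="diag",
                             reg_covar=1e-6, tol=0, max_iter=1,
                             init_params="k-means++", random_state=0,
                             warm_start=True)
        bounds = []
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(25):
                gm.fit(x)
                bounds.append(gm.lower_bound_)
        assert np.all(np.diff(bounds) >= -1e-9)

    def test_bad_component_count_rejected(self, rng):
        with pytest.raises(ValueError):
            train_gmm(rng.normal(size=(10, 2)), 0)


class TestPPNN:
    def test_window_function_at_zero_distance(self):
        model = train_ppnn(np.zeros((1, 3)))
        assert model.likelihood(np.zeros((1, 3)))[0] == pytest.approx(
            np.exp(-1))

    def test_likelihood_monotone_in_distance(self):
        model = train_ppnn(np.zeros((1, 2)), bandwidth=1.0)
        distances = np.linspace(0, 5, 20)
        queries = np.column_stack([distances, np.zeros(20)])
        like = model.likelihood(queries)
        assert np.all(np.diff(like) < 0)

    def test_outlier_scores_above_training(self, rng):
        x = rng.normal(0, 1, (100, 5))
        model = train_ppnn(x)
        outlier = model.score(np.full((1, 5), 10.0))[0]
        assert outlier > model.score(x).max()

    def test_degenerate_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            train_ppnn(np.zeros((5, 2)))


class TestAutoencoder:
    def test_outlier_scores_above_training_quantile(self, rng):
        x = rng.normal(0, 1, (60, 7))
        model = train_autoencoder(x, 10, seed=1)
        train_scores = model.score(x)
        outlier = model.score(np.full((1, 7), 10.0))[0]
        assert outlier > np.quantile(train_scores, 0.95)

    def test_repeated_constant_input_reconstructs(self, rng):
        x = np.tile(rng.normal(0, 1, 5), (30, 1))
        model = train_autoencoder(x, 6, seed=0)
        assert model.score(x).mean() < 1e-3

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(0, 1, (40, 5))
        s1 = train_autoencoder(x, 6, seed=7).score(x)
        s2 = train_autoencoder(x, 6, seed=7).score(x)
        assert np.array_equal(s1, s2)


class TestOCSVM:
    def test_separable_outlier_scores_above_training(self, rng):
        # offset cloud: every kernel can separate it from an origin-side
        # outlier (linear/polynomial kernels carve halfspaces through the
        # origin, so a centered cloud would be degenerate for them)
        x = rng.normal(0, 1, (80, 4)) + 3.0
        for kernel in ("linear", "quadratic", "cubic", "medium gaussian"):
            model = train_ocsvm(x, kernel, seed=0)
            outlier = model.score(np.zeros((1, 4)))[0]
            assert outlier > model.score(x).max()

    def test_margin_support_vector_on_boundary(self, rng):
        x = rng.normal(0, 1, (100, 3))
        model = train_ocsvm(x, "medium gaussian", seed=0)
        svm = model.svm
        coef = np.abs(svm.dual_coef_).ravel()
        margin = coef < coef.max() - 1e-9
        assert margin.any()
        boundary_scores = model.score(x[svm.support_][margin])
        assert np.abs(boundary_scores).max() < 1e-2

    def test_rbf_scores_rotation_invariant(self, rng):
        x = rng.normal(0, 1, (60, 3))
        q = rng.normal(0, 2, (15, 3))
        rotation = Rotation.random(rng=rng).as_matrix()
        s1 = train_ocsvm(x, "medium gaussian").score(q)
        s2 = train_ocsvm(x @ rotation.T, "medium gaussian").score(
            q @ rotation.T)
        assert np.allclose(s1, s2, atol=1e-8)


class TestUnifiedContract:
    # enclosing hyperparameters per kind (linear/polynomial SVM kernels are
    # halfspace models and cannot enclose a centered cloud by construction)
    ENCLOSING = {"ocsvm": {"kernel": "medium gaussian"}}

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_outliers_score_higher_than_inliers(self, kind, rng):
        """Held-out inliers score below 3-sigma outliers for every kind."""
        train = rng.normal(0, 1, (80, 5))
        inliers = rng.normal(0, 1, (40, 5))
        outliers = rng.normal(0, 1, (40, 5)) + 3.0 * np.sqrt(5)
        params = self.ENCLOSING.get(kind, default_grid(kind)[0])
        model = train_model(kind, train, params, seed=0)
        assert model.score(inliers).mean() < model.score(outliers).mean()

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_empty_matrix_and_purity(self, kind, rng):
        train = rng.normal(0, 1, (30, 4))
        model = train_model(kind, train, default_grid(kind)[0], seed=0)
        assert model.score(np.empty((0, 4))).shape == (0,)
        q = rng.normal(0, 1, (10, 4))
        assert np.array_equal(model.score(q), model.score(q))

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_dimension_mismatch_rejected(self, kind, rng):
        model = train_model(kind, rng.normal(size=(30, 4)),
                            default_grid(kind)[0], seed=0)
        with pytest.raises(ValidationError):
            model.score(rng.normal(size=(3, 5)))
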