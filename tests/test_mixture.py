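import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from gbiq.mixture import (
    Assignment,
    FitError,
    GaussianMixtureBIC,
    GaussianMixtureEM,
    assign,
    designate_classes,
    fit_gmm,
    select_model_bic,
    suggest_k_kmeans,
)

from conftest import planted_mixture


class TestGaussianMixtureEM:
    def test_recovers_planted_two_component(self):
        X, labels, means = planted_mixture(2, 500, sep=10.0, seed=11)
        m = fit_gmm(X, k=2, seed=0)
        pred = m.predict(X)
        # align components to truth by nearest mean
        perm = [int(np.argmin(np.linalg.norm(means - mu, axis=1))) for mu in m.means_]
        agree = np.mean(np.array(perm)[pred] == labels)
        assert agree >= 0.99
        for j, mu in enumerate(m.means_):
            true_mu = means[perm[j]]
            n_j = max((np.array(perm)[pred] == perm[j]).sum(), 1)
            se = 3.0 / np.sqrt(n_j)  # sigma=1 per axis
            assert np.all(np.abs(mu - true_mu) < 3 * se + 0.2)

    def test_single_component_closed_form(self, rng):
        X = rng.normal(2.0, 1.5, (300, 2))
        m = fit_gmm(X, k=1, seed=0)
        np.testing.assert_allclose(m.means_[0], X.mean(axis=0), atol=1e-9)
        ml_cov = np.cov(X.T, bias=True)
        np.testing.assert_allclose(
            m.covariances_[0], ml_cov, atol=1e-4 * np.abs(ml_cov).max() + 1e-5
        )

    def test_deterministic_for_fixed_seed(self):
        X, _, _ = planted_mixture(3, 400, seed=5)
        a = fit_gmm(X, k=3, seed=42)
        b = fit_gmm(X, k=3, seed=42)
        assert a.loglik_ == b.loglik_
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_loglik_monotone_every_fit(self):
        for seed in range(5):
            X, _, _ = planted_mixture(3, 300, sep=3.0, seed=seed)
            m = fit_gmm(X, k=4, seed=seed)
            t = m.loglik_trace_
            assert np.all(np.diff(t) >= -1e-9 * np.abs(t[:-1]))

    def test_matches_sklearn_loglik(self):
        """Independent implementation cross-check at the optimum."""
        X, _, _ = planted_mixture(4, 800, seed=1001)
        mine = fit_gmm(X, k=4, family="full-varying", seed=0)
        ref = GaussianMixture(
            4, covariance_type="full", n_init=5, tol=1e-8,
            reg_covar=1e-6, random_state=0,
        ).fit(X)
        assert mine.loglik_ / len(X) == pytest.approx(ref.score(X), abs=1e-6)

    def test_degenerate_data_raises(self):
        X = np.ones((50, 2))
        with pytest.raises(FitError, match="degenerate"):
            fit_gmm(X, k=2, seed=0)

    def test_non_finite_rejected(self):
        X = np.ones((50, 2)) * np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_gmm(X, k=2, seed=0)

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError, match="n > k"):
            fit_gmm(np.eye(4), k=2, seed=0)

    @pytest.mark.parametrize(
        "family,extra",
        [
            ("spherical-equal", 1),
            ("spherical-varying", 3),
            ("diagonal-varying", 6),
            ("full-varying", 9),
        ],
    )
    def test_bic_free_parameter_count(self, family, extra):
        X, _, _ = planted_mixture(3, 400, seed=2)
        m = fit_gmm(X, k=3, family=family, seed=0)
        assert m.n_parameters_ == (3 - 1) + 3 * 2 + extra
        assert m.bic_ == pytest.approx(
            -2 * m.loglik_ + m.n_parameters_ * np.log(400)
        )


class TestModelSelection:
    def test_bic_selects_planted_k(self):
        X, _, _ = planted_mixture(4, 800, seed=7)
        m = select_model_bic(X, k_range=(1, 6), seed=0)
        assert m.k_ == 4

    def test_single_gaussian_gives_k1(self, rng):
        X = rng.normal(0, 1, (500, 2))
        m = select_model_bic(X, k_range=(1, 4), seed=0)
        assert m.k_ == 1

    def test_scan_report_covers_all_candidates(self):
        X, _, _ = planted_mixture(2, 300, seed=3)
        m = select_model_bic(X, k_range=(1, 3), seed=0)
        assert len(m.scan_) == 3 * 4
        assert m.bic_ == m.scan_["bic"].min()

    def test_three_channel_colony_analogue_recovers_k4(self, rng):
        # synthetic stand-in for a 144-grid, 3-channel quantification with
        # four populations: reporter(+) nuclei, reporter(-) nuclei, void,
        # and feeder/cytoplasm
        n_per = 36
        pops = [
            (160, 150, 140),  # nucleus, reporter(+)
            (160, 8, 120),    # nucleus, reporter(-)
            (6, 5, 6),        # void
            (70, 40, 45),     # feeder / cytoplasm
        ]
        X = np.vstack(
            [rng.normal(mu, (8, 8, 8), size=(n_per, 3)) for mu in pops]
        )
        m = select_model_bic(X, k_range=(1, 6), seed=0)
        assert m.k_ == 4

    def test_label_permutation_leaves_bic_invariant(self):
        X, _, _ = planted_mixture(3, 400, seed=9)
        m = fit_gmm(X, k=3, seed=1)
        perm = np.array([2, 0, 1])
        permuted = GaussianMixtureEM(n_components=3)
        permuted.weights_ = m.weights_[perm]
        permuted.means_ = m.means_[perm]
        permuted.covariances_ = m.covariances_[perm]
        permuted.n_features_in_ = 2
        ll = permuted.score_samples(X).sum()
        assert ll == pytest.approx(m.loglik_)


class TestAssign:
    def test_component_mean_gets_confident_label(self):
        X, _, _ = planted_mixture(3, 600, sep=12.0, seed=21)
        m = fit_gmm(X, k=3, seed=0)
        a = assign(m, m.means_)
        assert isinstance(a, Assignment)
        assert np.all(a.responsibilities.max(axis=1) > 0.99)
        assert np.array_equal(a.labels, np.arange(3))

    def test_responsibilities_sum_to_one(self, rng):
        X, _, _ = planted_mixture(2, 200, seed=4)
        m = fit_gmm(X, k=2, seed=0)
        a = assign(m, rng.normal(0, 5, (50, 2)))
        np.testing.assert_allclose(a.responsibilities.sum(axis=1), 1.0)

    def test_equidistant_point_ties_to_lower_index(self):
        m = GaussianMixtureEM(n_components=2)
        m.weights_ = np.array([0.5, 0.5])
        m.means_ = np.array([[-1.0, 0.0], [1.0, 0.0]])
        m.covariances_ = np.stack([np.eye(2), np.eye(2)])
        m.n_features_in_ = 2
        a = assign(m, np.array([[0.0, 0.0]]))
        np.testing.assert_allclose(a.responsibilities[0], [0.5, 0.5])
        assert a.labels[0] == 0

    def test_dimension_mismatch(self):
        X, _, _ = planted_mixture(2, 200, seed=4)
        m = fit_gmm(X, k=2, seed=0)
        with pytest.raises(ValueError, match="features"):
            m.predict(np.zeros((5, 3)))


class TestSuggestK:
    def test_three_planted_clusters(self):
        X, _, _ = planted_mixture(3, 600, sep=10.0, seed=5)
        assert suggest_k_kmeans(X, k_max=8, seed=0) == 3

    def test_uniform_blob_gives_one(self, rng):
        X = rng.uniform(0, 1, (500, 2))
        assert suggest_k_kmeans(X, k_max=8, seed=0) == 1

    def test_deterministic(self):
        X, _, _ = planted_mixture(4, 500, seed=6)
        assert suggest_k_kmeans(X, 8, seed=3) == suggest_k_kmeans(X, 8, seed=3)


class TestDesignation:
    def _fit_colony_like(self, rng):
        pops = {
            "pos": (160, 150, 140),
            "neg": (160, 8, 120),
            "void": (6, 5, 6),
            "feeder": (70, 40, 45),
        }
        X = np.vstack(
            [rng.normal(mu, 6, size=(40, 3)) for mu in pops.values()]
        )
        names = ["H33342_median", "EGFP_median", "antiOct4_median"]
        m = fit_gmm(X, k=4, seed=0)
        m.feature_names_ = names
        return m, X, list(pops)

    def test_four_population_semantics(self, rng):
        m, X, order = self._fit_colony_like(rng)
        a = assign(m, X)
        names = designate_classes(m, a, "H33342", "EGFP")
        assert sorted(names.values()) == sorted(
            ["reporter(+)", "reporter(-)", "void", "other"]
        )
        # the cluster holding the first 40 rows is the reporter(+) block
        by_block = [np.bincount(a.labels[i * 40:(i + 1) * 40]).argmax()
                    for i in range(4)]
        assert names[by_block[0]] == "reporter(+)"
        assert names[by_block[1]] == "reporter(-)"
        assert names[by_block[2]] == "void"
        assert names[by_block[3]] == "other"

    def test_k1_designated_by_profile(self, rng):
        X = rng.normal((100, 90, 80), 5, size=(100, 3))
        m = fit_gmm(X, k=1, seed=0)
        m.feature_names_ = ["H33342_median", "EGFP_median", "antiOct4_median"]
        names = designate_classes(m, assign(m, X), "H33342", "EGFP")
        assert names == {0: "reporter(+)"}

    def test_designation_never_alters_labels(self, rng):
        m, X, _ = self._fit_colony_like(rng)
        a = assign(m, X)
        before = a.labels.copy()
        designate_classes(m, a, "H33342", "EGFP")
        np.testing.assert_array_equal(a.labels, before)
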