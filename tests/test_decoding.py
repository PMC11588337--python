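import numpy as np
import pytest
from scipy import stats

from popazi import (
    AnalysisConfig,
    AzimuthGrid,
    ResponseDataset,
    chance_error_distribution,
    compare_to_chance,
    fit_bayes,
    fit_pca,
    knn_decode,
    loo_decode,
    performance_curve,
    predict_bayes,
    sidak,
    tune_bayes,
)
from popazi.data_model import ErrorDistribution
from popazi.decoding import _fit_bayes_arrays, _kernel_density

ANGLES = np.arange(-90, 91, 15, dtype=float)


class TestChanceModel:
    def test_matches_brute_force_enumeration(self, grid):
        chance = chance_error_distribution(grid)
        brute = sorted(
            abs(t - p) for t in grid.angles for p in grid.angles
        )
        assert chance.errors.size == 169
        assert sorted(chance.errors) == brute
        assert chance.p_error(0.0) == pytest.approx(13 / 169)
        assert chance.median == pytest.approx(np.median(brute))
        assert chance.mean == pytest.approx(sum(brute) / 169)

    def test_sign_convention_invariance(self):
        flipped = AzimuthGrid(contralateral_sign=-1)
        a = chance_error_distribution(AzimuthGrid())
        b = chance_error_distribution(flipped)
        assert sorted(a.errors) == sorted(b.errors)


class TestBayesDecoder:
    def test_balanced_priors(self, small_dataset):
        model = fit_bayes(small_dataset)
        np.testing.assert_allclose(model.priors, np.full(13, 1 / 13))
        assert model.priors.sum() == pytest.approx(1.0)

    def test_symmetric_conditionals_give_uniform_posterior(self):
        labels = np.repeat(ANGLES, 2)
        responses = np.tile([1.0, 2.0], 13)[:, None]  # identical per class
        ds = ResponseDataset(responses=responses, labels=labels)
        model = fit_bayes(ds)
        posterior, _ = predict_bayes(model, np.array([1.5]))
        np.testing.assert_allclose(posterior, np.full(13, 1 / 13), atol=1e-12)

    def test_disjoint_supports_give_confident_map(self):
        labels = np.repeat(ANGLES, 3)
        responses = (labels / 15.0 + 7.0)[:, None] * 10.0  # classes far apart
        rng = np.random.default_rng(0)
        responses = responses + rng.uniform(0, 0.1, size=responses.shape)
        ds = ResponseDataset(responses=responses, labels=labels)
        model = fit_bayes(ds)
        posterior, pred = predict_bayes(model, ds.responses[5])
        assert pred == labels[5]
        assert posterior.max() > 0.99

    def test_posterior_matches_hand_computed_kernel_sums(self):
        # 2 classes x 1 unit with a Gaussian kernel: the posterior must
        # equal a direct evaluation of prior x mean-of-kernels, normalized
        train_a = np.array([1.0, 2.0, 3.0])
        train_b = np.array([4.0, 5.0])
        labels = np.array([-90.0] * 3 + [90.0] * 2 + [-90.0, 90.0])
        values = np.concatenate([train_a, train_b, [1.5], [4.5]])
        ds = ResponseDataset(responses=values[:, None], labels=labels)
        # use only the first 5 trials for training
        model = _fit_bayes_arrays(
            values[:5, None], labels[:5], "gaussian", "silverman", ds.grid
        )
        x = 3.4
        posterior, _ = predict_bayes(model, np.array([x]))

        def dens(v, h):
            u = (x - v) / h
            return np.mean(np.exp(-0.5 * u**2) / np.sqrt(2 * np.pi)) / h

        score_a = (3 / 5) * dens(train_a, model.bandwidths[0, 0])
        score_b = (2 / 5) * dens(train_b, model.bandwidths[1, 0])
        expected = np.array([score_a, score_b]) / (score_a + score_b)
        np.testing.assert_allclose(posterior, expected, rtol=1e-10)

    def test_log_space_equals_direct_product(self):
        rng = np.random.default_rng(1)
        labels = np.repeat(ANGLES, 4)
        responses = rng.gamma(2.0, 1.0, size=(labels.size, 3))
        ds = ResponseDataset(responses=responses, labels=labels)
        model = fit_bayes(ds)
        x = ds.responses[10]
        posterior, _ = predict_bayes(model, x)
        direct = []
        for k, c in enumerate(model.classes):
            prod = model.priors[k]
            vk = model.class_values[k]
            for j in range(3):
                h = model.bandwidths[k, j]
                u = (x[j] - vk[:, j]) / h
                prod *= max(
                    float(np.mean(_kernel_density(u, "gaussian")) / h), 1e-300
                )
            direct.append(prod)
        direct = np.array(direct) / np.sum(direct)
        np.testing.assert_allclose(posterior, direct, rtol=1e-10)

    def test_posterior_normalized(self, small_dataset):
        model = fit_bayes(small_dataset)
        for t in range(0, small_dataset.n_trials, 7):
            posterior, _ = predict_bayes(model, small_dataset.responses[t])
            assert abs(posterior.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("kernel", ["uniform", "epanechnikov", "triangular"])
    def test_bounded_kernels_fall_back_to_floor(self, kernel, small_dataset):
        model = fit_bayes(small_dataset, kernel=kernel)
        posterior, pred = predict_bayes(
            model, np.full(small_dataset.n_units, 1e6)
        )
        # far outside every kernel's support: posterior defined, sums to 1
        assert abs(posterior.sum() - 1.0) < 1e-12
        assert pred in ANGLES

    def test_map_tie_break_prefers_center_then_contralateral(self):
        from popazi.decoding import _map_choice

        grid = AzimuthGrid()
        classes = np.array([-30.0, 30.0, 45.0])
        scores = np.array([0.0, 0.0, -1.0])
        assert _map_choice(classes, scores, grid) == 30.0  # contralateral wins
        grid_flip = AzimuthGrid(contralateral_sign=-1)
        assert _map_choice(classes, scores, grid_flip) == -30.0


class TestTuneBayes:
    def test_single_candidate_returned(self, separable_dataset):
        got = tune_bayes(
            separable_dataset, kernels=("gaussian",), bandwidths=[0.3], folds=3
        )
        assert got == ("gaussian", 0.3)

    def test_separable_data_reaches_zero_error_and_determinism(
        self, separable_dataset
    ):
        a = tune_bayes(separable_dataset, bandwidths=[0.1, 1.0], folds=3, seed=4)
        b = tune_bayes(separable_dataset, bandwidths=[0.1, 1.0], folds=3, seed=4)
        assert a == b
        kernel, bw = a
        res = loo_decode(
            separable_dataset,
            config=AnalysisConfig(kernel=kernel, bandwidth=bw),
        )
        assert np.all(res.errors.errors == 0)

    def test_bad_folds_rejected(self, separable_dataset):
        with pytest.raises(ValueError):
            tune_bayes(separable_dataset, folds=10)  # only 3 reps per class


class TestPca:
    def test_variance_fractions_sum_to_one(self, small_dataset):
        pca = fit_pca(small_dataset.responses)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_rank_one_data(self):
        u = np.outer(np.arange(1, 11, dtype=float), [1.0, 2.0, 3.0])
        pca = fit_pca(u)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_back_projection_recovers_centered_data(self, small_dataset):
        X = small_dataset.responses
        pca = fit_pca(X)
        scores = pca.transform(X)
        np.testing.assert_allclose(
            scores @ pca.loadings.T, X - pca.mean, atol=1e-9
        )

    def test_matches_sklearn(self, small_dataset):
        from sklearn.decomposition import PCA

        X = small_dataset.responses
        ours = fit_pca(X)
        ref = PCA(n_components=3, svd_solver="full").fit(X)
        for k in range(3):
            a, b = ours.loadings[:, k], ref.components_[k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((5, 3)))


class TestKnn:
    def test_exact_match_with_k1(self, separable_dataset):
        x = separable_dataset.responses[4]
        pred = knn_decode(
            separable_dataset.responses, separable_dataset.labels, x, k=1
        )
        assert pred == separable_dataset.labels[4]

    def test_k_equals_all_resolved_by_distance(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([-90.0, -90.0, 90.0, 90.0])
        pred = knn_decode(X, y, np.array([0.5]), k=4)
        assert pred == -90.0

    def test_bad_k(self):
        X, y = np.ones((3, 1)), np.array([0.0, 15.0, 30.0])
        with pytest.raises(ValueError):
            knn_decode(X, y, np.array([1.0]), k=0)
        with pytest.raises(ValueError):
            knn_decode(X, y, np.array([1.0]), k=4)


class TestComparisons:
    def test_sidak_closed_form(self):
        assert sidak(0.01, 5) == pytest.approx(1 - 0.99**5)
        assert sidak(0.0, 3) == 0.0

    def test_chance_sample_against_itself(self, grid):
        chance = chance_error_distribution(grid)
        cmp_ = compare_to_chance(
            ErrorDistribution(chance.errors.copy(), provenance="chance"), chance
        )
        assert cmp_.ks_statistic == 0.0
        assert cmp_.pvalue == pytest.approx(1.0)

    def test_perfect_decoder_beats_chance(self, grid):
        chance = chance_error_distribution(grid)
        cmp_ = compare_to_chance(np.zeros(169), chance)
        assert cmp_.pvalue < 1e-6
        assert cmp_.direction == "better"


class TestLooDecode:
    def test_separable_limit_all_errors_zero(self, separable_dataset):
        for classifier in ("bayes", "knn"):
            res = loo_decode(
                separable_dataset,
                classifier=classifier,
                config=AnalysisConfig(knn_k=2),
            )
            assert np.all(res.errors.errors == 0), classifier

    def test_selector_validation(self, small_dataset):
        with pytest.raises(ValueError, match="top_ranked:9"):
            loo_decode(small_dataset, selector="top_ranked:9")
        with pytest.raises(ValueError):
            loo_decode(small_dataset, selector="lasso:3")

    def test_fold_provenance_supports_leakage_audit(self, small_dataset):
        from popazi.decoding import _rank_training_fold
        from popazi import rank_units

        res = loo_decode(small_dataset, selector="top_ranked:2")
        classes = np.unique(small_dataset.labels)
        for record in res.folds[::7]:
            mask = np.ones(small_dataset.n_trials, dtype=bool)
            mask[record.test_index] = False
            p, s = _rank_training_fold(
                small_dataset.responses[mask],
                small_dataset.labels[mask],
                classes,
                10,
            )
            np.testing.assert_array_equal(
                rank_units(p, s).top(2), record.selected_units
            )


class TestPerformanceCurve:
    def test_single_size_no_correction(self, separable_dataset):
        curve = performance_curve(separable_dataset, "pca", [1])
        assert curve.sizes.tolist() == [1]
        assert curve.pvalues_adjusted[0] == pytest.approx(curve.pvalues[0])

    def test_rejects_bad_sizes(self, separable_dataset):
        with pytest.raises(ValueError):
            performance_curve(separable_dataset, "pca", [])
        with pytest.raises(ValueError):
            performance_curve(separable_dataset, "umap", [1])
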