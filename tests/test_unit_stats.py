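import numpy as np
import pytest
from scipy import stats

from popazi import (
    PopulationSpec,
    ResponseDataset,
    bf_azimuth_correlation,
    chi2_dependency,
    frequency_dependence,
    kruskal_wallis_tuning,
    neuronal_snr,
    rank_units,
    sample_dataset,
    spec_presets,
)
from popazi.unit_stats import _chi2_one_unit

ANGLES = np.arange(-90, 91, 15, dtype=float)


def dataset_from_unit(values_by_azimuth):
    """Single-unit dataset from a mapping azimuth -> list of responses."""
    labels, resp = [], []
    for theta, vals in values_by_azimuth.items():
        labels += [theta] * len(vals)
        resp += list(vals)
    return ResponseDataset(
        responses=np.array(resp, dtype=float)[:, None], labels=np.array(labels)
    )


class TestNeuronalSnr:
    def test_inverse_cv_arithmetic(self):
        data = {theta: [0.0, 0.0] for theta in ANGLES}
        data[30.0] = [2.0, 4.0]
        ds = dataset_from_unit(data)
        table = neuronal_snr(ds)
        assert table.best_azimuth[0] == 30.0
        assert table.snr[0] == pytest.approx(3.0 / np.sqrt(2.0))

    def test_zero_sd_flagged_infinite(self):
        data = {theta: [0.0, 0.0] for theta in ANGLES}
        data[0.0] = [4.0, 4.0, 4.0, 4.0]
        table = neuronal_snr(dataset_from_unit(data))
        assert table.infinite[0] and np.isinf(table.snr[0])
        assert table.defined.size == 0

    def test_all_zero_unit_undefined(self):
        data = {theta: [0.0, 0.0] for theta in ANGLES}
        table = neuronal_snr(dataset_from_unit(data))
        assert table.undefined[0]
        assert table.defined.size == 0

    def test_baseline_subtraction_can_undefine(self):
        data = {theta: [1.0, 1.0] for theta in ANGLES}
        ds = dataset_from_unit(data)
        baseline = np.full_like(ds.responses, 2.0)
        table = neuronal_snr(ds, baseline=baseline)
        assert table.undefined[0]

    def test_stimulus_exceeds_ongoing_for_tuned_population(self):
        # evoked responses (high, regular at the best azimuth) versus a
        # label-free ongoing block with burstier spontaneous activity:
        # the nS/N distribution must shift upward under stimulation
        spec = PopulationSpec(
            n_units=40, fraction_dependent=1.0, tuning_family="sigmoid",
            reps_per_azimuth=20, dispersion=3.0, p_fail=0.0, seed=5,
        )
        ds = sample_dataset(spec, seed=5)
        stim = neuronal_snr(ds)
        rng = np.random.default_rng(5)
        ongoing = ResponseDataset(
            responses=rng.gamma(0.8, 0.1, size=(40, ds.n_units)),
            labels=np.zeros(40),
        )
        ong = neuronal_snr(ongoing, condition="ongoing")
        ks = stats.ks_2samp(stim.defined, ong.defined)
        assert np.median(stim.defined) > np.median(ong.defined)
        assert ks.pvalue < 0.05


class TestKruskalWallis:
    def test_identical_groups_null(self):
        data = {theta: [1.0, 2.0, 3.0] for theta in ANGLES}
        res = kruskal_wallis_tuning(dataset_from_unit(data))
        assert res.statistics[0] == 0.0 and res.pvalues[0] == 1.0

    def test_separated_group_matches_rank_oracle(self):
        # one azimuth's responses strictly exceed all others': the ranks
        # are enumerable by hand, so H has a closed form
        data = {
            theta: list(np.linspace(0, 1, 14) + 1.37 * i)
            for i, theta in enumerate(ANGLES)
        }
        data[45.0] = list(np.linspace(100, 101, 14))  # no overlap with anything
        ds = dataset_from_unit(data)
        res = kruskal_wallis_tuning(ds)
        # direct rank computation: all values distinct, no ties
        values = ds.responses[:, 0]
        ranks = stats.rankdata(values)
        n = values.size
        h_oracle = 0.0
        for theta in ANGLES:
            r = ranks[ds.labels == theta]
            h_oracle += len(r) * (r.mean() - (n + 1) / 2) ** 2
        h_oracle *= 12 / (n * (n + 1))
        assert res.statistics[0] == pytest.approx(h_oracle)
        assert res.pvalues[0] == pytest.approx(stats.chi2.sf(h_oracle, 12))
        assert res.pvalues[0] < 1e-6

    def test_matches_scipy_on_random_data(self, small_dataset):
        res = kruskal_wallis_tuning(small_dataset)
        groups = [
            small_dataset.responses[small_dataset.labels == c, 0]
            for c in small_dataset.classes
        ]
        h, p = stats.kruskal(*groups)
        assert res.statistics[0] == pytest.approx(h)
        assert res.pvalues[0] == pytest.approx(p)


class TestChi2Dependency:
    def test_constant_unit_flagged(self):
        data = {theta: [2.0, 2.0] for theta in ANGLES}
        res = chi2_dependency(dataset_from_unit(data))
        assert res.non_informative[0]
        assert res.pvalues[0] == 1.0 and res.statistics[0] == 0.0

    def test_single_azimuth_responder_detected(self):
        data = {theta: [0.0] * 14 for theta in ANGLES}
        data[30.0] = [5.0] * 14
        res = chi2_dependency(dataset_from_unit(data))
        assert res.pvalues[0] < 1e-6

    def test_matches_scipy_contingency(self):
        # the fast inner statistic must agree with the library route
        rng = np.random.default_rng(0)
        for _ in range(20):
            values = rng.gamma(1.0, 1.0, size=130)
            class_idx = np.repeat(np.arange(13), 10)
            p, s, dof, flag, _ = _chi2_one_unit(values, class_idx, 13, 10)
            assert not flag
            edges = np.linspace(values.min(), values.max(), 11)
            bins = np.clip(
                np.searchsorted(edges, values, side="right") - 1, 0, 9
            )
            table = np.zeros((10, 13))
            np.add.at(table, (bins, class_idx), 1.0)
            table = table[table.sum(axis=1) > 0]
            ref = stats.chi2_contingency(table, correction=False)
            assert s == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)
            assert dof == ref.dof

    def test_more_sensitive_than_kruskal_on_zero_inflated_data(self):
        # the response-distribution test should recover clearly more of the
        # planted dependent units than the median test when responses
        # frequently fail outright
        from popazi import dependent_units

        total_chi2 = total_kw = 0
        wins = 0
        for seed in range(50):
            spec = PopulationSpec(
                n_units=12,
                fraction_dependent=0.5,
                reps_per_azimuth=14,
                p_fail=0.55,
                dispersion=1.0,
                seed=seed,
            )
            ds = sample_dataset(spec, seed=seed)
            dep = dependent_units(spec)
            n_chi2 = int(np.sum(chi2_dependency(ds).pvalues[dep] < 0.05))
            n_kw = int(np.sum(kruskal_wallis_tuning(ds).pvalues[dep] < 0.05))
            total_chi2 += n_chi2
            total_kw += n_kw
            wins += n_chi2 >= n_kw
        assert total_chi2 > total_kw
        assert wins >= 35


class TestRanking:
    def test_orders_by_pvalue(self):
        r = rank_units(np.array([0.2, 0.001, 0.05]), np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(r.order, [1, 2, 0])

    def test_tie_broken_by_statistic(self):
        r = rank_units(np.array([0.5, 0.5]), np.array([5.0, 9.0]))
        np.testing.assert_array_equal(r.order, [1, 0])

    def test_final_tie_break_is_index_order(self):
        r = rank_units(np.ones(4), np.zeros(4))
        np.testing.assert_array_equal(r.order, [0, 1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rank_units(np.ones(3), np.ones(2))

    def test_top_requires_enough_units(self):
        r = rank_units(np.ones(3), np.zeros(3))
        with pytest.raises(ValueError):
            r.top(4)


class TestFrequencyDependence:
    def test_best_frequency_is_argmax(self):
        spec = spec_presets("tone-ephys", n_units=8, latent_corr=None)
        ds = sample_dataset(spec, seed=2)
        res = frequency_dependence(ds)
        means = np.stack([ds.responses_for(c).mean(axis=0) for c in ds.classes])
        np.testing.assert_array_equal(
            res.best_frequency, ds.classes[np.argmax(means, axis=0)]
        )

    def test_single_frequency_responder(self):
        freqs = 4.0 * 2.0 ** (np.arange(14) / 4.0)
        labels = np.repeat(freqs, 10)
        resp = np.zeros((labels.size, 1))
        resp[labels == freqs[5]] = 6.0
        ds = ResponseDataset(responses=resp, labels=labels, block="frequency")
        res = frequency_dependence(ds)
        assert res.pvalues[0] < 1e-6
        assert res.best_frequency[0] == pytest.approx(freqs[5])

    def test_azimuth_block_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            frequency_dependence(small_dataset)


class TestBfAzimuthCorrelation:
    def test_perfect_linear_pairs(self):
        bf = np.array([4.0, 8.0, 16.0, 32.0])
        lp = np.log10(bf) * 2.0 + 1.0
        assert bf_azimuth_correlation(bf, lp) == pytest.approx(1.0)

    def test_constant_best_frequency_undefined(self):
        assert np.isnan(
            bf_azimuth_correlation(np.array([8.0, 8.0, 8.0]), np.array([1.0, 2.0, 3.0]))
        )

    def test_matches_direct_formula(self):
        bf = np.array([4.0, 12.0, 7.0, 30.0, 22.0])
        lp = np.array([0.3, 2.0, 1.1, 0.8, 2.5])
        x = np.log10(bf)
        expected = np.cov(x, lp, ddof=1)[0, 1] / (x.std(ddof=1) * lp.std(ddof=1))
        assert bf_azimuth_correlation(bf, lp) == pytest.approx(expected)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bf_azimuth_correlation(np.array([4.0, 8.0]), np.array([1.0, 2.0]))
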