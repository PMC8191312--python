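"""MSM estimation and validation: counting, trimming, spectra, GMRQ,
residence probabilities, MCMC observables and block bootstrap."""

import math

import numpy as np
import pytest

from bridgemsm.msm import (
    block_bootstrap,
    count_transitions,
    estimate_markov_model,
    gmrq_cross_validate,
    gmrq_score,
    implied_timescales_scan,
    mcmc_mfpt,
    residence_probability_test,
    sample_observable_mcmc,
    trim_to_connected,
)
from bridgemsm.synthgen import sample_markov_chain, sample_markov_chains

from conftest import model_from_T, random_reversible_T


def three_block_T(coupling: float = 0.01) -> np.ndarray:
    """Six microstates in three metastable blocks along a linear topology."""
    W = np.array(
        [
            [10.0, 5.0, coupling, 0.0, 0.0, 0.0],
            [5.0, 10.0, coupling, coupling, 0.0, 0.0],
            [coupling, coupling, 10.0, 5.0, coupling, 0.0],
            [0.0, coupling, 5.0, 10.0, coupling, coupling],
            [0.0, 0.0, coupling, coupling, 10.0, 5.0],
            [0.0, 0.0, 0.0, coupling, 5.0, 10.0],
        ]
    )
    return W / W.sum(axis=1)[:, None]


class TestCounting:
    def test_hand_counted_lag1(self):
        cm = count_transitions([np.array([0, 0, 1, 1, 0])], lag=1)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [1, 1]])

    def test_hand_counted_lag2(self):
        cm = count_transitions([np.array([0, 0, 1, 1, 0])], lag=2)
        np.testing.assert_array_equal(cm.counts, [[0, 2], [1, 0]])

    def test_constant_trajectory(self):
        cm = count_transitions([np.zeros(50, dtype=int)], lag=1)
        assert cm.counts[0, 0] == 49

    def test_all_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than lag"):
            count_transitions([np.array([0, 1])], lag=5)


class TestTrim:
    def test_state_without_outgoing_counts_dropped(self):
        cm = count_transitions([np.array([0, 0, 1, 1, 0, 2])], lag=1)
        trimmed = trim_to_connected(cm)
        np.testing.assert_array_equal(trimmed.active_set, [0, 1])

    def test_fully_connected_unchanged(self):
        cm = count_transitions([np.array([0, 1, 2, 0, 1, 2, 0])], lag=1)
        trimmed = trim_to_connected(cm)
        np.testing.assert_array_equal(trimmed.active_set, [0, 1, 2])

    def test_larger_of_two_disjoint_blocks_retained(self):
        d = [np.array([0, 1, 2, 0, 1, 2, 0]), np.array([3, 4, 3, 4, 3])]
        trimmed = trim_to_connected(count_transitions(d, lag=1))
        np.testing.assert_array_equal(trimmed.active_set, [0, 1, 2])


class TestEstimation:
    def test_symmetric_counts_give_uniform_chain(self):
        from bridgemsm.msm import CountMatrix

        cm = CountMatrix(np.array([[1, 1], [1, 1]]), 1, np.arange(2), 2)
        model = estimate_markov_model(cm)
        np.testing.assert_allclose(model.T, 0.5)
        np.testing.assert_allclose(model.pi, 0.5)
        assert model.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_state_closed_form(self, two_state_model):
        np.testing.assert_allclose(two_state_model.pi, [2 / 3, 1 / 3], atol=1e-6)
        assert two_state_model.eigenvalues[1] == pytest.approx(0.7, abs=1e-6)
        assert two_state_model.implied_timescales(1)[0] == pytest.approx(
            -1 / math.log(0.7), rel=1e-5
        )

    def test_implied_timescale_formula(self, two_state_T):
        model = model_from_T(two_state_T, frame_interval=45.0)
        # lambda_2 = 0.7 at tau = 45 -> t2 = -45/ln 0.7
        assert model.implied_timescales(1)[0] == pytest.approx(
            -45.0 / math.log(0.7), rel=1e-5
        )

    def test_pi_is_fixed_point(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            model = model_from_T(random_reversible_T(6, rng))
            assert np.abs(model.pi @ model.T - model.pi).sum() < 1e-10

    def test_detailed_balance_of_reversible_estimator(self):
        rng = np.random.default_rng(1)
        model = model_from_T(random_reversible_T(5, rng))
        flux = model.pi[:, None] * model.T
        np.testing.assert_allclose(flux, flux.T, atol=1e-10)

    def test_nonreversible_estimator_row_normalizes_counts(self):
        from bridgemsm.msm import CountMatrix

        counts = np.array([[8, 2], [1, 9]])
        cm = CountMatrix(counts, 1, np.arange(2), 2)
        model = estimate_markov_model(cm, reversible=False)
        np.testing.assert_allclose(model.T, counts / counts.sum(axis=1)[:, None])


class TestTimescaleScan:
    def test_markovian_data_has_flat_timescales(self, two_state_T):
        dtrajs = [sample_markov_chain(two_state_T, 50_000, 0, s) for s in range(4)]
        table = implied_timescales_scan(dtrajs, lags=[1, 2, 4, 8])
        t2 = table["t2"].to_numpy()
        assert np.ptp(t2) / t2.mean() < 0.2

    def test_white_noise_has_tiny_t2(self):
        rng = np.random.default_rng(2)
        dtrajs = [rng.integers(0, 3, size=5000) for _ in range(2)]
        table = implied_timescales_scan(dtrajs, lags=[1, 2])
        assert (table["t2"] < 1.0).all()

    def test_degenerate_lag_flagged_low_counts(self):
        dtrajs = [np.array([0, 1] * 6)]
        table = implied_timescales_scan(dtrajs, lags=[11])
        assert table.empty or table["low_counts"].all()


class TestGMRQ:
    @staticmethod
    def _dtrajs(T, n_traj, n_steps, seed):
        chains = sample_markov_chains(
            T, n_traj, n_steps, np.zeros(n_traj, dtype=int), seed
        )
        return [chains[i] for i in range(n_traj)]

    def test_m1_scores_one_for_connected_model(self, two_state_T):
        dtrajs = self._dtrajs(two_state_T, 4, 5000, 0)
        model = estimate_markov_model(
            trim_to_connected(count_transitions(dtrajs, 1))
        )
        score, flagged = gmrq_score(model, dtrajs, m=1)
        assert score == pytest.approx(1.0, abs=1e-6)
        assert not flagged

    def test_state_resolving_partition_beats_permuted(self):
        T = three_block_T()
        dtrajs = self._dtrajs(T, 8, 4000, 1)
        true_map = np.array([0, 0, 1, 1, 2, 2])
        scrambled = np.array([0, 1, 2, 0, 1, 2])

        def make_discretizer(param, train):
            return lambda d: param[np.asarray(d)]

        report = gmrq_cross_validate(
            dtrajs,
            grid=[true_map, scrambled],
            make_discretizer=make_discretizer,
            msm_lag=1,
            n_splits=5,
            m=3,
            seed=0,
        )
        means = report.table.groupby("param_index")["test_score"].mean()
        assert means[0] > means[1]  # grid order: true_map, scrambled
        assert report.best_param is true_map

    def test_train_score_exceeds_test_on_average(self):
        T = three_block_T()
        diffs = []
        for seed in range(10):
            dtrajs = self._dtrajs(T, 6, 1500, seed)
            report = gmrq_cross_validate(
                dtrajs,
                grid=[None],
                make_discretizer=lambda p, tr: lambda d: np.asarray(d),
                msm_lag=1,
                n_splits=3,
                m=3,
                seed=seed,
            )
            diffs.append(
                (report.table["train_score"] - report.table["test_score"]).mean()
            )
        assert np.mean(diffs) > 0


class TestResidenceProbability:
    @staticmethod
    def metastable_T(n=8, seed=0, boost=40.0):
        rng = np.random.default_rng(seed)
        W = rng.random((n, n)) + boost * np.eye(n)
        W = 0.5 * (W + W.T)
        return W / W.sum(axis=1)[:, None]

    def test_model_consistent_data_passes_everywhere(self):
        T = self.metastable_T()
        model = model_from_T(T)
        chains = sample_markov_chains(
            T, 10, 50_000, np.zeros(10, dtype=int), seed=3
        )
        report = residence_probability_test(
            model, list(chains), n_top=8, min_start_spacing=5,
            smoothing_window=1, seed=0,
        )
        assert report.all_passed
        np.testing.assert_allclose(report.model_curves[:, 0], 1.0)
        np.testing.assert_allclose(report.data_curves[:, 0], 1.0)

    def test_perturbed_dynamics_fails_somewhere(self):
        T = self.metastable_T()
        model = model_from_T(T)
        # data from a chain with much shorter residence in every state
        T_fast = self.metastable_T(boost=5.0)
        chains = sample_markov_chains(
            T_fast, 10, 50_000, np.zeros(10, dtype=int), seed=4
        )
        report = residence_probability_test(
            model, list(chains), n_top=8, min_start_spacing=5,
            smoothing_window=1, seed=0,
        )
        assert not report.passed.all()

    def test_sparse_state_excluded_with_warning(self):
        T = self.metastable_T(n=3)
        model = model_from_T(T)
        dtrajs = [np.array([0, 1, 0, 1, 0, 1, 2, 0, 1, 0, 1, 0])]
        with pytest.warns(UserWarning, match="excluded"):
            report = residence_probability_test(
                model, dtrajs, n_top=3, lag_multiples=(0, 1),
                min_start_spacing=1, smoothing_window=1,
            )
        assert 2 in report.excluded


class TestMCMCObservables:
    def test_indicator_recovers_stationary_population(self, two_state_model):
        res = sample_observable_mcmc(
            two_state_model, np.array([1.0, 0.0]), n_chains=10,
            n_steps=20_000, seed=0,
        )
        se = res["sd"] / math.sqrt(10)
        assert abs(res["mean"] - 2 / 3) < 3 * se

    def test_constant_observable_has_zero_sd(self, two_state_model):
        res = sample_observable_mcmc(
            two_state_model, np.array([4.2, 4.2]), n_chains=3, n_steps=2000
        )
        assert res["mean"] == pytest.approx(4.2)
        assert res["sd"] == pytest.approx(0.0, abs=1e-14)

    def test_two_block_population_recovery(self):
        # blocks {0,1} and {2,3} with pi-weights 0.7 / 0.3
        W = np.array(
            [
                [60.0, 10.0, 0.5, 0.0],
                [10.0, 60.0, 0.0, 0.5],
                [0.5, 0.0, 25.0, 5.0],
                [0.0, 0.5, 5.0, 25.0],
            ]
        )
        T = W / W.sum(axis=1)[:, None]
        model = model_from_T(T)
        block_weight = model.pi[:2].sum()
        res = sample_observable_mcmc(
            model, np.array([1.0, 1.0, 0.0, 0.0]), n_chains=10,
            n_steps=50_000, seed=1,
        )
        se = res["sd"] / math.sqrt(10)
        assert abs(res["mean"] - block_weight) < 3 * se

    def test_bootstrap_band_contains_mean(self, two_state_model):
        res = sample_observable_mcmc(
            two_state_model, np.array([1.0, 0.0]), n_chains=10,
            n_steps=10_000, seed=2, n_boot=500,
        )
        assert res["ci_low"] <= res["mean"] <= res["ci_high"]

    def test_single_chain_rejected(self, two_state_model):
        with pytest.raises(ValueError, match="2 chains"):
            sample_observable_mcmc(two_state_model, np.zeros(2), n_chains=1)


class TestMCMCMFPT:
    def test_two_state_closed_form(self, two_state_model):
        res = mcmc_mfpt(
            two_state_model, [0], [1], n_chains=10, n_steps=50_000, seed=0
        )
        assert res["mfpt"] == pytest.approx(10.0, rel=0.03)

    def test_target_equals_source_is_zero(self, two_state_model):
        res = mcmc_mfpt(two_state_model, [0], [0], n_chains=4, n_steps=2000)
        assert res["mfpt"] == 0.0

    def test_unreachable_target_raises(self):
        from bridgemsm.msm import CountMatrix

        cm = CountMatrix(
            np.array([[10, 0], [0, 10]]), 1, np.arange(2), 2
        )
        model = estimate_markov_model(cm)
        with pytest.raises(RuntimeError, match="passages"):
            mcmc_mfpt(model, [0], [1], n_chains=3, n_steps=500, seed=0)


class TestBlockBootstrap:
    def test_constant_series_collapses(self):
        res = block_bootstrap(np.full(100, 3.3), block_length=10, n_resamples=50)
        assert res["ci_low"] == pytest.approx(3.3)
        assert res["ci_high"] == pytest.approx(3.3)

    def test_interval_width_shrinks_with_series_length(self):
        rng = np.random.default_rng(5)
        widths = []
        for n in (1024, 4096):
            series = rng.standard_normal(n)
            res = block_bootstrap(series, 32, n_resamples=400, seed=1)
            widths.append(res["ci_high"] - res["ci_low"])
        # quadrupling the block count should halve the width (CLT scaling)
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)

    def test_failing_statistic_reports_resample(self):
        def bad(_):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="resample 0"):
            block_bootstrap(np.ones(20), 5, statistic=bad, n_resamples=3)

    def test_block_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="block_length"):
            block_bootstrap(np.ones(10), 20)
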