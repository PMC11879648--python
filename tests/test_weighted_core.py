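import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepshare import core
from conftest import two_protein_cluster, align_weights

import oracles


# --------------------------------------------------------------------------
# Huber loss
# --------------------------------------------------------------------------

class TestHuberLoss:
    @pytest.mark.parametrize(
        "x, M, expected",
        [
            (0.0, 0.001, 0.0),
            (0.0005, 0.001, 2.5e-7),
            (1.0, 0.001, 0.001999),
            (-1.0, 0.001, 0.001999),
        ],
    )
    def test_printed_values(self, x, M, expected):
        assert core.huber_loss(x, M) == pytest.approx(expected, abs=1e-15)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            core.huber_loss(1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        x=st.floats(-10, 10), y=st.floats(-10, 10),
        lam=st.floats(0, 1), M=st.floats(1e-6, 1.0),
    )
    def test_convexity(self, x, y, lam, M):
        lhs = core.huber_loss(lam * x + (1 - lam) * y, M)
        rhs = lam * core.huber_loss(x, M) + (1 - lam) * core.huber_loss(y, M)
        assert lhs <= rhs + 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(M=st.floats(1e-5, 1.0))
    def test_continuous_at_threshold(self, M):
        eps = 1e-9 * M
        assert core.huber_loss(M - eps, M) == pytest.approx(core.huber_loss(M + eps, M),
                                                            rel=1e-6)


# --------------------------------------------------------------------------
# median polish and the classical summarizer
# --------------------------------------------------------------------------

class TestMedianPolish:
    def test_exactly_additive_matrix(self):
        overall, row, col, resid = core.median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert overall == pytest.approx(2.5)
        np.testing.assert_allclose(row, [-1.0, 1.0])
        np.testing.assert_allclose(col, [-0.5, 0.5])
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_constant_matrix(self):
        overall, row, col, resid = core.median_polish(np.full((3, 4), 7.0))
        assert overall == pytest.approx(7.0)
        np.testing.assert_allclose(row, 0.0, atol=1e-12)
        np.testing.assert_allclose(col, 0.0, atol=1e-12)

    def test_outlier_matrix_matches_sweep_oracle(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [3.0, 100.0]])
        mine = core.median_polish(X)
        ref = oracles.medpolish_sweeps(X)
        for a, b in zip(mine, ref):
            np.testing.assert_allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(10, 2, size=(rng.integers(2, 6), rng.integers(2, 6)))
        if seed % 2:
            X[rng.integers(X.shape[0]), rng.integers(X.shape[1])] = np.nan
        if not (np.isfinite(X).any(0).all() and np.isfinite(X).any(1).all()):
            X = np.nan_to_num(X, nan=10.0)
        mine = core.median_polish(X)
        ref = oracles.medpolish_sweeps(X)
        for a, b in zip(mine, ref):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_all_missing_row_excluded(self):
        X = np.array([[1.0, 2.0], [np.nan, np.nan]])
        _, row, _, _ = core.median_polish(X)
        assert np.isnan(row[1]) and np.isfinite(row[0])


class TestTmpSummarize:
    def test_single_feature_passthrough(self):
        x = np.array([1.0, 5.0, 3.0])
        np.testing.assert_allclose(core.tmp_summarize(x), x, atol=1e-12)

    def test_parallel_features_preserve_channel_differences(self):
        base = np.array([1.0, 2.0, 4.0])
        X = np.vstack([base, base + 3.0])
        y = core.tmp_summarize(X)
        np.testing.assert_allclose(np.diff(y), np.diff(base), atol=1e-12)

    def test_composition_with_polish_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(12, 1, (3, 4))
        X[1, 2] = 30.0  # outlier cell
        t, _, ce, _ = oracles.medpolish_sweeps(X)
        np.testing.assert_allclose(core.tmp_summarize(X), t + ce, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            core.tmp_summarize(np.full((2, 2), np.nan))


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _toy_cluster(X, membership, proteins=None):
    F, C = np.asarray(X, float).shape
    proteins = proteins or [f"P{k+1}" for k in range(np.asarray(membership).shape[1])]
    return core.ClusterData(
        np.asarray(X, float), np.asarray(membership, bool),
        [f"f{i+1}_2" for i in range(F)], proteins,
        [f"ch{c+1:02d}" for c in range(C)],
    )


class TestInitProfiles:
    def test_single_protein_constraint_algebra(self):
        X = np.array([[1.0, 2.0, 6.0], [1.5, 2.5, 6.5]])
        data = _toy_cluster(X, [[1], [1]])
        mu, feat, prot, chan = core.init_profiles(data)
        y = core.tmp_summarize(X)
        assert prot[0] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(chan[0], y - y.mean(), atol=1e-10)

    def test_unique_feature_profiles_recentred(self):
        X = np.array([[10.0, 11.0], [20.0, 19.0], [15.0, 15.0]])
        data = _toy_cluster(X, [[1, 0], [0, 1], [1, 1]])
        mu, feat, prot, chan = core.init_profiles(data)
        assert prot.sum() == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(chan.sum(axis=1), 0.0, atol=1e-10)
        # shapes of the per-protein channel profiles survive re-centering
        np.testing.assert_allclose(np.diff(chan[0]), np.diff(X[0]), atol=1e-10)

    def test_subset_protein_uses_uniform_fallback(self):
        # P2 has no unique feature; its profile must still be finite
        X = np.array([[10.0, 11.0], [12.0, 13.0]])
        data = _toy_cluster(X, [[1, 0], [1, 1]])
        mu, feat, prot, chan = core.init_profiles(data)
        assert np.isfinite(prot).all() and np.isfinite(chan).all()


# --------------------------------------------------------------------------
# weight step
# --------------------------------------------------------------------------

class TestEstimateWeights:
    def _profiles(self):
        # two clearly non-parallel protein profiles over 6 channels
        chan = np.array([
            [1.0, 0.5, 0.0, -0.5, -1.0, 0.0],
            [-1.0, -0.5, 0.0, 0.5, 1.0, 0.0],
        ])
        return 10.0, np.array([0.0, 0.0]), chan

    def test_unique_feature_weight_is_one(self):
        mu, prot, chan = self._profiles()
        X = mu + np.vstack([prot[0] + chan[0], prot[1] + chan[1]])
        data = _toy_cluster(X, [[1, 0], [0, 1]])
        W, _ = core.estimate_weights(data, mu, np.zeros(2), prot, chan, core.HuberConfig())
        np.testing.assert_array_equal(W, np.eye(2))

    def test_feature_following_one_protein_matches_grid_oracle(self):
        mu, prot, chan = self._profiles()
        shared = mu + prot[0] + chan[0] + 0.3  # follows P1, offset absorbed by Feature_f
        X = np.vstack([mu + prot[0] + chan[0], mu + prot[1] + chan[1], shared])
        data = _toy_cluster(X, [[1, 0], [0, 1], [1, 1]])
        config = core.HuberConfig()
        W, _ = core.estimate_weights(data, mu, np.zeros(3), prot, chan, config)
        t_oracle = oracles.grid_weight_search(
            shared - mu, prot[0] + chan[0], prot[1] + chan[1], config.M
        )
        assert W[2, 0] == pytest.approx(1.0, abs=0.01)
        assert W[2, 0] == pytest.approx(t_oracle, abs=0.01)

    def test_identical_profiles_keep_initialization(self):
        chan = np.array([[1.0, -1.0, 0.0], [1.0, -1.0, 0.0]])
        prot = np.array([0.0, 0.0])
        X = np.vstack([10 + chan[0], 10 + chan[1], 10 + chan[0]])
        data = _toy_cluster(X, [[1, 0], [0, 1], [1, 1]])
        W, _ = core.estimate_weights(data, 10.0, np.zeros(3), prot, chan, core.HuberConfig())
        np.testing.assert_allclose(W[2], [0.5, 0.5])


# --------------------------------------------------------------------------
# profile step
# --------------------------------------------------------------------------

class TestEstimateProfiles:
    def test_single_protein_matches_convex_solver_oracle(self):
        rng = np.random.default_rng(0)
        config = core.HuberConfig(M=1e-3)
        # noise well inside the quadratic zone: strictly convex objective
        X = 12.0 + rng.normal(0, 1, 5)[:, None] + rng.normal(0, 2, 6)[None, :] \
            + rng.normal(0, 2e-4, (5, 6))
        data = _toy_cluster(X, np.ones((5, 1)))
        fit = core.fit_weighted_model(data, config)
        np.testing.assert_allclose(
            fit.summaries()[0], oracles.huber_two_way_fit(X, config.M), atol=1e-4
        )

    def test_zero_noise_parameter_recovery(self):
        mu_t = 14.0
        prot_t = np.array([0.6, -0.6])
        chan_t = np.array([[0.5, -0.5, 0.2, -0.2], [-0.4, 0.4, -0.1, 0.1]])
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.7, 0.3]])
        feat_t = np.array([0.2, -0.1, 0.0])
        feat_t = feat_t - W @ np.linalg.pinv(W.T @ W) @ (W.T @ feat_t)
        X = mu_t + feat_t[:, None] + W @ (prot_t[:, None] + chan_t)
        data = _toy_cluster(X, [[1, 0], [0, 1], [1, 1]])
        mu, feat, prot, chan = core.estimate_profiles(data, W, core.HuberConfig())
        np.testing.assert_allclose(mu, mu_t, atol=1e-6)
        np.testing.assert_allclose(prot, prot_t, atol=1e-6)
        np.testing.assert_allclose(chan, chan_t, atol=1e-6)

    def test_contaminated_cell_barely_moves_summaries(self):
        rng = np.random.default_rng(1)
        config = core.HuberConfig(M=1e-3)
        X = 12.0 + rng.normal(0, 1, 5)[:, None] + rng.normal(0, 2, 6)[None, :] \
            + rng.normal(0, 2e-4, (5, 6))
        Xc = X.copy()
        Xc[2, 3] += 10.0
        clean = core.fit_weighted_model(_toy_cluster(X, np.ones((5, 1))), config)
        dirty = core.fit_weighted_model(_toy_cluster(Xc, np.ones((5, 1))), config)
        assert np.abs(clean.summaries() - dirty.summaries()).max() < 0.05

    def test_l2_loss_matches_least_squares(self):
        rng = np.random.default_rng(7)
        X = 10.0 + rng.normal(0, 1, (4, 5))
        data = _toy_cluster(X, np.ones((4, 1)))
        fit = core.fit_weighted_model(data, core.HuberConfig(loss="l2"))
        # two-way OLS summary: grand mean + column deviation
        expected = X.mean(axis=0)
        np.testing.assert_allclose(fit.summaries()[0], expected, atol=1e-8)

    def test_zero_weight_protein_kept_at_init(self):
        X = np.array([[10.0, 11.0], [12.0, 13.0]])
        data = _toy_cluster(X, [[1, 0], [1, 0]], proteins=["P1", "P2"])
        W = np.array([[1.0, 0.0], [1.0, 0.0]])
        init = (0.0, np.zeros(2), np.array([0.0, 0.5]), np.zeros((2, 2)))
        mu, feat, prot, chan, degenerate = core._profile_step(
            data, W, core.HuberConfig(), init
        )
        assert degenerate == ["P2"]


# --------------------------------------------------------------------------
# full alternating fit
# --------------------------------------------------------------------------

class TestFitWeightedModel:
    def test_trivial_cluster_converges_first_iteration(self):
        X = np.array([[1.0, 2.0, 3.0], [1.1, 2.1, 3.1]])
        fit = core.fit_weighted_model(_toy_cluster(X, np.ones((2, 1))))
        assert fit.converged and fit.n_iter == 1
        np.testing.assert_array_equal(fit.weights, 1.0)

    def test_low_noise_weight_recovery(self):
        data, truth = two_protein_cluster(noise_sd=0.05, channel_sd=0.2, seed=2)
        fit = core.fit_weighted_model(data)
        assert fit.converged
        assert np.abs(align_weights(fit, truth)).max() < 0.1

    def test_uniform_weights_forced_is_inclusion_fit(self):
        data, _ = two_protein_cluster(noise_sd=0.05, channel_sd=0.2, seed=3)
        fit = core.fit_weighted_model(data, update_weights=False)
        expected = core.initial_weights(data)
        np.testing.assert_array_equal(fit.weights, expected)
        # summaries equal a direct profile fit at the uniform weights
        mu, feat, prot, chan = core.estimate_profiles(
            data, expected, core.HuberConfig(), init=core.init_profiles(data)
        )
        np.testing.assert_allclose(
            fit.summaries(), mu + prot[:, None] + chan, atol=1e-8
        )

    def test_objective_monotone_over_half_steps(self):
        data, _ = two_protein_cluster(noise_sd=0.1, channel_sd=0.2, seed=4)
        fit = core.fit_weighted_model(data)
        trace = np.array(fit.objective_trace)
        assert (np.diff(trace) <= 1e-6).all()

    def test_constraints_satisfied(self):
        data, _ = two_protein_cluster(noise_sd=0.1, channel_sd=0.2, seed=5)
        fit = core.fit_weighted_model(data)
        assert fit.feature_effects.sum() == pytest.approx(0.0, abs=1e-8)
        assert fit.protein_effects.sum() == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.channel_effects.sum(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.weights.sum(axis=1), 1.0, atol=1e-6)
        assert (fit.weights >= 0).all()
        assert (fit.weights[~data.membership] == 0).all()

    def test_protein_relabeling_permutes_outputs(self):
        data, _ = two_protein_cluster(noise_sd=0.05, channel_sd=0.3, seed=6)
        fit = core.fit_weighted_model(data)
        # relabel so the sorted protein order flips
        swapped = core.ClusterData(
            data.X, data.membership[:, ::-1], data.feature_ids,
            ["Zz" if p == "Prot1" else p for p in reversed(data.proteins)],
            data.channels,
        )
        fit2 = core.fit_weighted_model(swapped)
        np.testing.assert_allclose(fit.summaries()[0], fit2.summaries()[1], atol=1e-6)
        np.testing.assert_allclose(fit.weights[:, 0], fit2.weights[:, 1], atol=1e-6)

    def test_location_equivariance(self):
        data, _ = two_protein_cluster(noise_sd=0.05, channel_sd=0.3, seed=8)
        fit = core.fit_weighted_model(data)
        shifted = core.ClusterData(
            data.X + 3.0, data.membership, data.feature_ids, data.proteins, data.channels
        )
        fit2 = core.fit_weighted_model(shifted)
        np.testing.assert_allclose(fit2.summaries(), fit.summaries() + 3.0, atol=1e-6)

    def test_missing_values_ignored(self):
        data, truth = two_protein_cluster(noise_sd=0.02, channel_sd=0.3, seed=9)
        X = data.X.copy()
        X[0, 0] = np.nan
        X[3, 5] = np.nan
        fit = core.fit_weighted_model(
            core.ClusterData(X, data.membership, data.feature_ids,
                             data.proteins, data.channels)
        )
        assert np.isfinite(fit.summaries()).all()

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            core.fit_weighted_model(
                core.ClusterData(np.empty((0, 3)), np.empty((0, 1), bool),
                                 [], ["P1"], ["a", "b", "c"])
            )


class TestExtractSummaries:
    def test_summary_identity(self):
        data, _ = two_protein_cluster(noise_sd=0.05, channel_sd=0.2, seed=10)
        fit = core.fit_weighted_model(data)
        out = core.extract_summaries(fit)
        assert len(out) == len(fit.proteins) * len(fit.channels)
        y = out[out.protein == fit.proteins[0]].summary.to_numpy()
        np.testing.assert_allclose(
            y, fit.mu + fit.protein_effects[0] + fit.channel_effects[0], atol=1e-12
        )
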