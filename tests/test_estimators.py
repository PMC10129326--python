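"""Estimator correctness against closed forms and independent oracles."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import Ridge as SkRidge

import cerebconn as cc
from cerebconn.estimators import (
    LassoConnectivity,
    RidgeConnectivity,
    WTAConnectivity,
)


def _orthonormal_design(rng, t, q):
    M = rng.normal(size=(t, q))
    Q, _ = np.linalg.qr(M)
    return Q[:, :q]


class TestRidge:
    def test_orthonormal_columns_lambda_zero_gives_xty(self, rng):
        X = _orthonormal_design(rng, 30, 5)
        Y = rng.normal(size=(30, 3))
        est = RidgeConnectivity(log_lambda=-np.inf).fit(X, Y)
        assert np.allclose(est.W_, X.T @ Y, atol=1e-10)

    def test_identity_design_closed_form(self):
        # X = I2, y = (1, 0), lambda = 1 -> w = (X'X + I)^-1 X'y = (0.5, 0)
        est = RidgeConnectivity(log_lambda=0.0).fit(np.eye(2), np.array([1.0, 0.0]))
        assert np.allclose(est.W_.ravel(), [0.5, 0.0])

    def test_shrinkage_limit(self, rng):
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 2))
        norms = [
            np.linalg.norm(RidgeConnectivity(log_lambda=ll).fit(X, Y).W_)
            for ll in (0.0, 4.0, 8.0, 12.0, 18.0)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-4

    def test_matches_normal_equations_and_sklearn(self, rng):
        for _ in range(20):
            T = int(rng.integers(10, 51))
            Q = int(rng.integers(2, 21))
            X = rng.normal(size=(T, Q))
            Y = rng.normal(size=(T, 3))
            for ll in (-4.0, 0.0, 3.0):
                lam = np.exp(ll)
                W = RidgeConnectivity(log_lambda=ll).fit(X, Y).W_
                W_direct = np.linalg.solve(X.T @ X + lam * np.eye(Q), X.T @ Y)
                assert np.allclose(W, W_direct, rtol=1e-8, atol=1e-10)
                W_sk = SkRidge(alpha=lam, fit_intercept=False).fit(X, Y).coef_.T
                assert np.allclose(W, W_sk, rtol=1e-6, atol=1e-8)

    def test_rank_deficient_lambda_zero_warns_minimum_norm(self, rng):
        X = np.tile(rng.normal(size=(10, 1)), (1, 3))
        with pytest.warns(UserWarning, match="minimum-norm"):
            est = RidgeConnectivity(log_lambda=-np.inf).fit(X, rng.normal(size=10))
        assert np.isfinite(est.W_).all()


class TestLasso:
    def test_lambda_zero_equals_ols(self, rng):
        X = rng.normal(size=(50, 5))
        Y = rng.normal(size=(50, 2))
        W = LassoConnectivity(log_lambda=-np.inf).fit(X, Y).W_
        W_ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.allclose(W, W_ols, atol=1e-5)

    def test_orthonormal_soft_threshold(self, rng):
        # min ||y - Xw||^2 + lambda |w| with X'X = I soft-thresholds the
        # OLS coefficient at lambda / 2: b = 1, lambda = 1 -> w = 0.5
        X = _orthonormal_design(rng, 40, 4)
        b = np.array([1.0, -0.8, 0.3, 0.0])
        y = X @ b
        W = LassoConnectivity(log_lambda=0.0, tol=1e-10).fit(X, y).W_.ravel()
        expected = np.sign(b) * np.maximum(np.abs(b) - 0.5, 0.0)
        assert np.allclose(W, expected, atol=1e-5)

    def test_zero_response_gives_zero_weights(self, rng):
        X = rng.normal(size=(30, 5))
        W = LassoConnectivity(log_lambda=1.0).fit(X, np.zeros((30, 2))).W_
        assert not W.any()

    def test_kkt_conditions_at_solution(self, rng):
        # gradient of the smooth part is 2 X'(Xw - y); at the optimum it
        # equals -lambda sign(w) on active coordinates and is within
        # [-lambda, lambda] (halved per side: lambda/2 scaling folded into
        # the objective) on the zero ones
        X = rng.normal(size=(60, 10))
        Y = X @ rng.normal(size=(10, 4)) + 0.5 * rng.normal(size=(60, 4))
        ll = 3.0
        lam = np.exp(ll)
        W = LassoConnectivity(log_lambda=ll, tol=1e-12, max_iter=50_000).fit(X, Y).W_
        G = 2.0 * X.T @ (X @ W - Y)
        tol = 1e-4 * lam
        active = W != 0
        assert np.allclose(G[active], -lam * np.sign(W[active]), atol=tol)
        assert (np.abs(G[~active]) <= lam * (1 + 1e-4) + tol).all()

    def test_sparsity_monotone_in_lambda(self, rng):
        X = rng.normal(size=(50, 12))
        Y = X @ rng.normal(size=(12, 3)) + rng.normal(size=(50, 3))
        counts = [
            (LassoConnectivity(log_lambda=ll).fit(X, Y).W_ != 0).sum()
            for ll in np.arange(-2.0, 9.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestWTA:
    def test_exact_match_selects_that_parcel_with_unit_weight(self, rng):
        X, _ = cc.zstandardize(rng.normal(size=(30, 5)))
        y = X[:, 2].copy()
        est = WTAConnectivity().fit(X, y)
        assert est.winners_[0] == 2
        assert est.W_[2, 0] == pytest.approx(1.0)
        assert (est.W_[[0, 1, 3, 4], 0] == 0).all()
        assert np.allclose(est.predict(X).ravel(), y)

    def test_against_brute_force_correlation_scan(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 7))
        est = WTAConnectivity().fit(X, Y)
        for p in range(7):
            rs = [np.corrcoef(X[:, q], Y[:, p])[0, 1] for q in range(3)]
            q_best = int(np.argmax(rs))
            assert est.winners_[p] == q_best
            slope = np.polyfit(X[:, q_best], Y[:, p], 1)[0]
            assert est.W_[q_best, p] == pytest.approx(slope)
            assert (np.delete(est.W_[:, p], q_best) == 0).all()

    def test_exact_tie_goes_to_lower_index(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, x])
        est = WTAConnectivity().fit(X, x)
        assert est.winners_[0] == 0

    def test_zero_variance_voxel_flagged_as_zeros(self, rng):
        X = rng.normal(size=(10, 3))
        Y = np.column_stack([rng.normal(size=10), np.full(10, 2.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            est = WTAConnectivity().fit(X, Y)
        assert np.array_equal(est.degenerate_voxels_, [1])
        assert not est.W_[:, 1].any()

    def test_training_accuracy_bounded_by_unpenalized_ridge(self, small_pairs):
        # WTA is a constrained special case of the linear model
        pair = small_pairs[0]
        wta = WTAConnectivity().fit(pair.X, pair.Y)
        ols = RidgeConnectivity(log_lambda=-np.inf).fit(pair.X, pair.Y)
        r_wta = cc.predictive_accuracy(wta.predict(pair.X), pair.Y)
        r_ols = cc.predictive_accuracy(ols.predict(pair.X), pair.Y)
        assert (r_wta <= r_ols + 1e-10).all()

    def test_sklearn_protocol(self):
        est = RidgeConnectivity(log_lambda=2.0)
        assert est.get_params() == {"log_lambda": 2.0}
        cloned = clone(est).set_params(log_lambda=1.0)
        assert cloned.get_params()["log_lambda"] == 1.0
        assert clone(LassoConnectivity(log_lambda=0.5)).log_lambda == 0.5
        assert isinstance(clone(WTAConnectivity()), WTAConnectivity)


class TestTuneLambda:
    def test_singleton_grid_returns_that_value(self, small_pairs):
        grid = cc.tune_lambda(small_pairs, "ridge", grid=[2.5], seed=0)
        assert grid.chosen == 2.5

    def test_empty_grid_rejected(self, small_pairs):
        with pytest.raises(ValueError, match="empty"):
            cc.tune_lambda(small_pairs, "ridge", grid=[], seed=0)

    def test_noise_forces_ridge_shrinkage(self, parcels20):
        truth = cc.make_ground_truth(
            parcels20, 40, "convergent", seed=1, noise_variance=4.0
        )
        study = cc.simulate_study("A", parcels20, truth, seed=2)
        fits = [cc.reconstruct_session(s) for s in study.sessions]
        pairs = cc.make_crossed_pairs(*fits)
        grid = cc.tune_lambda(pairs, "ridge", seed=0)
        assert grid.chosen > grid.log_lambdas.min()

    def test_noiseless_data_prefers_weak_penalty(self, parcels20):
        truth = cc.GroundTruth(
            W_true=cc.make_ground_truth(parcels20, 40, "convergent", seed=1).W_true,
            scenario="convergent", noise_variance=0.0,
            weight_variance=0.2, seed=1,
        )
        study = cc.simulate_study(
            "A", parcels20, truth, seed=2, cortical_noise_variance=0.0
        )
        fits = [cc.reconstruct_session(s) for s in study.sessions]
        pairs = cc.make_crossed_pairs(*fits)
        grid = cc.tune_lambda(pairs, "ridge", seed=0)
        # accuracy curve must not improve with heavy shrinkage, and the
        # chosen lambda sits near the bottom of the grid
        assert grid.chosen <= grid.log_lambdas.min() + 2
        top = grid.cv_accuracy[grid.log_lambdas >= 4]
        assert (np.diff(top) <= 1e-8).all()


class TestGroupAverage:
    def _weights(self, W):
        return cc.ConnectivityWeights(W=np.asarray(W, float), method="ridge",
                                      log_lambda=0.0)

    def test_idempotent_and_mean(self):
        a = self._weights([[0.0, 2.0]])
        b = self._weights([[2.0, 0.0]])
        assert np.array_equal(cc.group_average_weights([a, a]).W, a.W)
        assert np.allclose(cc.group_average_weights([a, b]).W, [[1.0, 1.0]])

    def test_shape_and_method_mismatch_rejected(self):
        a = self._weights([[1.0]])
        b = self._weights([[1.0, 2.0]])
        with pytest.raises(ValueError):
            cc.group_average_weights([a, b])
        wta = cc.ConnectivityWeights(W=np.array([[1.0]]), method="wta")
        with pytest.raises(ValueError):
            cc.group_average_weights([a, wta])

    def test_averaging_reduces_weight_error(self, parcels20):
        """Group-averaged weights beat every individual in recovery RMSE."""
        truth = cc.make_ground_truth(parcels20, 15, "convergent", seed=5)
        individuals = []
        for seed in range(8):
            study = cc.simulate_study("A", parcels20, truth, seed=40 + seed)
            fits = [
                cc.reconstruct_session(s, standardize=False)
                for s in study.sessions
            ]
            pairs = cc.make_crossed_pairs(*fits)
            individuals.append(cc.fit_ridge(pairs, log_lambda=0.0))
        group = cc.group_average_weights(individuals)
        rmse = lambda w: np.sqrt(np.mean((w.W - truth.W_true) ** 2))
        assert rmse(group) < min(rmse(w) for w in individuals)
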