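"""PLS core: extraction, coefficients, prediction, component selection."""

import json

import numpy as np
import pytest

import envpls as ep
from envpls.pls import PLS, select_ncomp


def _random_problem(seed, n=12, p=4, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestFit:
    def test_single_direction_exact_fit(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2.0 * X.ravel()
        res = ep.pls_fit(X, y, a=1)
        np.testing.assert_allclose(res.B, [2.0], atol=1e-12)
        np.testing.assert_allclose(res.fittedvalues, y, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_full_rank_fit_equals_least_squares(self, seed):
        X, y = _random_problem(seed)
        res = ep.pls_fit(X, y, a=4)
        Xc = X - X.mean(axis=0)
        beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(res.B, beta_ols, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_score_orthogonality(self, seed):
        X, y = _random_problem(seed, n=20, p=8)
        res = ep.pls_fit(X, y, a=6)
        TtT = res.T.T @ res.T
        off = TtT - np.diag(np.diag(TtT))
        assert np.max(np.abs(off)) < 1e-8

    def test_r_matrix_identity(self):
        X, y = _random_problem(3, n=15, p=6)
        res = ep.pls_fit(X, y, a=4)
        np.testing.assert_allclose(res.R, res.W @ np.linalg.inv(res.P.T @ res.W),
                                   atol=1e-8)
        # T = X_centered R
        np.testing.assert_allclose(res.T, (X - X.mean(axis=0)) @ res.R, atol=1e-8)

    def test_scale_equivariance_in_y(self):
        X, y = _random_problem(4)
        B1 = ep.pls_fit(X, y, a=3).B
        B2 = ep.pls_fit(X, 7.5 * y, a=3).B
        np.testing.assert_allclose(B2, 7.5 * B1, rtol=1e-10)

    def test_one_component_proportional_to_xty(self):
        X, y = _random_problem(5, n=25, p=6)
        res = ep.pls_fit(X, y, a=1)
        s = (X - X.mean(axis=0)).T @ (y - y.mean())
        ratio = res.B / s
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_deflation_shrinks_x_norm_monotonically(self):
        X, y = _random_problem(6, n=30, p=10)
        res = ep.pls_fit(X, y, a=8)
        Xc = X - X.mean(axis=0)
        E = Xc.copy()
        norms = [np.linalg.norm(E)]
        for k in range(res.ncomp_eff):
            E = E - np.outer(res.T[:, k], res.P[:, k])
            norms.append(np.linalg.norm(E))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_duplicated_column_never_hurts_training_fit(self):
        X, y = _random_problem(7, n=20, p=5)
        base = np.linalg.norm(ep.pls_fit(X, y, a=3).resid)
        dup = np.linalg.norm(ep.pls_fit(np.hstack([X, X[:, :1]]), y, a=3).resid)
        assert dup <= base + 1e-10

    def test_matches_sklearn_reference(self):
        # independent implementation of the same algorithm
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_problem(8, n=40, p=10)
        ours = ep.pls_fit(X, y, a=4)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(ours.B, ref.coef_.ravel(), atol=1e-8)

    def test_errors(self):
        X, y = _random_problem(0)
        with pytest.raises(ValueError, match="ncomp"):
            PLS(y, X, ncomp=12)
        with pytest.raises(ValueError, match="zero variance"):
            PLS(np.ones(12), X, ncomp=1)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self):
        X, y = _random_problem(1)
        res = ep.pls_fit(X, y, a=3)
        np.testing.assert_allclose(res.predict(X), res.fittedvalues, atol=1e-12)

    def test_center_row_predicts_training_mean(self):
        X, y = _random_problem(2)
        res = ep.pls_fit(X, y, a=3)
        pred = res.predict(res.x_center)
        np.testing.assert_allclose(pred, [y.mean()], atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_coefficient_and_score_routes_agree(self, seed):
        X, y = _random_problem(seed, n=18, p=7)
        res = ep.pls_fit(X, y, a=5)
        X_new = np.random.default_rng(100 + seed).standard_normal((6, 7))
        via_B = res.predict(X_new, via="B")
        via_T = res.predict(X_new, via="scores")
        assert np.max(np.abs(via_B - via_T)) < 1e-10

    def test_column_mismatch_errors(self):
        X, y = _random_problem(3)
        res = ep.pls_fit(X, y, a=2)
        with pytest.raises(ValueError, match="columns"):
            res.predict(np.zeros((2, 5)))

    def test_serialization_round_trip(self):
        X, y = _random_problem(4)
        res = ep.pls_fit(X, y, a=3)
        payload = json.loads(res.to_json())
        np.testing.assert_allclose(payload["B"], res.B)
        assert payload["ncomp_eff"] == res.ncomp_eff


class TestSelectNcomp:
    def test_noiseless_rank_one_selects_one_component(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(30)
        X = np.outer(u, rng.standard_normal(5))
        y = X @ np.array([1.0, 2, 3, 4, 5])
        a_star, curve = select_ncomp(X, y, k_folds=5, a_max=3, seed=0)
        assert a_star == 1
        assert curve[0] < 1e-8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 10))
        y = X @ rng.standard_normal(10) + rng.standard_normal(40)
        out1 = select_ncomp(X, y, k_folds=5, seed=123)
        out2 = select_ncomp(X, y, k_folds=5, seed=123)
        assert out1[0] == out2[0]
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_recovers_generative_rank(self):
        # y built from 3 orthogonal informative X-directions at high SNR:
        # the 10-fold RMSEP minimum should sit at 3 components in >= 95% of seeds
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            Q, _ = np.linalg.qr(rng.standard_normal((200, 8)))
            X = Q * np.array([5.0, 4.0, 3.0, 1.0, 1.0, 1.0, 1.0, 1.0])
            y = (X[:, 0] * 2.0 + X[:, 1] * 1.5 + X[:, 2] * 1.0
                 + 0.3 * rng.standard_normal(200))
            a_star, _ = select_ncomp(X, y, k_folds=10, a_max=8, seed=seed)
            hits += a_star == 3
        assert hits >= 48  # >= 95% of 50

    def test_fold_too_small_errors(self):
        X, y = _random_problem(5, n=3, p=3)
        with pytest.raises(ValueError):
            select_ncomp(X, y, k_folds=2, a_max=2, seed=0)
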