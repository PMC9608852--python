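"""Bayesian GBLUP sampler and the closed-form BLUP oracle."""

import numpy as np
import pytest

import envpls as ep
from envpls.design import ObservationIndex
from envpls.gblup import GBLUP, GBLUPSpec, blup_oracle, gblup_fit


def _split_env(idx, env_pos):
    ei = idx.env_positions()
    return idx.subset(ei != env_pos), idx.subset(ei == env_pos)


class TestOracle:
    def test_matches_brute_force_conditional_gaussian(self, tiny_gblup_setup):
        # independent route: assemble the joint normal of (train, test) rows
        # and condition directly
        y, idx, G, H, vc = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 2)
        train_mask = idx.env_positions() != 2
        pred = blup_oracle(y[train_mask], idx_train, idx_test, G, H, vc)

        Hm, Gm = H.matrix, G.matrix

        def K(e1, l1, e2, l2):
            Hb = Hm[np.ix_(e1, e2)]
            Gb = Gm[np.ix_(l1, l2)]
            return vc["env"] * Hb + vc["g"] * Gb + vc["ge"] * Hb * Gb

        e1, l1 = idx_train.env_positions(), idx_train.line_positions()
        e2, l2 = idx_test.env_positions(), idx_test.line_positions()
        V = K(e1, l1, e1, l1) + vc["resid"] * np.eye(idx_train.n)
        C = K(e2, l2, e1, l1)
        Vinv = np.linalg.inv(V)
        ones = np.ones(idx_train.n)
        mu = (ones @ Vinv @ y[train_mask]) / (ones @ Vinv @ ones)
        brute = mu + C @ Vinv @ (y[train_mask] - mu)
        assert np.max(np.abs(pred - brute)) < 1e-10

    def test_zero_genetic_variance_predicts_gls_mean(self, tiny_gblup_setup):
        y, idx, G, H, _ = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 1)
        train_mask = idx.env_positions() != 1
        vc0 = {"env": 0.0, "g": 0.0, "ge": 0.0, "resid": 1.0}
        pred = blup_oracle(y[train_mask], idx_train, idx_test, G, H, vc0)
        np.testing.assert_allclose(pred, y[train_mask].mean(), atol=1e-10)

    def test_shrinkage_limit_recovers_line_deviation(self, tiny_gblup_setup):
        # huge line variance, tiny noise, no GE, H = I: the prediction for a
        # line seen in training approaches mu + its training deviation
        y, idx, G, H, _ = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 2)
        train_mask = idx.env_positions() != 2
        vc = {"env": 0.0, "g": 1e6, "ge": 0.0, "resid": 1e-6}
        pred = blup_oracle(y[train_mask], idx_train, idx_test, G, H, vc)
        # expected: per-line mean of training deviations, since g is free
        y_tr = y[train_mask]
        li_tr = idx_train.line_positions()
        li_te = idx_test.line_positions()
        mu = y_tr.mean()
        line_dev = np.array([
            (y_tr[li_tr == j] - mu).mean() for j in li_te
        ])
        np.testing.assert_allclose(pred, mu + line_dev, atol=1e-3)

    def test_singular_covariance_errors(self, tiny_gblup_setup):
        y, idx, G, H, _ = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 0)
        train_mask = idx.env_positions() != 0
        vc = {"env": 0.0, "g": 0.0, "ge": 0.0, "resid": 0.0}
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            blup_oracle(y[train_mask], idx_train, idx_test, G, H, vc)


class TestGibbs:
    def test_fixed_variance_posterior_matches_oracle(self, tiny_gblup_setup):
        y, idx, G, H, vc = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 2)
        train_mask = idx.env_positions() != 2
        oracle = blup_oracle(y[train_mask], idx_train, idx_test, G, H, vc)
        model = GBLUP(y[train_mask], idx_train, G, H, include_ge=True)
        post = model.fit(iterations=12_000, burnin=2_000, thin=5, seed=3,
                         fix_varcomps=vc, index_test=idx_test)
        gap = np.abs(post.yhat_test - oracle)
        assert np.all(gap < 3.0 * np.maximum(post.yhat_test_mcse(), 1e-6))

    def test_pure_noise_predictions_near_train_mean(self):
        rng = np.random.default_rng(5)
        J, I = 40, 5
        M = rng.integers(0, 3, (J, 80)).astype(float)
        G = ep.compute_G(M)
        H = ep.identity_H(I)
        idx = ObservationIndex.balanced(H.ids, G.ids)
        y = 4.0 + rng.standard_normal(idx.n)  # all genetic variances zero
        idx_train, idx_test = _split_env(idx, I - 1)
        train_mask = idx.env_positions() != I - 1
        model = GBLUP(y[train_mask], idx_train, G, H)
        post = model.fit(iterations=4_000, burnin=1_000, thin=4, seed=1,
                         index_test=idx_test)
        sd = post.yhat_test_draws.std(axis=0, ddof=1)
        gap = np.abs(post.yhat_test - y[train_mask].mean())
        assert np.all(gap < 3.0 * np.maximum(sd, 1e-3))

    def test_main_effects_variant_equals_ge_variance_zero(self, tiny_gblup_setup):
        y, idx, G, H, vc = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 1)
        train_mask = idx.env_positions() != 1
        vc_nog = {"env": vc["env"], "g": vc["g"], "resid": vc["resid"]}
        m2 = GBLUP(y[train_mask], idx_train, G, H, include_ge=False)
        p2 = m2.fit(iterations=8_000, burnin=1_000, thin=5, seed=11,
                    fix_varcomps=vc_nog, index_test=idx_test)
        vc_zero = dict(vc_nog, ge=0.0)
        m1 = GBLUP(y[train_mask], idx_train, G, H, include_ge=True)
        p1 = m1.fit(iterations=8_000, burnin=1_000, thin=5, seed=12,
                    fix_varcomps=vc_zero, index_test=idx_test)
        tol = 3.0 * (p1.yhat_test_mcse() + p2.yhat_test_mcse())
        assert np.all(np.abs(p1.yhat_test - p2.yhat_test) < np.maximum(tol, 1e-3))

    def test_exchangeable_lines_get_identical_predictions(self):
        # two lines with identical G rows and identical phenotypes are
        # statistically indistinguishable
        rng = np.random.default_rng(9)
        J, I = 6, 3
        M = rng.integers(0, 3, (J, 50)).astype(float)
        M[1] = M[0]  # duplicate line genotype
        G = ep.compute_G(M)
        H = ep.identity_H(I)
        idx = ObservationIndex.balanced(H.ids, G.ids)
        li = idx.line_positions()
        y = rng.standard_normal(idx.n) + 3.0
        y[li == 1] = y[li == 0]  # identical phenotypes
        idx_train, idx_test = _split_env(idx, I - 1)
        train_mask = idx.env_positions() != I - 1
        post = GBLUP(y[train_mask], idx_train, G, H).fit(
            iterations=6_000, burnin=1_000, thin=5, seed=2, index_test=idx_test)
        te_li = idx_test.line_positions()
        p0 = post.yhat_test[te_li == 0][0]
        p1 = post.yhat_test[te_li == 1][0]
        se = post.yhat_test_mcse()
        assert abs(p0 - p1) < 4.0 * (se[te_li == 0][0] + se[te_li == 1][0])

    def test_predict_method_agrees_with_stored_test_means(self, tiny_gblup_setup):
        y, idx, G, H, vc = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 0)
        train_mask = idx.env_positions() != 0
        post = GBLUP(y[train_mask], idx_train, G, H).fit(
            iterations=3_000, burnin=500, thin=5, seed=4, index_test=idx_test)
        # post-hoc prediction from posterior-mean effects equals the average
        # of the per-draw predictions (linearity), up to float accumulation
        np.testing.assert_allclose(post.predict(idx_test), post.yhat_test,
                                   atol=1e-8)

    def test_spec_wrapper_and_chain_validation(self, tiny_gblup_setup):
        y, idx, G, H, vc = tiny_gblup_setup
        idx_train, idx_test = _split_env(idx, 0)
        train_mask = idx.env_positions() != 0
        spec = GBLUPSpec(G=G, H=H, iterations=1_000, burnin=200, thin=2, seed=0)
        res = gblup_fit(y[train_mask], idx_train, idx_test, spec)
        assert res.yhat_test.shape == (idx_test.n,)
        assert all(s["mean"] >= 0 for s in res.varcomp_summaries.values())
        with pytest.raises(ValueError):
            GBLUPSpec(G=G, H=H, iterations=100, burnin=200)
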