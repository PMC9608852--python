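"""Bayesian GBLUP reaction-norm model and a closed-form BLUP oracle.

The model for phenotype y_ij of line j in environment i is

    y_ij = mu + L_i + g_j + gL_ij + e_ij

with L ~ N(0, sigma2_E H), g ~ N(0, sigma2_g G), gL ~ N(0, sigma2_gL (H kron G))
and i.i.d. residuals e ~ N(0, sigma2).  H is the environmental relationship
matrix (identity when no covariates are available) and G the genomic one.
The main-effects variant simply drops the gL term.

Fitting is by Gibbs sampling.  Each random term u ~ N(0, sigma2_u K) is
reparameterized through the eigendecomposition of its full kernel,
u = U diag(sqrt(d)) alpha with alpha ~ N(0, sigma2_u I), which turns the term
into a Bayesian ridge regression on the fixed basis Phi = Z U diag(sqrt(d)).
Because the basis spans ALL levels of the kernel — including environments
absent from training — the sampled alpha automatically carries the posterior
(prior conditional on the observed levels) of unobserved environments'
effects, so posterior predictive means for a brand-new environment come out
of the same draws.  Variance components get scaled-inverse-chi-square priors
whose modes split the phenotypic variance equally across model terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ObservationIndex
from .kinship import Kinship

__all__ = ["GBLUP", "GBLUPResults", "GBLUPSpec", "gblup_fit", "blup_oracle"]

_EIG_TOL = 1e-10


def _kernel_basis(K: np.ndarray):
    """Return Psi = U diag(sqrt(d)) keeping eigenvalues > tol * max."""
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    keep = d > _EIG_TOL * max(d.max(), 1.0)
    return U[:, keep] * np.sqrt(d[keep])


@dataclass(frozen=True)
class GBLUPSpec:
    """Model + sampler settings for the Bayesian GBLUP fit."""

    G: Kinship
    H: Kinship
    include_ge: bool = True
    prior_df: float = 5.0
    iterations: int = 12_000
    burnin: int = 2_000
    thin: int = 5
    seed: int = 0
    fix_varcomps: dict | None = None

    def __post_init__(self):
        if self.iterations <= self.burnin or self.burnin < 0:
            raise ValueError("need iterations > burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df <= 0:
            raise ValueError("prior_df must be > 0")


class GBLUP:
    """Bayesian GBLUP model over an observed (environment, line) index.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Training phenotypes, aligned with ``index.rows``.
    index : ObservationIndex
        Observed (environment, line) pairs for the training rows.  Its
        environment/line spaces must cover any rows later predicted.
    G, H : Kinship
        Genomic (lines) and environmental (environments) relationship
        matrices; the kernel orders must match ``index.line_ids`` and
        ``index.env_ids``.
    include_ge : bool
        Include the interaction term with covariance sigma2_gL (H kron G).
    """

    def __init__(self, endog, index: ObservationIndex, G: Kinship, H: Kinship,
                 include_ge: bool = True):
        y = np.asarray(endog, dtype=float).ravel()
        if y.shape[0] != index.n:
            raise ValueError("endog length does not match index rows")
        if tuple(G.ids) != tuple(index.line_ids):
            raise ValueError("G ids must match index.line_ids in order")
        if tuple(H.ids) != tuple(index.env_ids):
            raise ValueError("H ids must match index.env_ids in order")
        self.endog = y
        self.index = index
        self.G = G
        self.H = H
        self.include_ge = bool(include_ge)
        # per-term full-kernel bases
        self._psi_H = _kernel_basis(H.matrix)   # I x mH
        self._psi_G = _kernel_basis(G.matrix)   # J x mG
        self._terms = ["env", "g"] + (["ge"] if self.include_ge else [])

    # basis rows for arbitrary (env, line) observation positions
    def _phi(self, term: str, ei: np.ndarray, li: np.ndarray) -> np.ndarray:
        if term == "env":
            return self._psi_H[ei]
        if term == "g":
            return self._psi_G[li]
        if term == "ge":
            A, B = self._psi_H[ei], self._psi_G[li]
            return np.einsum("ni,nj->nij", A, B).reshape(len(ei), -1)
        raise KeyError(term)

    def fit(self, iterations: int = 12_000, burnin: int = 2_000, thin: int = 5,
            seed: int = 0, prior_df: float = 5.0,
            fix_varcomps: dict | None = None,
            index_test: ObservationIndex | None = None) -> "GBLUPResults":
        """Run the Gibbs sampler and return posterior summaries.

        When ``index_test`` is given, per-draw predictions for those rows are
        stored so Monte Carlo standard errors are available.
        """
        if iterations <= burnin or burnin < 0:
            raise ValueError("need iterations > burnin >= 0")
        if thin < 1:
            raise ValueError("thin must be >= 1")
        rng = np.random.default_rng(int(seed) % (2**31))
        y = self.endog
        n = y.shape[0]
        ei = self.index.env_positions()
        li = self.index.line_positions()

        phi = {t: self._phi(t, ei, li) for t in self._terms}
        gram_eig = {}
        for t, P in phi.items():
            S, V = np.linalg.eigh(P.T @ P)
            gram_eig[t] = (np.clip(S, 0.0, None), V)

        fix = dict(fix_varcomps or {})
        df0 = float(prior_df)
        n_terms = len(self._terms) + 1  # + residual
        vary = float(np.var(y, ddof=1)) if n > 1 else 1.0
        vary = max(vary, 1e-12)
        # prior mode = vary / n_terms for every variance component
        S0 = (vary / n_terms) * (df0 + 2.0) / df0

        mu = float(y.mean())
        sigma2 = {t: fix.get(t, vary / n_terms) for t in self._terms}
        sigma2_e = fix.get("resid", vary / n_terms)
        alpha = {t: np.zeros(phi[t].shape[1]) for t in self._terms}
        e = y - mu

        if index_test is not None:
            ti = index_test.env_positions()
            tj = index_test.line_positions()
            phi_test = {t: self._phi(t, ti, tj) for t in self._terms}

        n_save = (iterations - burnin) // thin
        vc_draws = {t: np.zeros(n_save) for t in self._terms + ["resid"]}
        mu_sum = 0.0
        alpha_sum = {t: np.zeros_like(alpha[t]) for t in self._terms}
        yhat_train_sum = np.zeros(n)
        yhat_test_draws = np.zeros((n_save, index_test.n)) if index_test is not None else None

        saved = 0
        for it in range(iterations):
            # intercept (flat prior)
            e += mu
            mu = rng.normal(e.mean(), np.sqrt(sigma2_e / n))
            e -= mu
            # random terms: block update in the Gram eigenbasis
            for t in self._terms:
                P = phi[t]
                S, V = gram_eig[t]
                r = e + P @ alpha[t]
                if sigma2[t] <= 0.0:  # fixed at zero: effect degenerate at 0
                    alpha[t] = np.zeros_like(alpha[t])
                    e = r
                    continue
                z = V.T @ (P.T @ r) / sigma2_e
                dvec = 1.0 / (S / sigma2_e + 1.0 / sigma2[t])
                a_new = V @ (dvec * z + np.sqrt(dvec) * rng.standard_normal(S.shape[0]))
                alpha[t] = a_new
                e = r - P @ a_new
                if t not in fix:
                    ssq = float(a_new @ a_new)
                    chi = rng.chisquare(df0 + a_new.shape[0])
                    sigma2[t] = (ssq + df0 * S0) / chi
            if "resid" not in fix:
                sigma2_e = (float(e @ e) + df0 * S0) / rng.chisquare(df0 + n)

            if it >= burnin and (it - burnin) % thin == 0:
                for t in self._terms:
                    vc_draws[t][saved] = sigma2[t]
                vc_draws["resid"][saved] = sigma2_e
                mu_sum += mu
                for t in self._terms:
                    alpha_sum[t] += alpha[t]
                yhat_train_sum += y - e
                if index_test is not None:
                    pred = np.full(index_test.n, mu)
                    for t in self._terms:
                        pred += phi_test[t] @ alpha[t]
                    yhat_test_draws[saved] = pred
                saved += 1

        mu_hat = mu_sum / saved
        alpha_mean = {t: alpha_sum[t] / saved for t in self._terms}
        effect_means = {
            "env": self._psi_H @ alpha_mean["env"],
            "g": self._psi_G @ alpha_mean["g"],
        }
        if self.include_ge:
            # full I*J interaction effects, environment-major flattening
            A = alpha_mean["ge"].reshape(self._psi_H.shape[1], self._psi_G.shape[1])
            effect_means["ge"] = (self._psi_H @ A @ self._psi_G.T).reshape(-1)
        varcomp_summaries = {
            k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            for k, v in vc_draws.items()
        }
        return GBLUPResults(
            model=self,
            mu_hat=float(mu_hat),
            effect_means=effect_means,
            alpha_mean=alpha_mean,
            varcomp_summaries=varcomp_summaries,
            varcomp_draws=vc_draws,
            yhat_train=yhat_train_sum / saved,
            yhat_test_draws=yhat_test_draws,
            index_test=index_test,
            n_saved=saved,
        )


@dataclass
class GBLUPResults:
    """Posterior summaries of the Bayesian GBLUP fit."""

    model: GBLUP
    mu_hat: float
    effect_means: dict = field(repr=False)
    alpha_mean: dict = field(repr=False)
    varcomp_summaries: dict
    varcomp_draws: dict = field(repr=False)
    yhat_train: np.ndarray = field(repr=False)
    yhat_test_draws: np.ndarray | None = field(repr=False, default=None)
    index_test: ObservationIndex | None = None
    n_saved: int = 0

    def predict(self, index: ObservationIndex) -> np.ndarray:
        """Posterior predictive means for the given (environment, line) rows.

        Rows in environments absent from training get, through the full-kernel
        basis, the marginal contribution of their environment and interaction
        effects: zero when H is an identity, the H-conditional mean otherwise.
        """
        ei = index.env_positions()
        li = index.line_positions()
        pred = np.full(index.n, self.mu_hat)
        for t in self.model._terms:
            pred += self.model._phi(t, ei, li) @ self.alpha_mean[t]
        return pred

    @property
    def yhat_test(self) -> np.ndarray:
        if self.yhat_test_draws is None:
            raise ValueError("fit was run without index_test")
        return self.yhat_test_draws.mean(axis=0)

    def yhat_test_mcse(self) -> np.ndarray:
        """Monte Carlo standard error of the posterior predictive means,
        from non-overlapping batch means (robust to autocorrelation)."""
        draws = self.yhat_test_draws
        if draws is None:
            raise ValueError("fit was run without index_test")
        m = draws.shape[0]
        n_batch = max(min(20, m // 5), 2)
        size = m // n_batch
        batches = draws[: n_batch * size].reshape(n_batch, size, -1).mean(axis=1)
        return batches.std(axis=0, ddof=1) / np.sqrt(n_batch)

    def summary(self) -> str:
        lines = [
            "Bayesian GBLUP Results",
            "=" * 52,
            f"Observations          {self.model.index.n:>10d}",
            f"Environments / lines  {self.model.index.I:>5d} / {self.model.index.J}",
            f"GE term               {str(self.model.include_ge):>10s}",
            f"Posterior draws       {self.n_saved:>10d}",
            f"Intercept (post mean) {self.mu_hat:>10.4f}",
            "-" * 52,
            "variance component     post. mean    post. sd",
        ]
        label = {"env": "sigma2_E (environments)", "g": "sigma2_g (lines)",
                 "ge": "sigma2_gL (GE)", "resid": "sigma2 (residual)"}
        for k, s in self.varcomp_summaries.items():
            lines.append(f"{label[k]:<22s} {s['mean']:>11.4f} {s['sd']:>11.4f}")
        return "\n".join(lines)


def gblup_fit(y_train, index_train: ObservationIndex,
              index_test: ObservationIndex | None, spec: GBLUPSpec) -> GBLUPResults:
    """Functional wrapper matching the model/sampler spec object."""
    model = GBLUP(y_train, index_train, spec.G, spec.H, include_ge=spec.include_ge)
    return model.fit(
        iterations=spec.iterations, burnin=spec.burnin, thin=spec.thin,
        seed=spec.seed, prior_df=spec.prior_df, fix_varcomps=spec.fix_varcomps,
        index_test=index_test,
    )


def blup_oracle(y_train, index_train: ObservationIndex, index_test: ObservationIndex,
                G: Kinship, H: Kinship, varcomps: dict) -> np.ndarray:
    """Exact conditional-Gaussian predictor with known variance components.

    Builds the marginal covariance of the training rows,
    V = s2_E Z_L H Z_L' + s2_g Z_g G Z_g' + s2_gL Z_gL (H kron G) Z_gL' + s2 I,
    estimates mu by GLS, and returns the conditional mean
    mu + C V^{-1} (y - mu) using the test/train cross-covariance C.
    Deterministic; used as a testing oracle for the Gibbs sampler.
    """
    y = np.asarray(y_train, dtype=float).ravel()
    s2E = float(varcomps.get("env", 0.0))
    s2g = float(varcomps.get("g", 0.0))
    s2ge = float(varcomps.get("ge", 0.0))
    s2e = float(varcomps["resid"])
    Gm, Hm = G.matrix, H.matrix
    ei, li = index_train.env_positions(), index_train.line_positions()
    ti, tj = index_test.env_positions(), index_test.line_positions()

    def cov_blocks(e1, l1, e2, l2):
        Hb = Hm[np.ix_(e1, e2)]
        Gb = Gm[np.ix_(l1, l2)]
        return s2E * Hb + s2g * Gb + s2ge * Hb * Gb

    V = cov_blocks(ei, li, ei, li) + s2e * np.eye(len(y))
    C = cov_blocks(ti, tj, ei, li)
    try:
        Vinv_y = np.linalg.solve(V, y)
        ones = np.ones(len(y))
        Vinv_1 = np.linalg.solve(V, ones)
    except np.linalg.LinAlgError as exc:
        raise ValueError("training covariance V is singular") from exc
    denom = float(ones @ Vinv_1)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("training covariance V is singular")
    mu_gls = float(ones @ Vinv_y) / denom
    resid = y - mu_gls
    return mu_gls + C @ np.linalg.solve(V, resid)
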