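"""Univariate partial least squares regression (NIPALS / SVD form).

Each latent variable is extracted from the SVD of the cross-product of the
current (deflated) data matrices E and F: the first left/right singular
vectors w, q give scores t = E w (normalized to unit length) and u = F q;
loadings p = E^T t and q_load = F^T t are then removed from E and F as the
rank-one updates t p^T and t q_load^T.  After ``a`` components the weights are
mapped back to the original predictors with R = W (P^T W)^{-1}, the inner
regression is b = (T^T T)^{-1} T^T y, and the coefficient vector on the
original (centered) predictors is B = R b.  Predictions for new rows are
X_new B, equivalently (X_new R) b.

The number of components is chosen by minimizing the cross-validated root
mean squared error of prediction (RMSEP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = ["PLS", "PLSResults", "pls_fit", "pls_predict", "select_ncomp"]

#: residual Frobenius norm below this fraction of ||X||_F stops extraction
_DEFLATION_FLOOR = 1e-12


class PLS:
    """Partial least squares regression model for a univariate response.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector.
    exog : array-like, shape (n, p)
        Predictor matrix.  Columns are centered (and optionally scaled) by
        training statistics inside ``fit``.
    ncomp : int
        Number of latent variables to extract; must be <= min(n - 1, p).
    scale : bool
        Scale columns to unit sample variance in addition to centering.
        Off by default: the relationship-matrix-augmented design already has
        columns on comparable scales.

    Examples
    --------
    >>> res = PLS(y, X, ncomp=3).fit()
    >>> res.predict(X_new)
    """

    def __init__(self, endog, exog, ncomp: int = 1, scale: bool = False):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in endog/exog")
        n, p = X.shape
        if ncomp < 1:
            raise ValueError("ncomp must be >= 1")
        if ncomp > min(n - 1, p):
            raise ValueError(
                f"ncomp={ncomp} exceeds min(n-1, p) = {min(n - 1, p)}"
            )
        if np.std(y) == 0.0:
            raise ValueError("response has zero variance")
        self.endog = y
        self.exog = X
        self.ncomp = int(ncomp)
        self.scale = bool(scale)

    def fit(self) -> "PLSResults":
        X, y = self.exog, self.endog
        x_center = X.mean(axis=0)
        if self.scale:
            x_scale = X.std(axis=0, ddof=1)
            x_scale[x_scale == 0.0] = 1.0
        else:
            x_scale = np.ones(X.shape[1])
        y_center = y.mean()
        E = (X - x_center) / x_scale
        f = y - y_center
        x_norm = np.linalg.norm(E)

        n, p = E.shape
        a = self.ncomp
        W = np.zeros((p, a))
        T = np.zeros((n, a))
        P = np.zeros((p, a))
        Q = np.zeros(a)
        U = np.zeros((n, a))
        eff_a = 0
        for k in range(a):
            if np.linalg.norm(E) < _DEFLATION_FLOOR * max(x_norm, 1.0):
                break
            # SVD of E^T f for univariate f: left vector is E^T f normalized,
            # right "vector" is the scalar sign 1.
            s = E.T @ f
            s_norm = np.linalg.norm(s)
            if s_norm == 0.0:  # no remaining covariance with the response
                break
            w = s / s_norm
            # reproducible sign: largest-magnitude entry of w positive
            imax = int(np.argmax(np.abs(w)))
            if w[imax] < 0:
                w = -w
            t = E @ w
            t_norm = np.linalg.norm(t)
            if t_norm == 0.0:
                break
            t = t / t_norm
            u = f.copy()  # u = F q; q is the scalar +/-1 for univariate F
            p_load = E.T @ t
            q_load = f @ t
            E = E - np.outer(t, p_load)
            f = f - t * q_load
            W[:, k], T[:, k], P[:, k], Q[k], U[:, k] = w, t, p_load, q_load, u
            eff_a = k + 1
        if eff_a == 0:
            raise ValueError("could not extract any latent variable")
        W, T, P, Q, U = W[:, :eff_a], T[:, :eff_a], P[:, :eff_a], Q[:eff_a], U[:, :eff_a]
        R = W @ np.linalg.inv(P.T @ W)
        y_c = self.endog - y_center
        TtT = T.T @ T
        b = np.linalg.solve(TtT, T.T @ y_c)
        B = R @ b
        return PLSResults(
            model=self,
            W=W, T=T, P=P, Q=Q, R=R, U=U,
            b=b, B=B, ncomp_eff=eff_a,
            x_center=x_center, x_scale=x_scale, y_center=y_center,
        )


@dataclass
class PLSResults:
    """Fitted PLS model: weights, scores, loadings and coefficients.

    Attributes
    ----------
    W, P : ndarray (p, a)
        X weights and loadings per component.
    T : ndarray (n, a)
        Orthogonal, unit-norm score vectors.
    Q : ndarray (a,)
        Y loadings (univariate response).
    R : ndarray (p, a)
        Weights transformed to the original predictor space, T = X_c R.
    b : ndarray (a,)
        Inner regression coefficients of y on the scores.
    B : ndarray (p,)
        Coefficients on the centered/scaled original predictors, B = R b.
    """

    model: PLS
    W: np.ndarray = field(repr=False)
    T: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    Q: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    U: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)
    ncomp_eff: int = 0
    x_center: np.ndarray = field(default=None, repr=False)
    x_scale: np.ndarray = field(default=None, repr=False)
    y_center: float = 0.0

    def transform(self, exog_new) -> np.ndarray:
        """Score new rows: T_new = X_new_centered R."""
        X = np.asarray(exog_new, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_center.shape[0]:
            raise ValueError(
                f"exog_new has {X.shape[1]} columns, model was fit with "
                f"{self.x_center.shape[0]}"
            )
        return ((X - self.x_center) / self.x_scale) @ self.R

    def predict(self, exog_new, via: str = "B") -> np.ndarray:
        """Predict new rows; ``via`` selects the (algebraically identical)
        coefficient route ``X_new B`` or score route ``T_new b``."""
        X = np.asarray(exog_new, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.x_center.shape[0]:
            raise ValueError(
                f"exog_new has {X.shape[1]} columns, model was fit with "
                f"{self.x_center.shape[0]}"
            )
        Xc = (X - self.x_center) / self.x_scale
        if via == "B":
            return Xc @ self.B + self.y_center
        if via == "scores":
            return (Xc @ self.R) @ self.b + self.y_center
        raise ValueError("via must be 'B' or 'scores'")

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def summary(self) -> str:
        y = self.model.endog
        r = self.resid
        ss_res = float(r @ r)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        lines = [
            "Partial Least Squares Regression Results",
            "=" * 46,
            f"No. observations      {len(y):>12d}",
            f"No. predictors        {self.model.exog.shape[1]:>12d}",
            f"Latent variables      {self.ncomp_eff:>12d}",
            f"Column scaling        {str(self.model.scale):>12s}",
            f"Training R-squared    {1.0 - ss_res / ss_tot:>12.4f}",
            f"Training RMSE         {np.sqrt(ss_res / len(y)):>12.4f}",
            "-" * 46,
            "component   |b_k|        explained y-var",
        ]
        for k in range(self.ncomp_eff):
            fitted_k = self.T[:, k] * self.b[k]
            lines.append(
                f"{k + 1:>9d}   {abs(self.b[k]):<12.4g} {float(fitted_k @ fitted_k) / ss_tot:12.4f}"
            )
        return "\n".join(lines)

    def to_json(self) -> str:
        """Serialize the fitted model to a self-describing JSON string."""
        payload = {
            "ncomp_eff": self.ncomp_eff,
            "scale": self.model.scale,
            "W": self.W.tolist(), "T": self.T.tolist(), "P": self.P.tolist(),
            "Q": self.Q.tolist(), "R": self.R.tolist(), "b": self.b.tolist(),
            "B": self.B.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center,
        }
        return json.dumps(payload)


def pls_fit(X, y, a: int, scale: bool = False) -> PLSResults:
    """Functional wrapper: fit a PLS model with ``a`` latent variables."""
    return PLS(y, X, ncomp=a, scale=scale).fit()


def pls_predict(model: PLSResults, X_new) -> np.ndarray:
    """Functional wrapper around :meth:`PLSResults.predict`."""
    return model.predict(X_new)


def select_ncomp(X, y, k_folds: int = 5, a_max: int | None = None, seed: int = 0,
                 scale: bool = False):
    """Choose the latent-variable count by k-fold cross-validated RMSEP.

    Returns ``(a_star, rmsep_curve)`` where ``rmsep_curve[a - 1]`` is the root
    mean squared error of prediction pooled over all held-out points using
    ``a`` components, and ``a_star`` is the smallest count attaining the
    minimum (ties break toward fewer components).  Deterministic given
    ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError("more folds than observations")
    min_train = n - (n // k_folds + (1 if n % k_folds else 0))
    if min_train < 2:
        raise ValueError("a fold would leave fewer than 2 training rows")
    cap = min(min_train - 1, p, 30)
    if a_max is None:
        a_max = cap
    a_max = min(a_max, cap)
    if a_max < 1:
        raise ValueError("no admissible number of components")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=int(seed) % (2**31))
    sq_err = np.zeros(a_max)
    for train_idx, test_idx in kf.split(X):
        res = PLS(y[train_idx], X[train_idx], ncomp=a_max, scale=scale).fit()
        Xc = (X[test_idx] - res.x_center) / res.x_scale
        T_new = Xc @ res.R  # (m, eff)
        # nested predictions: scores are orthogonal, so the a-component
        # prediction is the cumulative sum of per-component contributions
        contrib = T_new * res.b
        cum = np.cumsum(contrib, axis=1) + res.y_center
        for a in range(1, a_max + 1):
            pred = cum[:, min(a, res.ncomp_eff) - 1]
            sq_err[a - 1] += float(((y[test_idx] - pred) ** 2).sum())
    rmsep_curve = np.sqrt(sq_err / n)
    a_star = int(np.argmin(rmsep_curve)) + 1
    return a_star, rmsep_curve
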