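"""Relationship matrices for lines and environments.

The genomic relationship matrix ``G`` (lines x lines) and the environmental
relationship matrix ``H`` (environments x environments) are both built as the
cross-product of a column-standardized feature matrix divided by the number of
retained columns, following VanRaden-style scaling.  Their symmetric square
roots ``L_g`` and ``L_E`` are what the PLS design augmentation consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Kinship",
    "KinshipRoot",
    "compute_G",
    "compute_H",
    "identity_H",
    "matrix_sqrt",
    "kron",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class Kinship:
    """A symmetric positive semi-definite similarity matrix over named entities.

    Parameters
    ----------
    ids : tuple of str
        Ordered entity identifiers (line or environment names).
    matrix : ndarray
        Square symmetric matrix, ``dim == len(ids)``.
    kind : {"genomic", "environmental", "identity"}
        Provenance of the similarity.
    """

    ids: tuple
    matrix: np.ndarray = field(repr=False)
    kind: str = "genomic"

    def __post_init__(self):
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if K.shape[0] != len(self.ids):
            raise ValueError("kinship dimension does not match number of ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("kinship ids must be unique")
        sym_err = np.max(np.abs(K - K.T)) if K.size else 0.0
        scale = max(np.max(np.abs(K)), 1.0)
        if sym_err > _SYM_TOL * scale:
            raise ValueError(f"kinship matrix not symmetric (max asymmetry {sym_err:g})")
        object.__setattr__(self, "matrix", (K + K.T) / 2.0)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def sqrt(self) -> "KinshipRoot":
        return matrix_sqrt(self)


@dataclass(frozen=True)
class KinshipRoot:
    """Symmetric square root L of a kinship matrix, with L @ L == K."""

    ids: tuple
    matrix: np.ndarray = field(repr=False)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _standardized_crossprod(X: np.ndarray, ids, kind: str, what: str) -> Kinship:
    """Center and scale columns to unit sample variance, drop constant columns,
    and return ``W W^T / p_retained``.  The trace of the result is ``n - 1``
    when no columns are dropped."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{what} matrix must be 2-dimensional")
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 rows to build a {kind} relationship matrix")
    if p < 1:
        raise ValueError(f"{what} matrix has no columns")
    if not np.all(np.isfinite(X)):
        raise ValueError(
            f"missing or non-finite values in {what} matrix; run QC/imputation first"
        )
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    n_drop = int(np.sum(~keep))
    if not np.any(keep):
        if kind == "genomic":
            raise ValueError("no informative markers: all markers are monomorphic")
        raise ValueError(f"all {what} columns are constant")
    if n_drop:
        logger.info("dropped %d constant %s column(s) of %d", n_drop, what, p)
    Xk = X[:, keep]
    W = (Xk - Xk.mean(axis=0)) / sd[keep]
    K = W @ W.T / W.shape[1]
    return Kinship(ids=tuple(ids), matrix=K, kind=kind)


def compute_G(markers, line_ids=None, method: str = "standardize") -> Kinship:
    """Genomic relationship matrix from 0/1/2 marker codes.

    Parameters
    ----------
    markers : MarkerMatrix or ndarray (lines x markers)
        Complete (QC'd / imputed) marker dosages.  Real-valued imputed dosages
        in [0, 2] are accepted.
    line_ids : sequence of str, optional
        Required when ``markers`` is a bare array.
    method : {"standardize", "vanraden1"}
        ``standardize`` (default): per-marker centering and unit-sample-variance
        scaling, G = W W^T / p; gives trace(G) = J - 1.  ``vanraden1``: center
        by 2p_k and divide the cross-product by ``2 * sum p_k (1 - p_k)``.
    """
    codes = getattr(markers, "codes", None)
    if codes is not None:
        X = np.asarray(codes, dtype=float)
        ids = tuple(markers.line_ids)
    else:
        X = np.asarray(markers, dtype=float)
        if line_ids is None:
            line_ids = [f"L{j + 1}" for j in range(X.shape[0])]
        ids = tuple(line_ids)
    if np.any(np.isnan(X)):
        raise ValueError("markers contain missing codes; apply qc_markers first")
    if X.size and (X.min() < 0 or X.max() > 2):
        raise ValueError("marker codes must lie in [0, 2] (0/1/2 or imputed dosages)")
    if method == "standardize":
        return _standardized_crossprod(X, ids, "genomic", "marker")
    if method == "vanraden1":
        freq = X.mean(axis=0) / 2.0
        keep = (freq > 0) & (freq < 1)
        if not np.any(keep):
            raise ValueError("no informative markers: all markers are monomorphic")
        Xk = X[:, keep]
        pk = freq[keep]
        W = Xk - 2.0 * pk
        denom = 2.0 * np.sum(pk * (1.0 - pk))
        return Kinship(ids=ids, matrix=W @ W.T / denom, kind="genomic")
    raise ValueError(f"unknown G method {method!r}")


def compute_H(covariates, env_ids=None) -> Kinship:
    """Environmental relationship matrix H = X_E X_E^T / r from standardized
    environmental covariates (environments x covariates)."""
    values = getattr(covariates, "values", None)
    if values is not None and hasattr(covariates, "index"):
        X = np.asarray(values, dtype=float)
        ids = tuple(str(i) for i in covariates.index)
    else:
        X = np.asarray(covariates, dtype=float)
        if env_ids is None:
            env_ids = [f"E{i + 1}" for i in range(X.shape[0])]
        ids = tuple(env_ids)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 environments to build H")
    return _standardized_crossprod(X, ids, "environmental", "covariate")


def identity_H(I: int, env_ids=None) -> Kinship:
    """Identity environmental relationship matrix, used when no environmental
    covariates are available."""
    if I < 1:
        raise ValueError("environment count must be >= 1")
    if env_ids is None:
        env_ids = [f"E{i + 1}" for i in range(I)]
    if len(env_ids) != I:
        raise ValueError("env_ids length must equal I")
    return Kinship(ids=tuple(env_ids), matrix=np.eye(I), kind="identity")


def matrix_sqrt(K: Kinship, clip_rel: float = 1e-8) -> KinshipRoot:
    """Symmetric PSD square root via eigendecomposition.

    Eigenvalues in ``[-clip_rel * max|lambda|, 0)`` are clipped to zero (numeric
    noise); anything more negative raises, since the matrix is then not PSD.
    """
    A = K.matrix if isinstance(K, Kinship) else np.asarray(K, dtype=float)
    lam, U = np.linalg.eigh((A + A.T) / 2.0)
    lmax = max(np.max(np.abs(lam)), 1.0)
    if np.min(lam) < -clip_rel * lmax:
        raise ValueError(
            f"matrix not PSD: eigenvalue {np.min(lam):g} below tolerance "
            f"{-clip_rel * lmax:g}"
        )
    lam = np.clip(lam, 0.0, None)
    L = (U * np.sqrt(lam)) @ U.T
    L = (L + L.T) / 2.0
    ids = K.ids if isinstance(K, Kinship) else tuple(f"i{k}" for k in range(A.shape[0]))
    return KinshipRoot(ids=ids, matrix=L)


def kron(A, B) -> np.ndarray:
    """Kronecker product (block (i, j) = A[i, j] * B)."""
    return np.kron(np.asarray(A, dtype=float), np.asarray(B, dtype=float))
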