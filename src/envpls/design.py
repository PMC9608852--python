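"""Dummy design matrices and their relationship-matrix augmentation.

For an observed (environment, line) index the three incidence matrices are
``X_L`` (n x I, environments), ``X_g`` (n x J, lines) and ``X_gL``
(n x I*J, their interaction).  The PLS input matrix is the column-wise
concatenation of the augmented blocks ``X_L L_E``, ``X_g L_g`` and
``X_gL (L_E kron L_g)``, which have the same shapes as the raw incidences.

Package-wide convention: the interaction columns are environment-major —
column ``i * J + j`` corresponds to (environment i, line j) — matching the
block structure of ``L_E kron L_g``.  Interaction columns are kept for all
I*J combinations even under unbalanced data; only rows are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import KinshipRoot, kron

__all__ = ["ObservationIndex", "DesignBundle", "build_incidence", "build_augmented"]


@dataclass(frozen=True)
class ObservationIndex:
    """Ordered list of observed (environment, line) pairs.

    ``env_ids`` and ``line_ids`` fix the column order of the design matrices;
    every environment and line must be referenced by at least one row.
    """

    rows: tuple  # of (env_id, line_id)
    env_ids: tuple
    line_ids: tuple

    def __post_init__(self):
        rows = tuple((str(e), str(l)) for e, l in self.rows)
        env_ids = tuple(str(e) for e in self.env_ids)
        line_ids = tuple(str(l) for l in self.line_ids)
        if len(set(rows)) != len(rows):
            dupes = [r for r in set(rows) if rows.count(r) > 1]
            raise ValueError(f"duplicate (environment, line) pairs: {sorted(dupes)[:5]}")
        if len(set(env_ids)) != len(env_ids) or len(set(line_ids)) != len(line_ids):
            raise ValueError("environment and line ids must be unique")
        seen_env = {e for e, _ in rows}
        seen_line = {l for _, l in rows}
        if not seen_env.issuperset(env_ids) or not set(env_ids).issuperset(seen_env):
            missing = set(env_ids) - seen_env or seen_env - set(env_ids)
            raise ValueError(f"environments without observations or unknown: {sorted(missing)}")
        if seen_line != set(line_ids):
            missing = set(line_ids) ^ seen_line
            raise ValueError(f"lines without observations or unknown: {sorted(missing)}")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "env_ids", env_ids)
        object.__setattr__(self, "line_ids", line_ids)

    @classmethod
    def from_pairs(cls, pairs, env_ids=None, line_ids=None) -> "ObservationIndex":
        pairs = [(str(e), str(l)) for e, l in pairs]
        if env_ids is None:
            env_ids = list(dict.fromkeys(e for e, _ in pairs))
        if line_ids is None:
            line_ids = list(dict.fromkeys(l for _, l in pairs))
        return cls(rows=tuple(pairs), env_ids=tuple(env_ids), line_ids=tuple(line_ids))

    @classmethod
    def balanced(cls, env_ids, line_ids) -> "ObservationIndex":
        rows = [(e, l) for e in env_ids for l in line_ids]
        return cls(rows=tuple(rows), env_ids=tuple(env_ids), line_ids=tuple(line_ids))

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def I(self) -> int:  # noqa: E743 - I is the field's symbol for env count
        return len(self.env_ids)

    @property
    def J(self) -> int:
        return len(self.line_ids)

    def env_positions(self) -> np.ndarray:
        lut = {e: i for i, e in enumerate(self.env_ids)}
        return np.array([lut[e] for e, _ in self.rows], dtype=int)

    def line_positions(self) -> np.ndarray:
        lut = {l: j for j, l in enumerate(self.line_ids)}
        return np.array([lut[l] for _, l in self.rows], dtype=int)

    def subset(self, row_mask) -> "ObservationIndex":
        """Row subset keeping the full environment/line column spaces.

        Bypasses the every-entity-referenced check on purpose: the LOEO split
        must keep the held-out environment's column in the design.
        """
        rows = tuple(r for r, m in zip(self.rows, row_mask) if m)
        obj = object.__new__(ObservationIndex)
        object.__setattr__(obj, "rows", rows)
        object.__setattr__(obj, "env_ids", self.env_ids)
        object.__setattr__(obj, "line_ids", self.line_ids)
        return obj


@dataclass(frozen=True)
class DesignBundle:
    """Incidence matrices plus the augmented PLS input matrix."""

    X_L: np.ndarray = field(repr=False)
    X_g: np.ndarray = field(repr=False)
    X_gL: np.ndarray = field(repr=False)
    X_aug: np.ndarray = field(repr=False)
    predictor: str = "E+G+GE"

    @property
    def shape(self):
        return self.X_aug.shape


def build_incidence(index: ObservationIndex):
    """0/1 incidence matrices (X_L, X_g, X_gL) for the observed rows.

    Balanced shapes are JI x I, JI x J and JI x JI; under unbalanced data rows
    are dropped but all columns kept.  Each row of each matrix sums to 1.
    """
    n, I, J = index.n, index.I, index.J
    ei = index.env_positions()
    li = index.line_positions()
    X_L = np.zeros((n, I))
    X_g = np.zeros((n, J))
    X_gL = np.zeros((n, I * J))
    X_L[np.arange(n), ei] = 1.0
    X_g[np.arange(n), li] = 1.0
    X_gL[np.arange(n), ei * J + li] = 1.0
    return X_L, X_g, X_gL


def build_augmented(
    X_L,
    X_g,
    X_gL,
    L_E: KinshipRoot,
    L_g: KinshipRoot,
    predictor: str = "E+G+GE",
) -> DesignBundle:
    """Relationship-matrix-augmented PLS input matrix.

    ``X_aug = [X_L L_E | X_g L_g | X_gL (L_E kron L_g)]`` for predictor
    ``"E+G+GE"``, or the first two blocks only for ``"E+G"``.  Because the
    roots are square, every augmented block keeps its incidence shape.
    """
    if predictor not in ("E+G", "E+G+GE"):
        raise ValueError(f"unknown predictor {predictor!r}")
    LE = L_E.matrix if isinstance(L_E, KinshipRoot) else np.asarray(L_E, dtype=float)
    Lg = L_g.matrix if isinstance(L_g, KinshipRoot) else np.asarray(L_g, dtype=float)
    I = LE.shape[0]
    J = Lg.shape[0]
    if X_L.shape[1] != I:
        raise ValueError(f"X_L has {X_L.shape[1]} columns but L_E is {I}x{I}")
    if X_g.shape[1] != J:
        raise ValueError(f"X_g has {X_g.shape[1]} columns but L_g is {J}x{J}")
    blocks = [X_L @ LE, X_g @ Lg]
    if predictor == "E+G+GE":
        if X_gL.shape[1] != I * J:
            raise ValueError(
                f"X_gL has {X_gL.shape[1]} columns, expected I*J = {I * J}"
            )
        # Each row of X_gL selects one row of L_E kron L_g; build those rows
        # directly instead of forming the full I*J x I*J Kronecker product.
        cols = np.argmax(X_gL, axis=1)
        if np.array_equal(X_gL.sum(axis=1), np.ones(X_gL.shape[0])):
            ei, li = np.divmod(cols, J)
            ge_block = np.einsum("ni,nj->nij", LE[ei], Lg[li]).reshape(-1, I * J)
        else:  # non-incidence input: fall back to the literal product
            ge_block = X_gL @ kron(LE, Lg)
        blocks.append(ge_block)
    X_aug = np.hstack(blocks)
    return DesignBundle(X_L=X_L, X_g=X_g, X_gL=X_gL, X_aug=X_aug, predictor=predictor)
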