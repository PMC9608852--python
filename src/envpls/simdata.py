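"""Synthetic multi-environment trial generator.

Data are drawn from the same variance-component model the GBLUP benchmark
fits: y_ij = mu + L_i + g_j + gL_ij + e_ij with L ~ N(0, s2_E H),
g ~ N(0, s2_g G), gL ~ N(0, s2_gL (H kron G)) and i.i.d. residuals.  Markers
are independent per-locus Binomial(2, p_k) draws (no linkage or population
structure), environmental covariates are standard normal, and the G and H
used to draw the effects are the REALIZED relationship matrices computed from
those markers/covariates — so parameter-recovery experiments are internally
consistent.  Setting ``r = 0`` covariates gives H = identity, the
no-environmental-information regime.  A configurable fraction of (env, line)
combinations can be removed to emulate unbalanced trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ObservationIndex
from .io_qc import Dataset, MarkerMatrix, PhenoTable
from .kinship import Kinship, compute_G, compute_H, identity_H, matrix_sqrt

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate", "truth_nrmse_floor"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings for one synthetic trial.

    Variance components default to a GE-dominated trial of moderate size:
    line and environment main effects of one unit each, interaction variance
    of half a unit and unit residual noise, matching the generative model's
    reference parameterization.
    """

    J: int = 100            # lines
    I: int = 5              # environments
    p: int = 500            # markers
    r: int = 0              # environmental covariates; 0 => H = identity
    maf_range: tuple = (0.05, 0.95)  # allele-frequency range for marker draws
    var_env: float = 1.0    # sigma2_E
    var_g: float = 1.0      # sigma2_g
    var_ge: float = 0.5     # sigma2_gL
    var_resid: float = 1.0  # sigma2
    mu: float = 10.0        # grand mean, kept well away from zero so NRMSE is defined
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.J < 2 or self.I < 2:
            raise ValueError("need J >= 2 lines and I >= 2 environments")
        if self.p < 1:
            raise ValueError("need at least one marker")
        if self.r < 0:
            raise ValueError("covariate count must be >= 0")
        if min(self.var_env, self.var_g, self.var_ge, self.var_resid) < 0:
            raise ValueError("variance components must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo < hi < 1")


@dataclass(frozen=True)
class SimTruth:
    """The drawn effects and variance components behind a SimDataset."""

    mu: float
    env_effects: np.ndarray = field(repr=False)    # (I,)
    line_effects: np.ndarray = field(repr=False)   # (J,)
    ge_effects: np.ndarray = field(repr=False)     # (I*J,) environment-major
    residuals: np.ndarray = field(repr=False)      # aligned with pheno rows
    varcomps: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimDataset:
    """A synthetic trial plus its generating truth."""

    config: SimConfig
    markers: MarkerMatrix
    covariates: pd.DataFrame | None
    pheno: PhenoTable
    G: Kinship
    H: Kinship
    truth: SimTruth

    def observation_index(self) -> ObservationIndex:
        return self.pheno.observation_index(
            env_ids=self.H.ids, line_ids=self.G.ids)

    def as_dataset(self) -> Dataset:
        return Dataset(pheno=self.pheno, markers=self.markers,
                       covariates=self.covariates)

    def write(self, directory, prefix: str = "sim") -> dict:
        """Write the phenotype / marker / covariate tables (CSV) and a truth
        file; returns the path mapping.  These files round-trip through
        :func:`envpls.io_qc.read_dataset`."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["pheno"] = directory / f"{prefix}_pheno.csv"
        self.pheno.frame.to_csv(paths["pheno"], index=False)
        paths["markers"] = directory / f"{prefix}_markers.csv"
        mdf = self.markers.to_frame()
        mdf.insert(0, "line", mdf.index)
        mdf.to_csv(paths["markers"], index=False)
        if self.covariates is not None:
            paths["covariates"] = directory / f"{prefix}_covariates.csv"
            cdf = self.covariates.copy()
            cdf.insert(0, "env", cdf.index)
            cdf.to_csv(paths["covariates"], index=False)
        paths["truth"] = directory / f"{prefix}_truth.csv"
        idx = self.observation_index()
        tdf = pd.DataFrame({
            "env": [e for e, _ in idx.rows],
            "line": [l for _, l in idx.rows],
            "signal": self.signal(),
            "residual": self.truth.residuals,
        })
        tdf.to_csv(paths["truth"], index=False)
        return {k: str(v) for k, v in paths.items()}

    def signal(self) -> np.ndarray:
        """True noiseless value mu + L_i + g_j + gL_ij for each pheno row."""
        idx = self.observation_index()
        ei, li = idx.env_positions(), idx.line_positions()
        t = self.truth
        return (t.mu + t.env_effects[ei] + t.line_effects[li]
                + t.ge_effects[ei * idx.J + li])


def simulate(config: SimConfig) -> SimDataset:
    """Draw one synthetic multi-environment trial; reproducible from seed."""
    rng = np.random.default_rng(int(config.seed) % (2**31))
    I, J, p, r = config.I, config.J, config.p, config.r
    env_ids = tuple(f"E{i + 1}" for i in range(I))
    line_ids = tuple(f"L{j + 1}" for j in range(J))

    # markers: per-locus Binomial(2, p_k); redraw monomorphic columns so G exists
    freqs = rng.uniform(*config.maf_range, size=p)
    codes = rng.binomial(2, freqs, size=(J, p)).astype(float)
    for k in range(p):
        while codes[:, k].std() == 0.0:
            codes[:, k] = rng.binomial(2, freqs[k], size=J)
    markers = MarkerMatrix(line_ids=line_ids, marker_ids=tuple(f"M{k + 1}" for k in range(p)),
                           codes=codes)
    G = compute_G(markers)

    if r > 0:
        cov_values = rng.standard_normal((I, r))
        covariates = pd.DataFrame(cov_values, index=list(env_ids),
                                  columns=[f"EC{k + 1}" for k in range(r)])
        covariates.index.name = "env"
        H = compute_H(covariates)
    else:
        covariates = None
        H = identity_H(I, env_ids=env_ids)

    Lg = matrix_sqrt(G).matrix
    LE = matrix_sqrt(H).matrix
    env_eff = np.sqrt(config.var_env) * (LE @ rng.standard_normal(I))
    line_eff = np.sqrt(config.var_g) * (Lg @ rng.standard_normal(J))
    # (H kron G)^{1/2} z  ==  vec-free form L_E Z L_g with Z ~ N(0, I_{IxJ})
    Z = rng.standard_normal((I, J))
    ge_eff = np.sqrt(config.var_ge) * (LE @ Z @ Lg).reshape(-1)

    # observed (env, line) index, optionally unbalanced but never orphaning
    all_pairs = [(e, l) for e in env_ids for l in line_ids]
    n_keep = int(round((1.0 - config.missing_fraction) * I * J))
    for _attempt in range(1000):
        keep_pos = rng.choice(I * J, size=n_keep, replace=False)
        keep_pos.sort()
        kept = [all_pairs[k] for k in keep_pos]
        if ({e for e, _ in kept} == set(env_ids)
                and {l for _, l in kept} == set(line_ids)):
            break
    else:
        raise RuntimeError("could not draw an unbalanced index covering all "
                           "lines and environments; lower missing_fraction")
    idx = ObservationIndex(rows=tuple(kept), env_ids=env_ids, line_ids=line_ids)
    ei, li = idx.env_positions(), idx.line_positions()
    resid = np.sqrt(config.var_resid) * rng.standard_normal(idx.n)
    y = (config.mu + env_eff[ei] + line_eff[li] + ge_eff[ei * J + li] + resid)

    pheno = PhenoTable(frame=pd.DataFrame({
        "line": [l for _, l in idx.rows],
        "env": [e for e, _ in idx.rows],
        "y": y,
    }))
    truth = SimTruth(
        mu=config.mu, env_effects=env_eff, line_effects=line_eff,
        ge_effects=ge_eff, residuals=resid,
        varcomps={"env": config.var_env, "g": config.var_g,
                  "ge": config.var_ge, "resid": config.var_resid},
    )
    return SimDataset(config=config, markers=markers, covariates=covariates,
                      pheno=pheno, G=G, H=H, truth=truth)


def truth_nrmse_floor(dataset: SimDataset, rows: np.ndarray | None = None) -> float:
    """NRMSE of the true signal against y: the noise floor no predictor that
    knows the truth can beat (in expectation) on the same rows."""
    from .evaluation import nrmse

    y = dataset.pheno.response(dataset.pheno.traits[0])
    signal = dataset.signal()
    if rows is not None:
        y, signal = y[rows], signal[rows]
    if np.allclose(y, signal):
        return 0.0
    return nrmse(y, signal)
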