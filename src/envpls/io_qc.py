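"""Input tables, marker quality control, and dataset assembly.

Three delimited-text tables (comma or tab, autodetected) describe a
multi-environment trial:

* phenotypes — long format, columns ``line``, ``env`` and one column per trait;
* markers — first column the line ID, remaining columns 0/1/2 SNP codes,
  missing cells empty or ``NA``;
* environmental covariates (optional) — first column the environment ID,
  remaining columns real covariates.

Marker QC follows the usual pipeline: drop markers with too much missingness,
impute remaining gaps with the expected dosage ``2 * p_hat`` under the
observed allele frequency, and drop markers whose minor allele frequency
(computed from observed, pre-imputation calls) is below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ObservationIndex

logger = logging.getLogger(__name__)

__all__ = ["MarkerMatrix", "PhenoTable", "Dataset", "read_dataset",
           "qc_markers", "read_markers", "read_pheno", "read_covariates"]


@dataclass(frozen=True)
class MarkerMatrix:
    """Lines x markers SNP dosages with a missingness mask (NaN = missing)."""

    line_ids: tuple
    marker_ids: tuple
    codes: np.ndarray = field(repr=False)  # float array, NaN for missing

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=float)
        if codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match id lengths")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line IDs in marker matrix")
        obs = codes[~np.isnan(codes)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("marker codes must lie in [0, 2]")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "line_ids", tuple(str(l) for l in self.line_ids))
        object.__setattr__(self, "marker_ids", tuple(str(m) for m in self.marker_ids))

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=list(self.line_ids),
                            columns=list(self.marker_ids))


@dataclass(frozen=True)
class PhenoTable:
    """Long-format phenotype records: one row per (line, environment)."""

    frame: pd.DataFrame = field(repr=False)  # columns: line, env, <traits...>

    def __post_init__(self):
        df = self.frame
        for col in ("line", "env"):
            if col not in df.columns:
                raise ValueError(f"phenotype table must have a '{col}' column")
        traits = [c for c in df.columns if c not in ("line", "env")]
        if not traits:
            raise ValueError("phenotype table has no trait columns")
        df = df.copy()
        df["line"] = df["line"].astype(str)
        df["env"] = df["env"].astype(str)
        dup = df.duplicated(subset=["line", "env"])
        if dup.any():
            rows = df.loc[dup, ["line", "env"]].head(5).to_records(index=False)
            raise ValueError(f"duplicate (line, env) phenotype rows: {list(rows)}")
        for t in traits:
            if not pd.api.types.is_numeric_dtype(df[t]):
                bad = df.index[pd.to_numeric(df[t], errors="coerce").isna()][:5]
                raise ValueError(f"non-numeric values in trait '{t}' at rows {list(bad)}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def traits(self) -> tuple:
        return tuple(c for c in self.frame.columns if c not in ("line", "env"))

    def observation_index(self, env_ids=None, line_ids=None) -> ObservationIndex:
        pairs = list(zip(self.frame["env"], self.frame["line"]))
        return ObservationIndex.from_pairs(pairs, env_ids=env_ids, line_ids=line_ids)

    def response(self, trait: str) -> np.ndarray:
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}; available: {self.traits}")
        return self.frame[trait].to_numpy(dtype=float)


@dataclass(frozen=True)
class Dataset:
    """Assembled trial: phenotypes, QC-ready markers, optional covariates."""

    pheno: PhenoTable
    markers: MarkerMatrix
    covariates: pd.DataFrame | None = None  # index: env IDs

    @property
    def env_ids(self) -> tuple:
        return tuple(dict.fromkeys(self.pheno.frame["env"]))

    @property
    def line_ids(self) -> tuple:
        return tuple(self.markers.line_ids)

    def observation_index(self) -> ObservationIndex:
        used = set(self.pheno.frame["line"])
        lines = [l for l in self.markers.line_ids if l in used]
        return self.pheno.observation_index(env_ids=self.env_ids, line_ids=lines)


def _read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    df = pd.read_csv(path, sep=None, engine="python",
                     na_values=["NA", "na", ""], keep_default_na=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a delimited table with >= 2 columns")
    return df


def read_markers(path) -> MarkerMatrix:
    df = _read_table(path)
    line_col = df.columns[0]
    lines = df[line_col].astype(str)
    codes = df.drop(columns=[line_col]).apply(pd.to_numeric, errors="coerce")
    raw = df.drop(columns=[line_col])
    bad = codes.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric marker cell at data row {r + 1}, "
            f"column '{codes.columns[c]}'"
        )
    return MarkerMatrix(line_ids=tuple(lines), marker_ids=tuple(codes.columns),
                        codes=codes.to_numpy(dtype=float))


def read_pheno(path) -> PhenoTable:
    df = _read_table(path)
    cols = {c.lower(): c for c in df.columns}
    ren = {}
    for want in ("line", "env"):
        if want not in df.columns:
            if want in cols:
                ren[cols[want]] = want
            else:
                raise ValueError(f"{path}: phenotype table needs a '{want}' column")
    return PhenoTable(frame=df.rename(columns=ren))


def read_covariates(path) -> pd.DataFrame:
    df = _read_table(path)
    env_col = df.columns[0]
    out = df.set_index(df[env_col].astype(str)).drop(columns=[env_col])
    out = out.apply(pd.to_numeric, errors="raise")
    out.index.name = "env"
    return out


def read_dataset(pheno_path, markers_path, covariates_path=None) -> Dataset:
    """Read and cross-validate the input tables into a Dataset.

    Lines phenotyped but absent from the marker table are an error;
    covariate environments absent from the phenotypes are dropped with a
    warning; phenotype environments without covariates (when covariates are
    supplied) are an error, since H could not cover them.
    """
    pheno = read_pheno(pheno_path)
    markers = read_markers(markers_path)
    missing = sorted(set(pheno.frame["line"]) - set(markers.line_ids))
    if missing:
        raise ValueError(
            f"lines phenotyped but missing from markers: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    covariates = None
    if covariates_path is not None:
        cov = read_covariates(covariates_path)
        pheno_envs = set(pheno.frame["env"])
        extra = sorted(set(cov.index) - pheno_envs)
        if extra:
            logger.warning("dropping covariate rows for unphenotyped environments: %s",
                           extra)
            cov = cov.drop(index=extra)
        lacking = sorted(pheno_envs - set(cov.index))
        if lacking:
            raise ValueError(f"environments without covariates: {lacking}")
        # order covariate rows by first appearance in the phenotype table
        order = [e for e in dict.fromkeys(pheno.frame["env"])]
        covariates = cov.loc[order]
    return Dataset(pheno=pheno, markers=markers, covariates=covariates)


def qc_markers(markers: MarkerMatrix, maf_min: float = 0.05,
               max_missing: float = 0.15) -> MarkerMatrix:
    """Marker QC: missingness filter, frequency imputation, MAF filter.

    Order of operations:

    1. drop markers whose missing fraction exceeds ``max_missing``;
    2. impute remaining missing cells with the marker's expected dosage
       ``2 * p_hat``, where ``p_hat`` is the observed allele frequency;
    3. drop markers with MAF < ``maf_min``, MAF computed from the observed
       (pre-imputation) calls.

    Imputation never alters observed cells; imputed dosages stay real-valued.
    """
    codes = markers.codes
    n, p = codes.shape
    miss_frac = np.isnan(codes).mean(axis=0)
    keep1 = miss_frac <= max_missing
    logger.info("QC: dropped %d/%d markers with missingness > %.0f%%",
                int((~keep1).sum()), p, 100 * max_missing)
    codes = codes[:, keep1]
    ids = np.array(markers.marker_ids)[keep1]

    n_obs = (~np.isnan(codes)).sum(axis=0)
    if codes.shape[1] and np.any(n_obs == 0):
        # fully-missing markers that slipped past max_missing=1
        keep0 = n_obs > 0
        codes, ids, n_obs = codes[:, keep0], ids[keep0], n_obs[keep0]
    with np.errstate(invalid="ignore"):
        p_hat = np.nansum(codes, axis=0) / (2.0 * n_obs)
    imputed = np.where(np.isnan(codes), 2.0 * p_hat, codes)

    maf = np.minimum(p_hat, 1.0 - p_hat)
    keep2 = maf >= maf_min
    logger.info("QC: dropped %d/%d markers with MAF < %.3f",
                int((~keep2).sum()), len(ids), maf_min)
    imputed = imputed[:, keep2]
    ids = ids[keep2]
    if imputed.shape[1] == 0:
        raise ValueError("QC removed all markers")
    return MarkerMatrix(line_ids=markers.line_ids, marker_ids=tuple(ids),
                        codes=imputed)
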