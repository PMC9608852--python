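"""Leave-one-environment-out evaluation and accuracy metrics.

Each environment in turn is the entire test set: models are trained on the
remaining environments, the PLS latent-variable count is tuned by an inner
k-fold cross-validation on the training rows only, and the whole held-out
environment is predicted.  Accuracy is the normalized root mean squared
error NRMSE = RMSE / mean(y_obs); methods are compared through the relative
efficiency RE = NRMSE_GBLUP / NRMSE_PLS (values above 1 favor PLS).

"Global" NRMSE pools all held-out predictions into one NRMSE; the mean of
the per-environment NRMSEs is also reported (as "GlobalMean") since either
reading of an across-environment summary is plausible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ObservationIndex, build_augmented, build_incidence
from .gblup import GBLUP
from .kinship import compute_G, compute_H, identity_H, matrix_sqrt
from .pls import PLS, select_ncomp

logger = logging.getLogger(__name__)

__all__ = ["nrmse", "relative_efficiency", "FoldResult", "LOEOReport", "loeo_run"]


def nrmse(y_obs, y_pred) -> float:
    """Normalized root mean squared error: sqrt(mean((y - yhat)^2)) / mean(y)."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0 or y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must be equal-length, nonempty vectors")
    ybar = y_obs.mean()
    if abs(ybar) <= 1e-12:
        raise ValueError("NRMSE undefined for mean-zero response")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)) / ybar)


def relative_efficiency(nrmse_gblup: float, nrmse_pls: float) -> float:
    """RE = NRMSE_GBLUP / NRMSE_PLS; > 1 means PLS is the more accurate method."""
    if nrmse_gblup <= 0 or nrmse_pls <= 0:
        raise ValueError("relative efficiency needs strictly positive NRMSE values")
    re = float(nrmse_gblup / nrmse_pls)
    if re < 1:
        logger.info("RE_NRMSE = %.4f < 1: GBLUP superior", re)
    return re


def _derive_seed(master: int, *tokens) -> int:
    """Deterministic sub-seed from the master seed and string tokens."""
    h = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return (int(master) * 1_000_003 + h) % (2**31)


@dataclass(frozen=True)
class FoldResult:
    """Held-out predictions for one environment under one method."""

    env_id: str
    method: str
    trait: str
    y_obs: np.ndarray = field(repr=False)
    y_pred: np.ndarray = field(repr=False)
    nrmse: float = float("nan")
    details: dict = field(default_factory=dict)


@dataclass
class LOEOReport:
    """Tidy per-environment and global accuracy summary."""

    trait: str
    predictor: str
    fold_results: list
    frame: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def global_nrmse(self, method: str) -> float:
        sel = self.frame[(self.frame["method"] == method)
                         & (self.frame["environment"] == "Global")]
        if sel.empty:
            raise KeyError(f"no Global entry for method {method!r}")
        return float(sel["nrmse"].iloc[0])

    def summary(self) -> str:
        wide = self.frame.pivot_table(index="environment", columns="method",
                                      values="nrmse", sort=False)
        lines = [
            f"Leave-one-environment-out report  (trait={self.trait}, "
            f"predictor={self.predictor})",
            "=" * 64,
            wide.round(4).to_string(),
        ]
        re_rows = self.frame.dropna(subset=["re_nrmse"])
        if not re_rows.empty:
            re_tab = re_rows.pivot_table(index="environment", values="re_nrmse",
                                         sort=False)
            lines += ["-" * 64,
                      "Relative efficiency NRMSE_GBLUP / NRMSE_PLS (>1 favors PLS):",
                      re_tab.round(4).to_string()]
        return "\n".join(lines)


def _assemble(dataset, use_env_covariates: bool):
    """Common preparation: observation index, y per trait, G, H and roots."""
    pheno = dataset.pheno
    markers = dataset.markers
    if markers.has_missing:
        raise ValueError("markers contain missing codes; run qc_markers first")
    used_lines = set(pheno.frame["line"])
    lacking = sorted(used_lines - set(markers.line_ids))
    if lacking:
        raise ValueError(f"lines phenotyped but missing from markers: {lacking[:10]}")
    line_ids = [l for l in markers.line_ids if l in used_lines]
    env_ids = list(dict.fromkeys(pheno.frame["env"]))
    keep = [markers.line_ids.index(l) for l in line_ids]
    G = compute_G(markers.codes[keep], line_ids=line_ids)
    cov = getattr(dataset, "covariates", None)
    if use_env_covariates and cov is not None:
        H = compute_H(cov.loc[env_ids])
    else:
        H = identity_H(len(env_ids), env_ids=env_ids)
    index = pheno.observation_index(env_ids=tuple(env_ids), line_ids=tuple(line_ids))
    return index, G, H


def loeo_run(dataset, methods=("PLS", "GBLUP"), predictor: str = "E+G+GE",
             trait: str | None = None, inner_folds: int = 5, seed: int = 0,
             use_env_covariates: bool = True, a_max: int | None = None,
             scale: bool = False, chain: tuple = (12_000, 2_000, 5),
             prior_df: float = 5.0) -> LOEOReport:
    """Run the leave-one-environment-out benchmark on one trait.

    Parameters
    ----------
    dataset : Dataset or SimDataset
        Assembled trial with complete (QC'd) markers.
    methods : sequence of {"PLS", "GBLUP", "TrainMean"}
        Models to evaluate; "TrainMean" predicts every held-out value with the
        training-set mean (a floor any informative method should beat).
    predictor : {"E+G", "E+G+GE"}
        Whether the PLS design and the GBLUP model include the interaction.
    inner_folds : int
        Folds of the nested CV used to pick the PLS component count.
    chain : (iterations, burnin, thin)
        Gibbs sampler settings for GBLUP.
    seed : int
        Master seed; per-environment sub-seeds are derived deterministically.

    Returns a :class:`LOEOReport` with one row per (environment, method) plus
    "Global" (pooled held-out NRMSE), "GlobalMean" (mean of per-environment
    NRMSEs) and relative efficiencies where both PLS and GBLUP were run.
    """
    methods = tuple(methods)
    bad = set(methods) - {"PLS", "GBLUP", "TrainMean"}
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    if hasattr(dataset, "as_dataset"):  # SimDataset
        dataset = dataset.as_dataset()
    pheno = dataset.pheno
    if trait is None:
        trait = pheno.traits[0]
    y_all = pheno.response(trait)
    index, G, H = _assemble(dataset, use_env_covariates)
    if index.I < 2:
        raise ValueError("leave-one-environment-out needs at least 2 environments")
    include_ge = predictor == "E+G+GE"
    if predictor not in ("E+G", "E+G+GE"):
        raise ValueError(f"unknown predictor {predictor!r}")

    X_aug = None
    if "PLS" in methods:
        L_E, L_g = matrix_sqrt(H), matrix_sqrt(G)
        X_L, X_g, X_gL = build_incidence(index)
        X_aug = build_augmented(X_L, X_g, X_gL, L_E, L_g, predictor=predictor).X_aug

    ei = index.env_positions()
    fold_results: list[FoldResult] = []
    pooled: dict[str, list] = {m: [] for m in methods}
    pooled_obs: list = []

    for e_pos, env in enumerate(index.env_ids):
        test_mask = ei == e_pos
        train_mask = ~test_mask
        if train_mask.sum() < 2:
            raise ValueError(f"removing environment {env!r} leaves too few rows")
        train_lines = {l for (ev, l), m in zip(index.rows, train_mask) if m}
        test_lines = {l for (ev, l), m in zip(index.rows, test_mask) if m}
        if not train_lines:
            raise ValueError(
                f"environment {env!r} removal leaves no training lines in G")
        new_lines = sorted(test_lines - train_lines)
        if new_lines:
            logger.info("fold %s: %d line(s) appear only in the held-out "
                        "environment", env, len(new_lines))
        y_train, y_test = y_all[train_mask], y_all[test_mask]
        pooled_obs.append(y_test)

        if "PLS" in methods:
            fold_seed = _derive_seed(seed, env, "pls-inner-cv")
            a_star, curve = select_ncomp(X_aug[train_mask], y_train,
                                         k_folds=inner_folds, a_max=a_max,
                                         seed=fold_seed, scale=scale)
            res = PLS(y_train, X_aug[train_mask], ncomp=a_star, scale=scale).fit()
            y_pred = res.predict(X_aug[test_mask])
            fold_results.append(FoldResult(
                env_id=env, method="PLS", trait=trait, y_obs=y_test,
                y_pred=y_pred, nrmse=nrmse(y_test, y_pred),
                details={"a_star": a_star, "rmsep_curve": curve,
                         "new_lines": len(new_lines)}))
            pooled["PLS"].append(y_pred)

        if "GBLUP" in methods:
            iterations, burnin, thin = chain
            idx_train = index.subset(train_mask)
            idx_test = index.subset(test_mask)
            model = GBLUP(y_train, idx_train, G, H, include_ge=include_ge)
            post = model.fit(iterations=iterations, burnin=burnin, thin=thin,
                             seed=_derive_seed(seed, env, "gblup-chain"),
                             prior_df=prior_df)
            y_pred = post.predict(idx_test)
            fold_results.append(FoldResult(
                env_id=env, method="GBLUP", trait=trait, y_obs=y_test,
                y_pred=y_pred, nrmse=nrmse(y_test, y_pred),
                details={"varcomps": post.varcomp_summaries,
                         "new_lines": len(new_lines)}))
            pooled["GBLUP"].append(y_pred)

        if "TrainMean" in methods:
            y_pred = np.full(y_test.shape, y_train.mean())
            fold_results.append(FoldResult(
                env_id=env, method="TrainMean", trait=trait, y_obs=y_test,
                y_pred=y_pred, nrmse=nrmse(y_test, y_pred), details={}))
            pooled["TrainMean"].append(y_pred)

    rows = []
    per_env_nrmse: dict[str, dict[str, float]] = {m: {} for m in methods}
    for fr in fold_results:
        per_env_nrmse[fr.method][fr.env_id] = fr.nrmse
        rows.append({"trait": trait, "predictor": predictor,
                     "environment": fr.env_id, "method": fr.method,
                     "n_test": len(fr.y_obs), "nrmse": fr.nrmse})
    y_obs_pooled = np.concatenate(pooled_obs)
    for m in methods:
        pred_pooled = np.concatenate(pooled[m])
        g = nrmse(y_obs_pooled, pred_pooled)
        per_env_nrmse[m]["Global"] = g
        rows.append({"trait": trait, "predictor": predictor,
                     "environment": "Global", "method": m,
                     "n_test": len(y_obs_pooled), "nrmse": g})
        env_vals = [per_env_nrmse[m][e] for e in index.env_ids]
        gm = float(np.mean(env_vals))
        per_env_nrmse[m]["GlobalMean"] = gm
        rows.append({"trait": trait, "predictor": predictor,
                     "environment": "GlobalMean", "method": m,
                     "n_test": len(y_obs_pooled), "nrmse": gm})
    frame = pd.DataFrame(rows)
    if "PLS" in methods and "GBLUP" in methods:
        frame["re_nrmse"] = [
            relative_efficiency(per_env_nrmse["GBLUP"][r.environment],
                                per_env_nrmse["PLS"][r.environment])
            if r.method == "PLS" else np.nan
            for r in frame.itertuples()
        ]
    else:
        frame["re_nrmse"] = np.nan
        logger.warning("relative efficiency not computed: needs both PLS and GBLUP")
    return LOEOReport(trait=trait, predictor=predictor,
                      fold_results=fold_results, frame=frame)
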