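"""Covariate-adjusted regression of ROI volume on a genetic risk score.

For each (ROI, training set, threshold) cell: ordinary least squares of the
z-scored volume on covariates plus the z-scored score, reporting the
standardized coefficient, its two-sided nominal P, the increment in variance
explained over the covariates-only model, and (optionally) an empirical P from
permutations of the score vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FitError, ValidationError
from .io import PhenotypeTable
from .prs import ScoreProfile

__all__ = [
    "CovariatePolicy",
    "AssociationResult",
    "fit_increment",
    "permutation_p",
    "run_table",
]


@dataclass(frozen=True)
class CovariatePolicy:
    """Which covariates enter each ROI's model.

    ``always`` applies to every ROI; ``age_rois`` lists the ROIs whose model
    additionally includes age (by default only the lateral ventricles, the one
    structure whose volume tracks age in the target cohort).
    """

    always: tuple[str, ...] = ("sex", "icv")
    age_rois: tuple[str, ...] = ("lateral_ventricles",)

    def covariates_for(self, roi: str) -> list[str]:
        cols = list(self.always)
        if roi in self.age_rois:
            cols.append("age")
        return cols


@dataclass
class AssociationResult:
    roi: str
    training_set: str
    p_t: float
    beta: float
    p_nominal: float
    delta_r2: float
    n_used: int
    p_perm: float | None = None

    def as_dict(self) -> dict:
        return {
            "roi": self.roi,
            "training_set": self.training_set,
            "p_t": self.p_t,
            "beta": self.beta,
            "p_nominal": self.p_nominal,
            "delta_r2": self.delta_r2,
            "p_perm": self.p_perm,
            "n_used": self.n_used,
        }


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise FitError("zero variance in a variable to be standardized")
    return (v - v.mean()) / sd


def _complete_cases(y, g, X):
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    Xm, names = _as_matrix(X)
    if Xm.size == 0:
        Xm = np.empty((len(y), 0))
    if not (len(y) == len(g) == Xm.shape[0]):
        raise ValidationError("y, g and X must have equal length")
    ok = np.isfinite(y) & np.isfinite(g)
    if Xm.shape[1]:
        ok &= np.isfinite(Xm).all(axis=1)
    return y[ok], g[ok], Xm[ok], names


def fit_increment(y, g, X=None) -> dict:
    """OLS of z-scored y on [covariates, z-scored g], complete cases only.

    Returns ``{"beta", "p_nominal", "delta_r2", "n_used"}`` where beta is the
    coefficient of g, p_nominal its two-sided t-test P, and delta_r2 the R2 of
    the full model minus the R2 of the covariates-only model fit on the same
    samples.  Covariates enter raw (plus an intercept).
    """
    y, g, Xm, names = _complete_cases(y, g, X)
    n = len(y)
    k = Xm.shape[1]
    if n <= k + 3:
        raise FitError(f"too few complete cases (n={n}) for {k} covariates")
    yz, gz = _zscore(y), _zscore(g)

    ones = np.ones((n, 1))
    cov_design = np.hstack([ones, Xm])
    full_design = np.hstack([cov_design, gz[:, None]])
    if np.linalg.matrix_rank(full_design) < full_design.shape[1]:
        bad = _collinear_columns(full_design, ["intercept", *names, "g"])
        raise FitError(f"rank-deficient design; collinear columns: {bad}")

    beta_full, rss_full = _ols(full_design, yz)
    _, rss_cov = _ols(cov_design, yz)
    tss = float(yz @ yz)  # yz has mean 0
    r2_full = 1.0 - rss_full / tss
    r2_cov = 1.0 - rss_cov / tss
    delta_r2 = max(r2_full - r2_cov, 0.0)

    df = n - full_design.shape[1]
    sigma2 = rss_full / df
    xtx_inv = np.linalg.inv(full_design.T @ full_design)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    b = float(beta_full[-1])
    if se == 0:
        p = 0.0 if b != 0 else 1.0
    else:
        p = float(2.0 * stats.t.sf(abs(b) / se, df))
    return {"beta": b, "p_nominal": p, "delta_r2": float(delta_r2), "n_used": n}


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return [names[i] for i in np.nonzero(diag < tol)[0]]


def permutation_p(
    y,
    g,
    X=None,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    method: str = "permute-score",
    estimator: str = "plain",
) -> float:
    """Empirical P: fraction of permutations with nominal p* below the observed p.

    ``method="permute-score"`` (default) permutes g across samples, keeping the
    (y, X) rows paired; ``method="freedman-lane"`` permutes the covariate
    residuals of y instead.  ``estimator="plain"`` returns k / n_perm (can be
    exactly 0); ``estimator="add-one"`` returns (k + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if method not in ("permute-score", "freedman-lane"):
        raise ValueError(f"unknown permutation method {method!r}")
    if estimator not in ("plain", "add-one"):
        raise ValueError(f"unknown estimator {estimator!r}")
    observed = fit_increment(y, g, X)
    p_obs = observed["p_nominal"]

    y, g, Xm, _ = _complete_cases(y, g, X)
    n = len(y)
    yz, gz = _zscore(y), _zscore(g)
    design = np.hstack([np.ones((n, 1)), Xm])
    q, _ = np.linalg.qr(design)
    ry = yz - q @ (q.T @ yz)
    df = n - design.shape[1] - 1

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k_below = 0
    chunk = max(1, min(n_perm, int(2e7) // max(n, 1)))
    done = 0
    ry_norm = np.sqrt(ry @ ry)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)  # b independent permutations
        if method == "permute-score":
            G = gz[idx].T  # n x b
            RG = G - q @ (q.T @ G)
            num = ry @ RG
            den = ry_norm * np.sqrt((RG * RG).sum(axis=0))
        else:  # freedman-lane: permute residualized y, test against g
            rg = gz - q @ (q.T @ gz)
            Y = ry[idx].T
            RY = Y - q @ (q.T @ Y)
            num = rg @ RY
            den = np.sqrt(rg @ rg) * np.sqrt((RY * RY).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / den, 0.0)
            r = np.clip(r, -1.0, 1.0)
            tstat = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
        p_star = 2.0 * stats.t.sf(np.abs(tstat), df)
        k_below += int((p_star < p_obs).sum())
        done += b
    if estimator == "plain":
        return k_below / n_perm
    return (k_below + 1) / (n_perm + 1)


def run_table(
    pheno: PhenotypeTable,
    scores: Mapping[str, ScoreProfile],
    policy: CovariatePolicy | None = None,
    rois: Sequence[str] | None = None,
    n_perm: int = 10000,
    perm_policy: str = "significant",
    alpha: float = 0.05,
    seed: int | None = None,
    perm_method: str = "permute-score",
    perm_estimator: str = "plain",
) -> list[AssociationResult]:
    """One association per (training set, threshold, ROI).

    ``perm_policy`` controls which cells get a permutation P: "significant"
    (default; only cells with nominal p < alpha, mirroring post-hoc
    correction), "all", or "none".  Per-cell permutation streams are spawned
    deterministically from ``seed`` so results do not depend on evaluation
    order.  Results are ordered training set -> threshold -> ROI.
    """
    policy = policy or CovariatePolicy()
    rois = list(rois) if rois is not None else list(pheno.rois)
    if perm_policy not in ("significant", "all", "none"):
        raise ValueError(f"unknown perm_policy {perm_policy!r}")
    for roi in rois:
        if roi not in pheno.table.columns:
            raise ValidationError(f"ROI column {roi!r} absent from phenotype table")
        if pheno.table[roi].isna().all():
            raise ValidationError(f"ROI {roi!r} has no observed volumes")

    results: list[AssociationResult] = []
    cells = [
        (ts, thr, roi)
        for ts, sp in scores.items()
        for thr in sp.thresholds
        for roi in rois
    ]
    child_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    for (ts, thr, roi), child in zip(cells, child_seeds):
        sp = scores[ts]
        common = pheno.table.index.intersection(sp.scores.index)
        if len(common) == 0:
            raise ValidationError(f"no shared samples between phenotypes and scores ({ts})")
        sub = pheno.table.loc[common]
        y = sub[roi].to_numpy(float)
        g = sp.scores.loc[common, thr].to_numpy(float)
        X = sub[policy.covariates_for(roi)]
        fit = fit_increment(y, g, X)
        p_perm = None
        if perm_policy == "all" or (
            perm_policy == "significant" and fit["p_nominal"] < alpha
        ):
            p_perm = permutation_p(
                y, g, X,
                n_perm=n_perm,
                seed=np.random.default_rng(child),
                method=perm_method,
                estimator=perm_estimator,
            )
        results.append(
            AssociationResult(
                roi=roi,
                training_set=ts,
                p_t=float(thr),
                beta=fit["beta"],
                p_nominal=fit["p_nominal"],
                delta_r2=fit["delta_r2"],
                n_used=fit["n_used"],
                p_perm=p_perm,
            )
        )
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Long-format DataFrame of association results."""
    return pd.DataFrame([r.as_dict() for r in results])
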