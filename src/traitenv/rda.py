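"""Redundancy analysis (constrained ordination) with VIF-based
collinearity pruning of the predictor set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["vif", "vif_prune", "VifReport", "RdaResult", "fit_rda"]


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1 / (1 - R2_j) per predictor.

    R2_j comes from an OLS regression (with intercept) of predictor j on
    all other predictors.  Perfectly collinear predictors get ``inf``.
    """
    cols = list(X.columns)
    M = X.to_numpy(dtype=float)
    n, p = M.shape
    out = {}
    for j, col in enumerate(cols):
        y = M[:, j]
        others = np.delete(M, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = np.sum((y - y.mean()) ** 2)
        if sst == 0:
            out[col] = np.nan
            continue
        r2 = 1.0 - np.sum(resid**2) / sst
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class VifReport:
    """Pruning trail: per-predictor final (or at-removal) VIF."""

    table: pd.DataFrame      # predictor, vif, removed, removal_order
    max_vif: float           # max VIF among surviving predictors
    target_met: bool


def vif_prune(
    X: pd.DataFrame,
    exclude_above: float = 20.0,
    target_max: float = 10.0,
) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop the highest-VIF predictor while any VIF exceeds
    ``exclude_above``; report whether the surviving set met ``target_max``."""
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more rows than predictors (n={X.shape[0]}, p={X.shape[1]})"
        )
    work = X.copy()
    removed: list[tuple[str, float, int]] = []
    order = 0
    while work.shape[1] > 1:
        v = vif(work)
        worst = v.idxmax()
        if not np.isfinite(v[worst]) or v[worst] > exclude_above:
            order += 1
            removed.append((worst, float(v[worst]), order))
            work = work.drop(columns=[worst])
        else:
            break
    final = vif(work) if work.shape[1] > 1 else pd.Series(1.0, index=work.columns)
    rows = [
        {"predictor": c, "vif": float(final[c]), "removed": False, "removal_order": 0}
        for c in work.columns
    ]
    rows += [
        {"predictor": c, "vif": v, "removed": True, "removal_order": o}
        for c, v, o in removed
    ]
    max_vif = float(final.max()) if len(final) else float("nan")
    report = VifReport(
        table=pd.DataFrame(rows),
        max_vif=max_vif,
        target_met=bool(max_vif <= target_max),
    )
    return work, report


@dataclass
class RdaResult:
    """Constrained-ordination output.

    ``variance_fraction_total`` uses the trace of the response covariance
    as denominator; ``variance_fraction_constrained`` uses the summed
    constrained eigenvalues.  Both are reported because published
    percentages often leave the denominator implicit.
    """

    eigenvalues: np.ndarray
    trait_scores: pd.DataFrame        # response loadings (unit eigenvectors)
    trait_scores_scaled: pd.DataFrame  # scaled by sqrt(eigenvalue)
    predictor_scores: pd.DataFrame    # correlation of predictors with axes
    site_scores: pd.DataFrame         # fitted-value projections
    variance_fraction_total: np.ndarray
    variance_fraction_constrained: np.ndarray
    total_variance: float
    constrained_variance: float


def fit_rda(Y: pd.DataFrame, X: pd.DataFrame) -> RdaResult:
    """RDA: eigen-analysis of fitted values from multivariate OLS of Y on X.

    ``Y`` should hold normalized (log-transformed, standardized) traits
    and ``X`` scaled, VIF-pruned predictors.  Axes are oriented so each
    axis's largest-magnitude predictor score is positive.
    """
    Yv = Y.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    if not (np.isfinite(Yv).all() and np.isfinite(Xv).all()):
        raise ValueError("missing/non-finite values in Y or X")
    n = Yv.shape[0]
    if Xv.shape[0] != n:
        raise ValueError("Y and X must have matching rows")
    Yc = Yv - Yv.mean(axis=0)
    Xc = Xv - Xv.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError(
            "predictor matrix is rank deficient; prune collinear "
            "predictors first (see vif_prune)"
        )
    B, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    Fhat = Xc @ B
    U, s, Vt = np.linalg.svd(Fhat / np.sqrt(n - 1), full_matrices=False)
    eig = s**2
    k = min(Xc.shape[1], Yc.shape[1], n - 1)
    keep = np.flatnonzero(eig > eig[0] * 1e-12)[: k] if eig.size else np.array([], int)
    eig = eig[keep]
    V = Vt.T[:, keep]
    sites = Fhat @ V                      # site scores on constrained axes
    # predictor scores: correlation of each predictor with each axis
    site_sd = sites.std(axis=0, ddof=1)
    site_sd[site_sd == 0] = 1.0
    x_sd = Xc.std(axis=0, ddof=1)
    x_sd[x_sd == 0] = 1.0
    pred_scores = (Xc / x_sd).T @ (sites / site_sd) / (n - 1)

    flip = np.sign(
        pred_scores[np.argmax(np.abs(pred_scores), axis=0), np.arange(len(keep))]
    )
    flip[flip == 0] = 1.0
    V = V * flip
    sites = sites * flip
    pred_scores = pred_scores * flip

    axis_names = [f"RDA{i + 1}" for i in range(len(keep))]
    total_var = float(np.sum(Yc.var(axis=0, ddof=1)))
    constrained_var = float(eig.sum())
    return RdaResult(
        eigenvalues=eig,
        trait_scores=pd.DataFrame(V, index=Y.columns, columns=axis_names),
        trait_scores_scaled=pd.DataFrame(
            V * np.sqrt(eig), index=Y.columns, columns=axis_names
        ),
        predictor_scores=pd.DataFrame(
            pred_scores, index=X.columns, columns=axis_names
        ),
        site_scores=pd.DataFrame(sites, index=Y.index, columns=axis_names),
        variance_fraction_total=eig / total_var,
        variance_fraction_constrained=eig / constrained_var,
        total_variance=total_var,
        constrained_variance=constrained_var,
    )
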