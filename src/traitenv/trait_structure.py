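"""Trait covariation structure: absolute-correlation heatmap input,
complete-linkage trait clustering, correlation-matrix PCA and
latitudinal-gradient regressions of component scores."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

__all__ = [
    "correlation_matrix",
    "TraitClusterTree",
    "cluster_traits",
    "PcaResult",
    "pca_traits",
    "significant_axes",
    "LatitudeFit",
    "latitude_fit",
]


def _transform_traits(
    traits: pd.DataFrame, log_scale: bool, signed_traits: Sequence[str]
) -> pd.DataFrame:
    """Natural-log transform positive traits; signed traits stay linear."""
    out = traits.copy()
    if log_scale:
        signed = set(signed_traits)
        for c in traits.columns:
            if c in signed:
                continue
            vals = out[c].to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError(
                    f"trait '{c}' has non-positive values and cannot be "
                    "log-transformed; declare it in signed_traits"
                )
            out[c] = np.log(vals)
    return out


def correlation_matrix(
    traits: pd.DataFrame,
    log_scale: bool = True,
    signed_traits: Sequence[str] = (),
) -> pd.DataFrame:
    """Absolute pairwise Pearson correlations (pairwise-complete).

    Positive traits are natural-log transformed first by default.
    Requires >= 3 complete pairs for every trait pair and non-constant
    traits.
    """
    tr = _transform_traits(traits, log_scale, signed_traits)
    for c in tr.columns:
        x = tr[c].dropna()
        if x.nunique() <= 1:
            raise ValueError(f"trait '{c}' has zero variance")
    corr = tr.corr(method="pearson", min_periods=3)
    if corr.isna().any().any():
        i, j = np.argwhere(corr.isna().to_numpy())[0]
        raise ValueError(
            f"fewer than 3 complete pairs for traits "
            f"'{corr.index[i]}' and '{corr.columns[j]}'"
        )
    out = corr.abs()
    np.fill_diagonal(out.to_numpy(), 1.0)
    return out


@dataclass
class TraitClusterTree:
    """Complete-linkage dendrogram on the 1 - |r| distance scale."""

    linkage_matrix: np.ndarray          # scipy linkage format
    traits: list[str]
    cut: float
    groups: dict[str, int]              # trait -> group label (1-based)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))


def cluster_traits(corr: pd.DataFrame, cut: float = 1.0) -> TraitClusterTree:
    """Complete-linkage clustering of traits at distance 1 - |r|.

    Groups are the connected components after cutting strictly below
    ``cut``: a pair merging exactly at ``cut`` lands in separate groups.
    """
    traits = list(corr.columns)
    d = 1.0 - np.abs(corr.to_numpy(dtype=float))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(Z, t=cut - 1e-9, criterion="distance")
    groups = {t: int(g) for t, g in zip(traits, labels)}
    return TraitClusterTree(Z, traits, cut, groups)


@dataclass
class PcaResult:
    """Correlation-matrix PCA of the trait table."""

    loadings: pd.DataFrame              # trait x component (unit eigenvectors)
    scores: pd.DataFrame                # row x component
    explained_variance_ratio: np.ndarray
    n_components: int

    def component(self, k: int) -> str:
        return self.scores.columns[k]


def pca_traits(
    traits: pd.DataFrame,
    log_scale: bool = True,
    signed_traits: Sequence[str] = (),
) -> PcaResult:
    """PCA of the column-standardized natural-log trait matrix.

    Each component is oriented so that its largest-magnitude loading is
    positive.  Variance fractions are eigenvalues over their total and
    sum to 1.
    """
    tr = _transform_traits(traits, log_scale, signed_traits)
    X = tr.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("residual missing values; run gap filling first")
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = tr.columns[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"trait '{bad}' has zero variance")
    X = X / sd
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    frac = eig / eig.sum()
    V = Vt.T
    # orient: largest-|loading| positive
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = X @ V
    comp_names = [f"PC{k + 1}" for k in range(V.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(V, index=tr.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=tr.index, columns=comp_names),
        explained_variance_ratio=frac,
        n_components=len(comp_names),
    )


def significant_axes(
    traits: pd.DataFrame,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    log_scale: bool = True,
    signed_traits: Sequence[str] = (),
) -> int:
    """Number of leading PCA axes significant under a permutation test.

    Null distributions come from independently permuting each
    standardized column; component ``k`` is significant when its
    variance fraction beats the null at a sequentially
    (Holm-Bonferroni) adjusted alpha.  Returns the largest ``k`` with
    components ``1..k`` all significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is small; p-value resolution is coarse",
            stacklevel=2,
        )
    tr = _transform_traits(traits, log_scale, signed_traits)
    X = tr.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n, p = X.shape

    def _fracs(M: np.ndarray) -> np.ndarray:
        s = np.linalg.svd(M, compute_uv=False)
        eig = s**2
        return eig / eig.sum()

    obs = _fracs(X)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(p)
    for _ in range(n_perm):
        Xp = np.empty_like(X)
        for j in range(p):
            Xp[:, j] = X[rng.permutation(n), j]
        exceed += _fracs(Xp) >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    retained = 0
    for k in range(p):
        adj_alpha = alpha / (p - k)
        if pvals[k] <= adj_alpha:
            retained = k + 1
        else:
            break
    return retained


@dataclass
class LatitudeFit:
    """OLS fit of a component score on absolute latitude."""

    level: str       # "species" (all rows) or "binned" (1-degree bin means)
    slope: float
    intercept: float
    r2: float
    n: int


def latitude_fit(
    scores: Sequence[float] | np.ndarray,
    latitudes: Sequence[float] | np.ndarray,
) -> tuple[LatitudeFit, LatitudeFit]:
    """Regress scores on |latitude|, raw and averaged in 1-degree bins.

    Returns ``(row_level_fit, binned_fit)``.  Bins are
    ``floor(|latitude|)``; the binned fit regresses bin-mean scores on
    bin-mean |latitude|.
    """
    scores = np.asarray(scores, dtype=float)
    alat = np.abs(np.asarray(latitudes, dtype=float))
    if scores.shape != alat.shape:
        raise ValueError("scores and latitudes must have equal length")
    if len(np.unique(alat)) < 3:
        raise ValueError("need >= 3 distinct latitudes")
    res = linregress(alat, scores)
    fit_all = LatitudeFit(
        "species", float(res.slope), float(res.intercept),
        float(res.rvalue**2), len(scores),
    )
    df = pd.DataFrame({"alat": alat, "score": scores, "bin": np.floor(alat)})
    binned = df.groupby("bin")[["alat", "score"]].mean()
    if len(binned) < 3:
        raise ValueError("need >= 3 distinct 1-degree latitude bins")
    res_b = linregress(binned["alat"], binned["score"])
    fit_bin = LatitudeFit(
        "binned", float(res_b.slope), float(res_b.intercept),
        float(res_b.rvalue**2), len(binned),
    )
    return fit_all, fit_bin
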