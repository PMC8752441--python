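"""Climate/soil variance partitioning of ecoregion-level traits.

For each trait, ridge regressions are fitted on three predictor sets —
climate components only, soil components only, and both — with nested
cross-validation (inner folds select the L2 penalty, outer folds give
holdout predictions).  The holdout r-squared (squared Pearson correlation
of concatenated out-of-fold predictions against observations) is averaged
over repetitions, and the explained variance is decomposed by
inclusion-exclusion into a joint effect and the independent effect of
each block.  With exactly two predictor blocks the averaged-orderings
partitioning scheme reduces to these formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RidgeSpec",
    "ReductionMap",
    "reduce_block",
    "CvResult",
    "cv_holdout_r2",
    "Partition",
    "partition_variance",
    "partition_total",
    "partition_table",
]


def _default_lambda_grid() -> np.ndarray:
    return np.logspace(-4, 4, 100)


@dataclass
class RidgeSpec:
    """Penalty grid, fold structure and repetition count for the CV loop."""

    lambdas: np.ndarray = field(default_factory=_default_lambda_grid)
    inner_folds: int = 10
    outer_folds: int = 10
    repetitions: int = 50
    n_components: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.lambdas = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
        if np.any(self.lambdas < 0):
            raise ValueError("lambdas must be >= 0")
        if self.inner_folds < 2 or self.outer_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass
class ReductionMap:
    """Standardization + rotation used to project a predictor block."""

    columns: list[str]
    dropped: list[str]
    mean: np.ndarray
    sd: np.ndarray
    components: np.ndarray      # p x k eigenvector matrix
    explained_variance: np.ndarray

    def transform(self, block: pd.DataFrame) -> np.ndarray:
        X = block[self.columns].to_numpy(dtype=float)
        return ((X - self.mean) / self.sd) @ self.components


def reduce_block(
    block: pd.DataFrame, n_components: int = 20
) -> tuple[pd.DataFrame, ReductionMap]:
    """PCA-reduce a standardized predictor block to its leading components.

    Returns the first ``min(n_components, p, n - 1)`` component scores and
    the reduction map for reuse.  Constant columns are dropped with a
    warning before the PCA.
    """
    X = block.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("predictor block contains missing/non-finite values")
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("predictor block needs >= 2 rows and >= 1 column")
    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(block.columns, sd) if s == 0]
    if dropped:
        warnings.warn(
            f"dropping constant predictor columns before PCA: {dropped}",
            stacklevel=2,
        )
    keep = [c for c in block.columns if c not in set(dropped)]
    X = block[list(keep)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Xs = (X - mean) / sd
    k = min(n_components, Xs.shape[1], n - 1)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s**2 / (n - 1)
    comps = Vt.T[:, :k]
    scores = Xs @ comps
    names = [f"{_common_prefix(keep)}pc{j + 1:02d}" for j in range(k)]
    rmap = ReductionMap(
        columns=list(keep),
        dropped=dropped,
        mean=mean,
        sd=sd,
        components=comps,
        explained_variance=eig[:k],
    )
    return pd.DataFrame(scores, index=block.index, columns=names), rmap


def _common_prefix(names: Sequence) -> str:
    names = [str(n) for n in names]
    pref = names[0].split("_")[0] if names else "x"
    return pref + "_" if all(n.startswith(pref) for n in names) else ""


def _make_folds(
    n: int, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [f for f in np.array_split(idx, n_folds)]


class _RidgePath:
    """SVD factorization of a (standardized, centred) training design,
    giving predictions for all penalties at once."""

    def __init__(self, X_tr: np.ndarray, tol: float = 1e-10):
        self.mean = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        self.sd = sd
        Xs = (X_tr - self.mean) / self.sd
        self.U, self.d, Vt = np.linalg.svd(Xs, full_matrices=False)
        self.V = Vt.T
        self.tol = tol

    def predict(
        self, y_tr: np.ndarray, X_te: np.ndarray, lambdas: np.ndarray
    ) -> np.ndarray:
        """Out-of-sample predictions, shape (n_te, n_lambdas)."""
        ybar = y_tr.mean()
        uty = self.U.T @ (y_tr - ybar)
        d = self.d[:, None]
        denom = d**2 + lambdas[None, :]
        ratio = np.where(
            denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0
        )
        # lambda = 0 with a zero singular value -> minimum-norm solution
        ratio[self.d < self.tol * max(1.0, self.d.max(initial=0.0)), :] = 0.0
        W = ratio * uty[:, None]                       # r x L
        Xs_te = (X_te - self.mean) / self.sd
        return Xs_te @ (self.V @ W) + ybar


class _NestedCv:
    """Precomputed fold structure + SVDs for one design matrix, reusable
    across response vectors (traits)."""

    def __init__(
        self,
        X: np.ndarray,
        outer_folds: list[np.ndarray],
        inner_folds_per_outer: list[list[np.ndarray]],
        lambdas: np.ndarray,
    ):
        self.X = X
        self.lambdas = lambdas
        self.outer = []
        for test_idx, inner in zip(outer_folds, inner_folds_per_outer):
            train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
            full_path = _RidgePath(X[train_idx])
            inner_paths = []
            for in_te in inner:
                in_tr = np.setdiff1d(train_idx, in_te)
                inner_paths.append((in_tr, in_te, _RidgePath(X[in_tr])))
            self.outer.append((train_idx, test_idx, full_path, inner_paths))

    def holdout_predictions(self, y: np.ndarray) -> tuple[np.ndarray, bool]:
        """Concatenated out-of-fold predictions (aligned to row order).

        The returned flag marks a degenerate fit: every fold's
        predictions collapsed to its training mean (infinite penalty),
        so the concatenated values carry no signal.
        """
        pred = np.empty_like(y, dtype=float)
        L = self.lambdas
        all_const = True
        for train_idx, test_idx, full_path, inner_paths in self.outer:
            mse = np.zeros(len(L))
            for in_tr, in_te, path in inner_paths:
                p = path.predict(y[in_tr], self.X[in_te], L)
                mse += np.mean((p - y[in_te, None]) ** 2, axis=0)
            best = int(np.argmin(mse))
            lam = np.array([L[best]])
            fold_pred = full_path.predict(
                y[train_idx], self.X[test_idx], lam
            )[:, 0]
            pred[test_idx] = fold_pred
            if np.ptp(fold_pred) > 1e-12 * max(1.0, np.abs(fold_pred).max()):
                all_const = False
        return pred, all_const


def _r2_pearson(pred: np.ndarray, obs: np.ndarray) -> tuple[float, bool]:
    """Squared Pearson correlation; (0, flag=True) when undefined."""
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0, True
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r**2), False


class CvResult(NamedTuple):
    mean: float
    min: float
    max: float
    per_repetition: np.ndarray
    degenerate: bool    # any repetition had constant predictions


def cv_holdout_r2(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    spec: RidgeSpec,
    folds_per_repetition: list[list[np.ndarray]] | None = None,
) -> CvResult:
    """Repeated nested-CV holdout r-squared of ridge predictions.

    Per repetition the rows are split into ``spec.outer_folds`` folds;
    each outer training set selects the penalty by inner CV (minimum mean
    MSE), out-of-fold predictions are concatenated, and r-squared is the
    squared Pearson correlation of predictions versus observations.
    ``folds_per_repetition`` lets callers impose a shared outer-fold
    layout across predictor sets.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y must have matching rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("missing/non-finite values in X or y")
    if n < 30:
        raise ValueError(f"n = {n} too small; need >= 30 rows")
    if n < spec.outer_folds * 2:
        raise ValueError(
            f"n = {n} too small for {spec.outer_folds} outer folds; "
            f"reduce outer_folds to <= {n // 2}"
        )
    rng_master = np.random.default_rng(spec.seed)
    r2s = np.empty(spec.repetitions)
    degenerate = False
    for rep in range(spec.repetitions):
        rng = np.random.default_rng(rng_master.integers(2**63))
        if folds_per_repetition is not None:
            outer = folds_per_repetition[rep]
        else:
            outer = _make_folds(n, spec.outer_folds, rng)
        inner = []
        for test_idx in outer:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            inner.append(
                [train_idx[f] for f in _make_folds(
                    len(train_idx), spec.inner_folds, rng
                )]
            )
        cv = _NestedCv(X, outer, inner, spec.lambdas)
        pred, all_const = cv.holdout_predictions(y)
        if all_const:
            r2, flag = 0.0, True
        else:
            r2, flag = _r2_pearson(pred, y)
        degenerate |= flag
        r2s[rep] = r2
    return CvResult(
        float(r2s.mean()), float(r2s.min()), float(r2s.max()), r2s, degenerate
    )


class Partition(NamedTuple):
    joint: float
    independent_climate: float
    independent_soil: float


def partition_variance(
    r2_both: float, r2_climate: float, r2_soil: float
) -> Partition:
    """Two-block inclusion-exclusion decomposition of explained variance.

    ``joint = r2_climate + r2_soil - r2_both``;
    ``independent_climate = r2_both - r2_soil``;
    ``independent_soil = r2_both - r2_climate``.
    Independent effects may legitimately be negative.
    """
    return Partition(
        joint=r2_climate + r2_soil - r2_both,
        independent_climate=r2_both - r2_soil,
        independent_soil=r2_both - r2_climate,
    )


def partition_total(
    joint: float, independent_climate: float, independent_soil: float
) -> float:
    """Total explained variance recovered from the three components
    (the decomposition's additivity identity)."""
    return joint + independent_climate + independent_soil


def display_shares(
    joint: float, independent_climate: float, independent_soil: float
) -> tuple[float, float]:
    """Per-block display shares: independent effect plus half the joint
    effect; a negative independent effect is not displayed (the block
    shows only its joint half)."""
    climate = max(independent_climate, 0.0) + joint / 2.0
    soil = max(independent_soil, 0.0) + joint / 2.0
    return climate, soil


def partition_table(
    traits: pd.DataFrame,
    climate_block: pd.DataFrame,
    soil_block: pd.DataFrame,
    spec: RidgeSpec,
    groups: dict[str, str] | None = None,
    log_scale: bool = True,
    signed_traits: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-trait explained-variance partition over shared CV repetitions.

    Each predictor block is PCA-reduced to ``spec.n_components``; the
    climate-only, soil-only and combined ridge models share the outer
    fold layout within each repetition, so the decomposition identities
    hold exactly per repetition and for the reported means.
    """
    clim_scores, _ = reduce_block(climate_block, spec.n_components)
    soil_scores, _ = reduce_block(soil_block, spec.n_components)
    Xc = clim_scores.to_numpy()
    Xs = soil_scores.to_numpy()
    Xb = np.hstack([Xc, Xs])
    n = Xc.shape[0]
    if n < 30:
        raise ValueError(f"n = {n} too small; need >= 30 ecoregions")

    signed = set(signed_traits)
    rng_master = np.random.default_rng(spec.seed)
    rep_rngs = [
        np.random.default_rng(rng_master.integers(2**63))
        for _ in range(spec.repetitions)
    ]
    # shared outer folds per repetition; per-design nested-CV caches
    caches: dict[str, list[_NestedCv]] = {"climate": [], "soil": [], "both": []}
    for rng in rep_rngs:
        outer = _make_folds(n, spec.outer_folds, rng)
        inner = []
        for test_idx in outer:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            inner.append(
                [train_idx[f] for f in _make_folds(
                    len(train_idx), spec.inner_folds, rng
                )]
            )
        for key, X in (("climate", Xc), ("soil", Xs), ("both", Xb)):
            caches[key].append(_NestedCv(X, outer, inner, spec.lambdas))

    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        if log_scale and trait not in signed:
            if np.any(y <= 0):
                raise ValueError(
                    f"trait '{trait}' has non-positive values; declare it "
                    "in signed_traits"
                )
            y = np.log(y)
        r2 = {k: np.empty(spec.repetitions) for k in caches}
        degenerate = False
        for rep in range(spec.repetitions):
            for key in caches:
                pred, all_const = caches[key][rep].holdout_predictions(y)
                if all_const:
                    val, flag = 0.0, True
                else:
                    val, flag = _r2_pearson(pred, y)
                degenerate |= flag
                r2[key][rep] = val
        parts = [
            partition_variance(b, c, s)
            for b, c, s in zip(r2["both"], r2["climate"], r2["soil"])
        ]
        joint = float(np.mean([p.joint for p in parts]))
        ind_c = float(np.mean([p.independent_climate for p in parts]))
        ind_s = float(np.mean([p.independent_soil for p in parts]))
        disp_c, disp_s = display_shares(joint, ind_c, ind_s)
        rows.append(
            {
                "trait": trait,
                "group": (groups or {}).get(trait, ""),
                "r2_both_mean": float(r2["both"].mean()),
                "r2_both_min": float(r2["both"].min()),
                "r2_both_max": float(r2["both"].max()),
                "r2_climate_mean": float(r2["climate"].mean()),
                "r2_climate_min": float(r2["climate"].min()),
                "r2_climate_max": float(r2["climate"].max()),
                "r2_soil_mean": float(r2["soil"].mean()),
                "r2_soil_min": float(r2["soil"].min()),
                "r2_soil_max": float(r2["soil"].max()),
                "joint": joint,
                "independent_climate": ind_c,
                "independent_soil": ind_s,
                "display_climate": disp_c,
                "display_soil": disp_s,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
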