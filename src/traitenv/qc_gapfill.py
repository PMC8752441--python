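"""Quality control and hierarchical matrix-factorization gap filling.

Trait values are natural-log transformed (signed traits excepted),
standardized per trait (zlog), screened by a z-score filter, and missing
cells are imputed by a Gibbs-sampled probabilistic matrix factorization
whose row latent vectors are shrunk through the taxonomic hierarchy
(row -> species -> genus -> family -> global mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "ZlogTransform",
    "zlog",
    "qc_filter",
    "QcReport",
    "HpmfModel",
    "gapfill",
    "hpmf_impute",
    "per_trait_mean_impute",
]


@dataclass(frozen=True)
class ZlogTransform:
    """Per-trait standardization z = (x - mean) / sd and its inverse."""

    mean: pd.Series
    sd: pd.Series

    def forward(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df - self.mean) / self.sd

    def inverse(self, zdf: pd.DataFrame) -> pd.DataFrame:
        return zdf * self.sd + self.mean


def zlog(df: pd.DataFrame) -> tuple[pd.DataFrame, ZlogTransform]:
    """Standardize each trait column to mean 0, sample s.d. 1 (ddof=1).

    Missing values are ignored in the statistics and propagate unchanged.
    Raises ``ValueError`` naming the trait for constant or near-empty
    columns.
    """
    means = {}
    sds = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        obs = x[np.isfinite(x)]
        if obs.size < 2:
            raise ValueError(f"trait '{col}': needs >= 2 non-missing values")
        sd = obs.std(ddof=1)
        if sd == 0:
            raise ValueError(f"trait '{col}': zero standard deviation (constant)")
        means[col] = obs.mean()
        sds[col] = sd
    tf = ZlogTransform(mean=pd.Series(means), sd=pd.Series(sds))
    return tf.forward(df), tf


@dataclass
class QcReport:
    """Outcome of the z-score screen."""

    per_trait: pd.DataFrame          # columns: trait, n_excluded, n_flagged
    excluded: list[tuple[int, str]]  # (row position, trait) of removed cells
    flagged: list[tuple[int, str]]   # retained but implausibly extreme cells


def qc_filter(
    zdf: pd.DataFrame,
    exclude_above: float = 4.0,
    flag_above: float = 3.0,
) -> tuple[pd.DataFrame, QcReport]:
    """Drop cells with |z| strictly above ``exclude_above``; flag |z| above
    ``flag_above`` (retained)."""
    out = zdf.copy()
    excluded: list[tuple[int, str]] = []
    flagged: list[tuple[int, str]] = []
    rows = []
    for col in zdf.columns:
        z = zdf[col].to_numpy(dtype=float)
        kill = np.isfinite(z) & (np.abs(z) > exclude_above)
        warn = np.isfinite(z) & (np.abs(z) > flag_above) & ~kill
        out.loc[kill, col] = np.nan
        excluded += [(int(i), col) for i in np.flatnonzero(kill)]
        flagged += [(int(i), col) for i in np.flatnonzero(warn)]
        rows.append(
            {"trait": col, "n_excluded": int(kill.sum()), "n_flagged": int(warn.sum())}
        )
    return out, QcReport(pd.DataFrame(rows), excluded, flagged)


@dataclass
class HpmfModel:
    """Configuration of the hierarchical matrix-factorization sampler.

    The Gibbs chain runs at most ``max_iter`` iterations; draws after
    ``burn_in``, thinned every ``thin``-th, are retained, giving exactly
    ``(max_iter - burn_in) // thin`` draws when no early stop triggers.
    The observed cells are split train/test/validation; validation RMSE
    drives early stopping (``patience`` consecutive iterations with
    |change| < ``rmse_tol``); test RMSE is monitored and logged only.
    """

    rank: int = 10
    obs_precision: float = 2.0
    prior_var: float = 1.0
    max_iter: int = 1000
    burn_in: int = 200
    thin: int = 20
    patience: int = 5
    rmse_tol: float = 1e-4
    train_frac: float = 0.8
    test_frac: float = 0.1
    val_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.obs_precision <= 0:
            raise ValueError("obs_precision must be > 0")
        if self.prior_var <= 0:
            raise ValueError("prior_var must be > 0")
        if not self.burn_in < self.max_iter:
            raise ValueError("burn_in must be < max_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        total = self.train_frac + self.test_frac + self.val_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("train/test/val fractions must sum to 1")

    @property
    def n_retained_draws(self) -> int:
        return (self.max_iter - self.burn_in) // self.thin


def _sample_mvn(prec: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^-1 b, prec^-1) via a Cholesky factor of prec."""
    c, low = cho_factor(prec, lower=True)
    mean = cho_solve((c, low), b)
    z = rng.standard_normal(b.shape[0])
    return mean + solve_triangular(c, z, lower=True, trans="T")


def hpmf_impute(
    Z: np.ndarray,
    hierarchy: Sequence[np.ndarray],
    model: HpmfModel,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Gibbs-sample a hierarchical matrix factorization of ``Z`` (NaN = missing).

    Parameters
    ----------
    Z:
        Standardized (zlog) matrix, rows x traits, NaN missing.
    hierarchy:
        Integer code arrays mapping each level's units to the next
        coarser level: ``hierarchy[0]`` maps rows to level-1 groups,
        ``hierarchy[1]`` maps level-1 groups to level-2 groups, etc.  May
        be empty (plain matrix factorization around a global zero mean).

    Returns ``(pred_mean, pred_sd, report)`` where ``pred_mean``/``pred_sd``
    are the mean and s.d. over retained posterior draws of the full
    reconstruction, and ``report`` carries RMSE trajectories and stopping
    information.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    K = model.rank
    rng = np.random.default_rng(model.seed)
    obs_i, obs_j = np.nonzero(np.isfinite(Z))
    n_obs = obs_i.size
    if n_obs == 0:
        raise ValueError("matrix has no observed values")

    perm = rng.permutation(n_obs)
    n_train = max(1, int(round(model.train_frac * n_obs)))
    n_test = int(round(model.test_frac * n_obs))
    tr = perm[:n_train]
    te = perm[n_train : n_train + n_test]
    va = perm[n_train + n_test :]
    tr_i, tr_j, tr_x = obs_i[tr], obs_j[tr], Z[obs_i[tr], obs_j[tr]]
    te_i, te_j, te_x = obs_i[te], obs_j[te], Z[obs_i[te], obs_j[te]]
    va_i, va_j, va_x = obs_i[va], obs_j[va], Z[obs_i[va], obs_j[va]]

    # per-column train rows / values (for the trait-vector updates)
    col_rows: list[np.ndarray] = [np.empty(0, dtype=int) for _ in range(p)]
    col_vals: list[np.ndarray] = [np.empty(0) for _ in range(p)]
    order = np.argsort(tr_j, kind="stable")
    bounds = np.searchsorted(tr_j[order], np.arange(p + 1))
    for j in range(p):
        sl = order[bounds[j] : bounds[j + 1]]
        col_rows[j] = tr_i[sl]
        col_vals[j] = tr_x[sl]
    # complement columns per row (columns absent from the train set),
    # flattened for batched precision-matrix corrections
    train_mask = np.zeros((n, p), dtype=bool)
    train_mask[tr_i, tr_j] = True
    nt_rows, nt_cols = np.nonzero(~train_mask)
    X_train = np.zeros((n, p))
    X_train[tr_i, tr_j] = tr_x

    hierarchy = [np.asarray(h, dtype=int) for h in hierarchy]
    level_sizes = [n] + [int(h.max()) + 1 if h.size else 1 for h in hierarchy]
    U = rng.normal(0.0, 0.1, (n, K))
    parents = [rng.normal(0.0, 0.1, (sz, K)) for sz in level_sizes[1:]]
    V = rng.normal(0.0, 0.1, (p, K))

    alpha = model.obs_precision
    pv = model.prior_var
    eye_pv = np.eye(K) / pv

    pred_sum = np.zeros((n, p))
    pred_sumsq = np.zeros((n, p))
    n_draws = 0
    val_rmse_log: list[float] = []
    test_rmse_log: list[float] = []
    streak = 0
    prev_rmse = np.inf
    stopped_early = False
    n_iter_run = 0

    for t in range(1, model.max_iter + 1):
        n_iter_run = t
        # trait latent vectors
        for j in range(p):
            Uj = U[col_rows[j]]
            prec = eye_pv + alpha * (Uj.T @ Uj)
            bvec = alpha * (Uj.T @ col_vals[j])
            V[j] = _sample_mvn(prec, bvec, rng)
        G = alpha * (V.T @ V)
        # row latent vectors, shrunk to their level-1 parent (batched)
        par0 = parents[0][hierarchy[0]] if hierarchy else np.zeros((n, K))
        P_all = np.broadcast_to(eye_pv + G, (n, K, K)).copy()
        if nt_rows.size:
            Vnt = V[nt_cols]
            np.add.at(
                P_all, nt_rows, -alpha * (Vnt[:, :, None] * Vnt[:, None, :])
            )
        b_all = par0 / pv + alpha * (X_train @ V)
        Lchol = np.linalg.cholesky(P_all)
        mean_all = np.linalg.solve(P_all, b_all[:, :, None])[:, :, 0]
        z = rng.standard_normal((n, K))
        U = mean_all + np.linalg.solve(
            np.transpose(Lchol, (0, 2, 1)), z[:, :, None]
        )[:, :, 0]
        # taxonomic level latents (diagonal conjugate updates)
        child_latents = U
        for lvl, codes in enumerate(hierarchy):
            sz = level_sizes[lvl + 1]
            sums = np.zeros((sz, K))
            np.add.at(sums, codes, child_latents)
            counts = np.bincount(codes, minlength=sz).astype(float)
            if lvl + 1 < len(parents):
                grand = parents[lvl + 1][hierarchy[lvl + 1]]
            else:
                grand = np.zeros((sz, K))
            post_var = pv / (1.0 + counts)
            post_mean = (grand + sums) / (1.0 + counts)[:, None]
            parents[lvl] = post_mean + rng.standard_normal((sz, K)) * np.sqrt(
                post_var
            )[:, None]
            child_latents = parents[lvl]

        if va_i.size:
            val_pred = np.einsum("ik,ik->i", U[va_i], V[va_j])
            rmse = float(np.sqrt(np.mean((val_pred - va_x) ** 2)))
        else:
            rmse = float("nan")
        val_rmse_log.append(rmse)
        if te_i.size:
            te_pred = np.einsum("ik,ik->i", U[te_i], V[te_j])
            test_rmse_log.append(float(np.sqrt(np.mean((te_pred - te_x) ** 2))))

        if t > model.burn_in and (t - model.burn_in) % model.thin == 0:
            pred = U @ V.T
            pred_sum += pred
            pred_sumsq += pred**2
            n_draws += 1

        if np.isfinite(rmse) and abs(rmse - prev_rmse) < model.rmse_tol:
            streak += 1
        else:
            streak = 0
        prev_rmse = rmse
        if streak >= model.patience and n_draws >= 1:
            stopped_early = True
            break

    if n_draws == 0:  # pragma: no cover - guarded by burn_in < max_iter
        raise RuntimeError("no posterior draws retained")
    pred_mean = pred_sum / n_draws
    if n_draws > 1:
        var = (pred_sumsq - n_draws * pred_mean**2) / (n_draws - 1)
        pred_sd = np.sqrt(np.clip(var, 0.0, None))
    else:
        pred_sd = np.zeros_like(pred_mean)
    report = {
        "n_iterations": n_iter_run,
        "n_draws": n_draws,
        "stopped_early": stopped_early,
        "val_rmse": val_rmse_log,
        "test_rmse": test_rmse_log,
        "final_val_rmse": val_rmse_log[-1] if val_rmse_log else float("nan"),
    }
    return pred_mean, pred_sd, report


def _hierarchy_codes(
    index: pd.Index, taxonomy: pd.DataFrame, levels: Sequence[str]
) -> list[np.ndarray]:
    """Chain of integer code maps row -> level1 -> level2 -> ... ."""
    tax = taxonomy.loc[index]
    codes: list[np.ndarray] = []
    if not levels:
        return codes
    child, child_cats = pd.factorize(tax[levels[0]])
    codes.append(np.asarray(child, dtype=int))
    for fine, coarse in zip(levels[:-1], levels[1:]):
        mapping = tax.drop_duplicates(subset=[fine]).set_index(fine)[coarse]
        parent_of_child = mapping.loc[child_cats]
        parent, parent_cats = pd.factorize(parent_of_child)
        codes.append(np.asarray(parent, dtype=int))
        child_cats = parent_cats
    return codes


def gapfill(
    traits: pd.DataFrame,
    taxonomy: pd.DataFrame,
    model: HpmfModel,
    signed_traits: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Fill missing trait cells via the hierarchical factorization.

    Parameters
    ----------
    traits:
        Original-scale trait table (rows = observations or species,
        columns = traits, NaN = missing).  Positive traits are
        natural-log transformed internally; columns listed in
        ``signed_traits`` stay on their linear scale.
    taxonomy:
        Table aligned with ``traits`` rows (same index) providing the
        taxonomic grouping columns among ``species, genus, family,
        higher`` (those present are used, finest first).

    Returns
    -------
    completed:
        Original-scale table; observed cells pass through unchanged,
        missing cells hold the posterior-mean imputation.
    sd:
        Standard deviation over retained draws for imputed cells (on the
        log scale for positive traits, linear scale for signed traits);
        NaN for observed cells.
    report:
        Sampler diagnostics (RMSE trajectories, draw counts).
    """
    mat = traits.to_numpy(dtype=float)
    if np.isinf(mat).any():
        raise ValueError("non-finite (infinite) trait values in input")
    observed = np.isfinite(mat)
    if (observed.sum(axis=1) == 0).any():
        bad = traits.index[observed.sum(axis=1) == 0][0]
        raise ValueError(
            f"row {bad!r} has no observed value; gap filling requires at "
            "least one value per row and per trait column"
        )
    if (observed.sum(axis=0) == 0).any():
        bad = traits.columns[observed.sum(axis=0) == 0][0]
        raise ValueError(
            f"trait column {bad!r} has no observed value; gap filling "
            "requires at least one value per row and per trait column"
        )

    log_df = traits.copy()
    pos_cols = [c for c in traits.columns if c not in set(signed_traits)]
    for c in pos_cols:
        vals = log_df[c].to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError(
                f"trait '{c}' has non-positive values; declare it in "
                "signed_traits or clean the input"
            )
        log_df[c] = np.log(vals)
    zdf, tf = zlog(log_df)

    if not observed.all():
        levels = [
            c for c in ("species", "genus", "family", "higher") if c in taxonomy.columns
        ]
        missing_rows = traits.index.difference(taxonomy.index)
        if len(missing_rows):
            raise ValueError(
                f"taxonomy does not cover all rows (e.g. {missing_rows[0]!r})"
            )
        codes = _hierarchy_codes(traits.index, taxonomy, levels)
        pred_mean, pred_sd, report = hpmf_impute(zdf.to_numpy(), codes, model)
    else:
        pred_mean = zdf.to_numpy()
        pred_sd = np.zeros_like(pred_mean)
        report = {"n_iterations": 0, "n_draws": 0, "stopped_early": False,
                  "val_rmse": [], "test_rmse": []}

    z_completed = zdf.to_numpy().copy()
    z_completed[~observed] = pred_mean[~observed]
    completed_log = tf.inverse(
        pd.DataFrame(z_completed, index=traits.index, columns=traits.columns)
    )
    completed = completed_log.copy()
    for c in pos_cols:
        completed[c] = np.exp(completed_log[c])
    completed_arr = completed.to_numpy()
    completed_arr[observed] = mat[observed]
    completed = pd.DataFrame(completed_arr, index=traits.index, columns=traits.columns)

    sd_scaled = pred_sd * tf.sd.to_numpy()[None, :]
    sd_arr = np.full_like(sd_scaled, np.nan)
    sd_arr[~observed] = sd_scaled[~observed]
    sd_df = pd.DataFrame(sd_arr, index=traits.index, columns=traits.columns)
    return completed, sd_df, report


def per_trait_mean_impute(traits: pd.DataFrame) -> pd.DataFrame:
    """Baseline: fill each missing cell with its trait's observed mean."""
    return traits.fillna(traits.mean())
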