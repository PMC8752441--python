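"""Configuration-driven orchestration of the full analysis.

Stages: simulate (or load) -> gap fill + QC -> aggregate (A1/A2 +
environment) -> trait axes (clustering, PCA, latitude fits) ->
climate/soil variance partition -> redundancy analysis -> report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import partition as part
from . import rda as rda_mod
from . import synthdata
from . import trait_structure as ts
from .qc_gapfill import HpmfModel, QcReport, gapfill, qc_filter, zlog

__all__ = ["RunConfig", "validate_config", "run"]

logger = logging.getLogger("traitenv")

_ID_COLUMNS = {
    "obs_id", "species", "genus", "family", "higher",
    "ecoregion", "location_id", "latitude", "longitude",
}

_STAGES = (
    "world", "gapfill_split", "gapfill", "axes", "partition", "rda",
)


@dataclass
class GapfillConfig:
    enabled: bool = True
    rank: int = 10
    obs_precision: float = 2.0
    max_iter: int = 400
    burn_in: int = 100
    thin: int = 10
    patience: int = 5

    def validate(self) -> None:
        HpmfModel(
            rank=self.rank, obs_precision=self.obs_precision,
            max_iter=self.max_iter, burn_in=self.burn_in,
            thin=self.thin, patience=self.patience,
        )


@dataclass
class QcConfig:
    exclude_above: float = 4.0
    flag_above: float = 3.0
    observed_only: bool = False

    def validate(self) -> None:
        if self.exclude_above <= 0 or self.flag_above <= 0:
            raise ValueError("qc thresholds must be > 0")


@dataclass
class AggregateConfig:
    min_species: int = 20
    min_fraction: float = 0.01

    def validate(self) -> None:
        if self.min_species < 0:
            raise ValueError("aggregate.min_species must be >= 0")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("aggregate.min_fraction must be in [0, 1]")


@dataclass
class AxesConfig:
    n_perm: int = 199
    alpha: float = 0.05
    cut: float = 1.0
    corr_log_scale: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("axes.alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("axes.n_perm must be >= 1")


@dataclass
class PartitionConfig:
    outer_folds: int = 10
    inner_folds: int = 10
    repetitions: int = 50
    n_components: int = 20
    lambda_min_exp: float = -4.0
    lambda_max_exp: float = 4.0
    n_lambdas: int = 100

    def validate(self) -> None:
        if self.repetitions < 1:
            raise ValueError("partition.repetitions must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("partition fold counts must be >= 2")
        if self.n_components < 1:
            raise ValueError("partition.n_components must be >= 1")
        if self.n_lambdas < 1:
            raise ValueError("partition.n_lambdas must be >= 1")

    def spec(self, seed: int) -> part.RidgeSpec:
        return part.RidgeSpec(
            lambdas=np.logspace(
                self.lambda_min_exp, self.lambda_max_exp, self.n_lambdas
            ),
            inner_folds=self.inner_folds,
            outer_folds=self.outer_folds,
            repetitions=self.repetitions,
            n_components=self.n_components,
            seed=seed,
        )


@dataclass
class RdaConfig:
    vif_exclude_above: float = 20.0
    vif_target_max: float = 10.0
    topsoil_only: bool = True

    def validate(self) -> None:
        if self.vif_exclude_above <= 0 or self.vif_target_max <= 0:
            raise ValueError("rda vif thresholds must be > 0")


@dataclass
class RunConfig:
    """Validated run configuration with every default materialized."""

    mode: str = "synthetic"
    seed: int = 0
    outdir: str = "traitenv_run"
    world: dict[str, Any] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)
    signed_traits: list[str] = field(default_factory=lambda: ["leaf_d15n"])
    gapfill: GapfillConfig = field(default_factory=GapfillConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    aggregate: AggregateConfig = field(default_factory=AggregateConfig)
    axes: AxesConfig = field(default_factory=AxesConfig)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    rda: RdaConfig = field(default_factory=RdaConfig)
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(
                f"mode must be 'synthetic' or 'files', got {self.mode!r}"
            )
        if self.mode == "files":
            required = {"observations", "environment", "ecoregions"}
            missing = required - set(self.files)
            if missing:
                raise ValueError(f"files mode requires paths for {sorted(missing)}")
        if self.mode == "synthetic":
            synthdata.WorldConfig(**{**self.world, "seed": 0})
        for sub in (self.gapfill, self.qc, self.aggregate, self.axes,
                    self.partition, self.rda):
            sub.validate()

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds deterministically spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(c.generate_state(1, dtype=np.uint32)[0])
            for name, c in zip(_STAGES, children)
        }


_SECTION_TYPES = {
    "gapfill": GapfillConfig,
    "qc": QcConfig,
    "aggregate": AggregateConfig,
    "axes": AxesConfig,
    "partition": PartitionConfig,
    "rda": RdaConfig,
}


def validate_config(raw: str | dict[str, Any] | None) -> RunConfig:
    """Build a :class:`RunConfig` from YAML text or a mapping.

    Fills documented defaults, rejects unknown keys by name, and
    enforces per-stage constraints.
    """
    if raw is None:
        data: dict[str, Any] = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")

    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in top_fields:
            raise ValueError(f"unknown config key '{key}'")

    kwargs: dict[str, Any] = {}
    for key, val in data.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            if isinstance(val, cls):
                kwargs[key] = val
                continue
            if not isinstance(val, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            for sub in val:
                if sub not in sub_fields:
                    raise ValueError(f"unknown config key '{key}.{sub}'")
            try:
                kwargs[key] = cls(**val)
            except TypeError as exc:
                raise ValueError(f"invalid config section '{key}': {exc}") from exc
        else:
            kwargs[key] = val
    try:
        cfg = RunConfig(**kwargs)
    except TypeError as exc:
        raise ValueError(str(exc)) from exc
    cfg.validate()
    return cfg


def _load_tables(
    cfg: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, synthdata.WorldTruth | None]:
    if cfg.mode == "synthetic":
        seeds = cfg.stage_seeds()
        world_cfg = synthdata.WorldConfig(**{**cfg.world, "seed": seeds["world"]})
        obs, env, eco, truth = synthdata.simulate_world(world_cfg)
        return obs, env, eco, truth
    tables = {}
    for key in ("observations", "environment", "ecoregions"):
        path = Path(cfg.files[key])
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        tables[key] = pd.read_csv(path, sep="\t")
    return tables["observations"], tables["environment"], tables["ecoregions"], None


def _trait_columns(obs: pd.DataFrame) -> list[str]:
    return [
        c for c in obs.columns
        if c not in _ID_COLUMNS and pd.api.types.is_numeric_dtype(obs[c])
    ]


def run(config: RunConfig, write_outputs: bool = True) -> dict[str, Any]:
    """Execute the full pipeline and return the structured run report."""
    cfg = config
    seeds = cfg.stage_seeds()
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    logger.setLevel(cfg.verbosity)

    report: dict[str, Any] = {"config": cfg.to_dict(), "stage_seeds": seeds}
    stage = "load"
    try:
        obs, env, eco, truth = _load_tables(cfg)
        trait_cols = _trait_columns(obs)
        signed = [t for t in cfg.signed_traits if t in trait_cols]
        report["input"] = {
            "n_observations": int(len(obs)),
            "n_traits": len(trait_cols),
            "traits": trait_cols,
            "signed_traits": signed,
            "n_ecoregions": int(obs["ecoregion"].nunique()),
            "n_species": int(obs["species"].nunique()),
        }

        # --- gap filling + QC ------------------------------------------
        stage = "gapfill"
        traits_df = obs[trait_cols].copy()
        n_missing = int(traits_df.isna().sum().sum())
        if cfg.gapfill.enabled and n_missing > 0:
            model = HpmfModel(
                rank=cfg.gapfill.rank,
                obs_precision=cfg.gapfill.obs_precision,
                max_iter=cfg.gapfill.max_iter,
                burn_in=cfg.gapfill.burn_in,
                thin=cfg.gapfill.thin,
                patience=cfg.gapfill.patience,
                seed=seeds["gapfill"],
            )
            taxonomy = obs[["species", "genus", "family", "higher"]].copy()
            completed, sd_table, gf_report = gapfill(
                traits_df, taxonomy, model, signed_traits=signed
            )
            report["gapfill"] = {
                "n_missing_filled": n_missing,
                "n_iterations": gf_report["n_iterations"],
                "n_draws": gf_report["n_draws"],
                "stopped_early": gf_report["stopped_early"],
                "final_val_rmse": gf_report.get("final_val_rmse"),
            }
        else:
            completed = traits_df
            report["gapfill"] = {"n_missing_filled": 0, "skipped": True}

        stage = "qc"
        log_df = completed.copy()
        for c in trait_cols:
            if c not in signed:
                log_df[c] = np.log(log_df[c].to_numpy(dtype=float))
        zdf, tf = zlog(log_df)
        if cfg.qc.observed_only:
            observed_mask = traits_df.notna()
            z_for_qc = zdf.where(observed_mask)
            filtered_z, qc_report = qc_filter(
                z_for_qc, cfg.qc.exclude_above, cfg.qc.flag_above
            )
            filtered_z = filtered_z.where(observed_mask, zdf)
        else:
            filtered_z, qc_report = qc_filter(
                zdf, cfg.qc.exclude_above, cfg.qc.flag_above
            )
        filtered_log = tf.inverse(filtered_z)
        clean = filtered_log.copy()
        for c in trait_cols:
            if c not in signed:
                clean[c] = np.exp(filtered_log[c])
        report["qc"] = {
            "n_excluded": int(qc_report.per_trait["n_excluded"].sum()),
            "n_flagged": int(qc_report.per_trait["n_flagged"].sum()),
            "per_trait": qc_report.per_trait.to_dict(orient="records"),
        }

        # --- aggregation ------------------------------------------------
        stage = "aggregate"
        obs_clean = pd.concat(
            [obs.drop(columns=trait_cols), clean], axis=1
        )
        a1 = agg.species_medians(obs_clean, trait_cols)
        richness = eco.set_index("ecoregion")["richness_estimate"]
        a2_traits, exclusions = agg.ecoregion_medians(
            a1, richness, trait_cols,
            min_species=cfg.aggregate.min_species,
            min_fraction=cfg.aggregate.min_fraction,
        )
        env_cols = [
            c for c in env.columns
            if c.startswith("clim_") or c.startswith("soil_")
        ]
        env_agg = agg.aggregate_environment(obs_clean, env, env_cols)
        a2 = a2_traits.merge(env_agg, on="ecoregion", how="left")
        assert not a2[env_cols].isna().any().any(), (
            "included ecoregion without aggregated environment"
        )
        report["aggregate"] = {
            "a1_rows": int(len(a1)),
            "a2_rows": int(len(a2)),
            "n_excluded_ecoregions": int(exclusions["ecoregion"].nunique()),
        }

        # --- trait structure -------------------------------------------
        stage = "axes"
        a1_traits = a1[trait_cols].dropna()
        corr = ts.correlation_matrix(
            a1_traits, log_scale=cfg.axes.corr_log_scale, signed_traits=signed
        )
        tree = ts.cluster_traits(corr, cut=cfg.axes.cut)
        pca = ts.pca_traits(a1_traits, signed_traits=signed)
        n_axes = ts.significant_axes(
            a1_traits, n_perm=cfg.axes.n_perm, alpha=cfg.axes.alpha,
            seed=seeds["axes"], signed_traits=signed,
        )
        lat = a1.loc[a1_traits.index, "latitude"].to_numpy()
        lat_fits = {}
        for k in range(min(2, pca.n_components)):
            fit_all, fit_bin = ts.latitude_fit(
                pca.scores.iloc[:, k].to_numpy(), lat
            )
            lat_fits[pca.component(k)] = {
                "species_r2": fit_all.r2,
                "binned_r2": fit_bin.r2,
                "species_slope": fit_all.slope,
                "binned_slope": fit_bin.slope,
            }
        report["axes"] = {
            "cluster_groups": tree.groups,
            "n_cluster_groups": tree.n_groups,
            "variance_fractions": [float(v) for v in pca.explained_variance_ratio],
            "n_significant_axes": int(n_axes),
            "latitude_fits": lat_fits,
        }

        # --- climate/soil partition ------------------------------------
        stage = "partition"
        clim_cols = [c for c in env_cols if c.startswith("clim_")]
        soil_cols = [c for c in env_cols if c.startswith("soil_")]
        a2_idx = a2.set_index("ecoregion")
        groups = truth.trait_groups if truth is not None else None
        part_df = part.partition_table(
            a2_idx[trait_cols],
            a2_idx[clim_cols],
            a2_idx[soil_cols],
            cfg.partition.spec(seeds["partition"]),
            groups=groups,
            signed_traits=signed,
        )
        report["partition"] = part_df.to_dict(orient="records")

        # --- redundancy analysis ---------------------------------------
        stage = "rda"
        soil_for_rda = (
            synthdata.topsoil_columns(soil_cols)
            if cfg.rda.topsoil_only else soil_cols
        )
        X_env = a2_idx[clim_cols + soil_for_rda]
        X_env = (X_env - X_env.mean()) / X_env.std(ddof=1)
        X_pruned, vif_report = rda_mod.vif_prune(
            X_env, cfg.rda.vif_exclude_above, cfg.rda.vif_target_max
        )
        Y = a2_idx[trait_cols].copy()
        for c in trait_cols:
            if c not in signed:
                Y[c] = np.log(Y[c].to_numpy(dtype=float))
        Y = (Y - Y.mean()) / Y.std(ddof=1)
        rda_res = rda_mod.fit_rda(Y, X_pruned)
        report["rda"] = {
            "n_predictors": int(X_pruned.shape[1]),
            "n_pruned": int(vif_report.table["removed"].sum()),
            "max_vif": vif_report.max_vif,
            "vif_target_met": vif_report.target_met,
            "variance_fraction_total": [
                float(v) for v in rda_res.variance_fraction_total
            ],
            "variance_fraction_constrained": [
                float(v) for v in rda_res.variance_fraction_constrained
            ],
        }
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if write_outputs:
        _write_outputs(outdir, report, locals())
    return report


def _write_outputs(outdir: Path, report: dict, ns: dict) -> None:
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    for name, key in [
        ("a1.tsv", "a1"), ("a2.tsv", "a2"), ("exclusions.tsv", "exclusions"),
    ]:
        if key in ns:
            ns[key].to_csv(outdir / name, sep="\t", index=False)
    if "part_df" in ns:
        ns["part_df"].to_csv(outdir / "partition.tsv", sep="\t", index=False)
    if "corr" in ns:
        ns["corr"].to_csv(outdir / "trait_correlations.tsv", sep="\t")
    if "pca" in ns:
        ns["pca"].loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    if "rda_res" in ns:
        ns["rda_res"].trait_scores_scaled.to_csv(
            outdir / "rda_trait_scores.tsv", sep="\t"
        )
        ns["rda_res"].predictor_scores.to_csv(
            outdir / "rda_predictor_scores.tsv", sep="\t"
        )
    summary = _summarize(report)
    (outdir / "summary.txt").write_text(summary)


def _summarize(report: dict) -> str:
    lines = ["traitenv run summary", "====================", ""]
    if "input" in report:
        inp = report["input"]
        lines.append(
            f"input: {inp['n_observations']} observations, "
            f"{inp['n_traits']} traits, {inp['n_species']} species, "
            f"{inp['n_ecoregions']} ecoregions"
        )
    if "qc" in report:
        lines.append(
            f"qc: {report['qc']['n_excluded']} cells excluded, "
            f"{report['qc']['n_flagged']} flagged"
        )
    if "aggregate" in report:
        a = report["aggregate"]
        lines.append(
            f"aggregation: A1 rows={a['a1_rows']}, A2 rows={a['a2_rows']}, "
            f"excluded ecoregions={a['n_excluded_ecoregions']}"
        )
    if "axes" in report:
        ax = report["axes"]
        fr = ", ".join(f"{100 * v:.1f}%" for v in ax["variance_fractions"][:3])
        lines.append(
            f"trait axes: top variance fractions {fr}; "
            f"{ax['n_significant_axes']} significant axes; "
            f"{ax['n_cluster_groups']} trait groups"
        )
    if "rda" in report:
        r = report["rda"]
        fr = ", ".join(
            f"{100 * v:.1f}%" for v in r["variance_fraction_constrained"][:2]
        )
        lines.append(f"rda: constrained-axis fractions {fr}")
    return "\n".join(lines) + "\n"
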