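"""Synthetic trait-environment world with known latent structure.

The generator produces the three delimited tables the analysis pipeline
consumes (observations, environment, ecoregion metadata) together with a
:class:`WorldTruth` record of the latent quantities, so every downstream
stage has a ground-truth recovery test.

Generative model
----------------
Each ecoregion ``e`` gets an absolute latitude uniform on [0, 70] degrees
(random hemisphere), a standardized latitude factor ``L_e`` (a linear
function of absolute latitude, population variance 1), and an independent
fertility factor ``F_e ~ N(0, 1)``.  Soil conditions are driven by the
mixed factor::

    M_e = sqrt(w) * L_e + sqrt(1 - w) * F_e

where ``w`` is ``shared_latent_weight`` (the fraction of soil-signal
variance tied to the latitude factor).  Climate variables are affine in
``L`` plus noise; soil variables are affine in ``M`` plus noise.

Species carry a size score (tracking ``L`` of their home ecoregion) and an
economics score (tracking ``M`` of their home ecoregion).  Species occupy
their home plus extra ecoregions sampled by similarity in ``(L, F)``
space, so ecoregion-level trait aggregates inherit the environmental
gradients.  Log-scale trait latents are linear in the two scores with
taxonomically structured (genus/family) offsets; observed values are
``exp`` of the latent plus observation noise, except a designated signed
trait kept on a linear scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "WorldConfig",
    "WorldTruth",
    "simulate_world",
    "inject_missingness",
    "truth_summary",
    "write_world",
    "topsoil_columns",
    "DEFAULT_TRAIT_NAMES",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


SIZE_TRAITS = (
    "height",
    "seed_mass",
    "seed_length",
    "dispersal_length",
    "leaf_area",
    "leaf_fresh_mass",
    "conduit_density",
)
ECON_TRAITS = (
    "sla",
    "leaf_n",
    "leaf_p",
    "leaf_c",
    "leaf_n_area",
    "leaf_np",
    "stem_density",
)
OTHER_TRAITS = ("seeds_per_unit", "vessel_length", "leaf_d15n")
DEFAULT_TRAIT_NAMES = SIZE_TRAITS + ECON_TRAITS + OTHER_TRAITS

# size axis carries the stronger signal so it dominates the first trait PC;
# the weaker economics axis keeps the two leading eigenvalues well separated
_DEFAULT_SIZE_LOADINGS = np.array([1.2, 1.1, 1.0, 0.9, 1.0, 1.1, -1.0])
_DEFAULT_ECON_LOADINGS = 0.55 * np.array([1.0, 0.9, 0.8, -0.6, 0.7, 0.9, -0.7])


def _default_loadings(n_traits: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-trait size/economics loadings and trait names for ``n_traits``."""
    size = np.zeros(n_traits)
    econ = np.zeros(n_traits)
    if n_traits == len(DEFAULT_TRAIT_NAMES):
        names = list(DEFAULT_TRAIT_NAMES)
        size[: len(SIZE_TRAITS)] = _DEFAULT_SIZE_LOADINGS
        econ[len(SIZE_TRAITS) : len(SIZE_TRAITS) + len(ECON_TRAITS)] = (
            _DEFAULT_ECON_LOADINGS
        )
    else:
        names = [f"trait_{i + 1:02d}" for i in range(n_traits)]
        n_size = max(1, int(round(0.4 * n_traits)))
        n_econ = max(1, int(round(0.4 * n_traits))) if n_traits > 1 else 0
        n_econ = min(n_econ, n_traits - n_size)
        size[:n_size] = np.linspace(1.2, 0.9, n_size)
        if n_econ:
            econ[n_size : n_size + n_econ] = np.linspace(1.0, 0.7, n_econ)
    return size, econ, names


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    Traits partition into "size", "economics" and "other" groups through
    the supports of ``size_loadings`` and ``econ_loadings`` (a trait may
    load on at most one of the two axes).
    """

    n_species: int = 300
    n_ecoregions: int = 60
    n_traits: int = 17
    n_climate_vars: int = 21
    n_soil_vars: int = 107
    shared_latent_weight: float = 0.5
    size_loadings: np.ndarray | None = None
    econ_loadings: np.ndarray | None = None
    trait_noise_sd: float = 0.3
    # heavy-tailed observation counts: n = 1 + Poisson(lognormal rate)
    obs_log_mean: float = 0.5
    obs_log_sd: float = 1.0
    sampling_bias_sd: float = 0.8
    max_obs_per_pair: int = 50
    missing_rate: float = 0.0
    seed: int = 0
    climate_noise_sd: float = 0.3
    soil_noise_sd: float = 0.3
    climate_loadings: np.ndarray | None = None
    soil_loadings: np.ndarray | None = None
    score_noise_sd: float = 0.2
    taxon_sd: float = 0.15
    species_resid_sd: float = 0.25
    occupancy_tau: float = 0.6
    mean_extra_ecoregions: float = 4.0
    n_locations_per_ecoregion: int = 5
    env_local_sd: float = 0.05
    trait_scale_sd: float = 1.0
    n_soil_depth_layers: int = 7
    signed_trait: str | None = "__auto__"
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "n_species",
            "n_ecoregions",
            "n_traits",
            "n_climate_vars",
            "n_soil_vars",
            "n_locations_per_ecoregion",
            "n_soil_depth_layers",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not 0.0 <= self.shared_latent_weight <= 1.0:
            raise ConfigError(
                f"shared_latent_weight must be in [0, 1], got {self.shared_latent_weight!r}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError(
                f"missing_rate must be in [0, 1), got {self.missing_rate!r}"
            )
        for name in (
            "trait_noise_sd",
            "climate_noise_sd",
            "soil_noise_sd",
            "score_noise_sd",
            "taxon_sd",
            "species_resid_sd",
            "env_local_sd",
            "trait_scale_sd",
            "obs_log_sd",
            "sampling_bias_sd",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be a finite real >= 0, got {v!r}")
        if self.occupancy_tau <= 0:
            raise ConfigError(f"occupancy_tau must be > 0, got {self.occupancy_tau!r}")
        if self.mean_extra_ecoregions < 0:
            raise ConfigError(
                f"mean_extra_ecoregions must be >= 0, got {self.mean_extra_ecoregions!r}"
            )

        default_size, default_econ, default_names = _default_loadings(self.n_traits)
        if self.size_loadings is None:
            self.size_loadings = default_size
        if self.econ_loadings is None:
            self.econ_loadings = default_econ
        self.size_loadings = np.asarray(self.size_loadings, dtype=float)
        self.econ_loadings = np.asarray(self.econ_loadings, dtype=float)
        if self.size_loadings.shape != (self.n_traits,):
            raise ConfigError(
                f"size_loadings must have length n_traits={self.n_traits}"
            )
        if self.econ_loadings.shape != (self.n_traits,):
            raise ConfigError(
                f"econ_loadings must have length n_traits={self.n_traits}"
            )
        if np.any((self.size_loadings != 0) & (self.econ_loadings != 0)):
            raise ConfigError(
                "size_loadings/econ_loadings: a trait may load on at most one axis"
            )
        if not self.trait_names:
            self.trait_names = default_names
        if len(self.trait_names) != self.n_traits:
            raise ConfigError(
                f"trait_names must have length n_traits={self.n_traits}"
            )
        if self.signed_trait == "__auto__":
            self.signed_trait = (
                "leaf_d15n" if "leaf_d15n" in self.trait_names else None
            )
        if self.signed_trait is not None and self.signed_trait not in self.trait_names:
            raise ConfigError(
                f"signed_trait {self.signed_trait!r} not among trait_names"
            )

    @property
    def trait_groups(self) -> dict[str, str]:
        """Map trait name -> generative group ('size'/'economics'/'other')."""
        groups = {}
        for name, a, b in zip(self.trait_names, self.size_loadings, self.econ_loadings):
            if a != 0:
                groups[name] = "size"
            elif b != 0:
                groups[name] = "economics"
            else:
                groups[name] = "other"
        return groups


@dataclass
class WorldTruth:
    """Latent ground truth of a simulated world."""

    ecoregion_ids: list[str]
    latitudes: np.ndarray
    lat_factor: np.ndarray          # L, standardized |latitude|
    fertility: np.ndarray           # F, independent of L
    soil_driver: np.ndarray         # M = sqrt(w) L + sqrt(1-w) F
    species_ids: list[str]
    size_scores: np.ndarray
    econ_scores: np.ndarray
    species_log_traits: np.ndarray  # species x trait latent (log scale)
    climate_loadings: np.ndarray
    soil_loadings: np.ndarray
    config: WorldConfig

    @property
    def trait_groups(self) -> dict[str, str]:
        return self.config.trait_groups


def _biome(abs_lat: np.ndarray) -> np.ndarray:
    bins = [23.5, 35.0, 50.0, 66.5]
    labels = np.array(["tropical", "subtropical", "temperate", "boreal", "polar"])
    return labels[np.digitize(abs_lat, bins)]


def soil_var_names(n_soil_vars: int, n_layers: int) -> list[str]:
    """Soil column names carrying a depth-layer tag (``_d0`` = topsoil)."""
    return [
        f"soil_p{i // n_layers:02d}_d{i % n_layers}" for i in range(n_soil_vars)
    ]


def topsoil_columns(columns: Sequence[str]) -> list[str]:
    """Subset of soil columns tagged as the shallowest depth layer."""
    return [c for c in columns if c.startswith("soil_") and c.endswith("_d0")]


def simulate_world(
    config: WorldConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, WorldTruth]:
    """Simulate observations, environment and ecoregion metadata.

    Returns ``(observations, environment, ecoregions, truth)``.  The
    observation table has one row per individual measurement with
    taxonomy, coordinates, an ecoregion id, a location id and one column
    per trait; the environment table has one row per location with
    climate and soil variables; the ecoregion table carries biome labels
    and species-richness estimates.  Fully reproducible under
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    nE, nS, nT = cfg.n_ecoregions, cfg.n_species, cfg.n_traits

    # --- ecoregions and latent factors ---------------------------------
    abs_lat = rng.uniform(0.0, 70.0, nE)
    hemi = rng.choice([-1.0, 1.0], nE)
    lat = hemi * abs_lat
    lon = rng.uniform(-180.0, 180.0, nE)
    L = (abs_lat - 35.0) / (70.0 / np.sqrt(12.0))
    F = rng.standard_normal(nE)
    w = cfg.shared_latent_weight
    M = np.sqrt(w) * L + np.sqrt(1.0 - w) * F
    er_ids = [f"ER{i + 1:04d}" for i in range(nE)]

    # --- environment variables -----------------------------------------
    if cfg.climate_loadings is None:
        a = rng.uniform(0.6, 1.2, cfg.n_climate_vars) * rng.choice(
            [-1.0, 1.0], cfg.n_climate_vars
        )
    else:
        a = np.asarray(cfg.climate_loadings, dtype=float)
        if a.shape != (cfg.n_climate_vars,):
            raise ConfigError("climate_loadings must have length n_climate_vars")
    if cfg.soil_loadings is None:
        b = rng.uniform(0.6, 1.2, cfg.n_soil_vars) * rng.choice(
            [-1.0, 1.0], cfg.n_soil_vars
        )
    else:
        b = np.asarray(cfg.soil_loadings, dtype=float)
        if b.shape != (cfg.n_soil_vars,):
            raise ConfigError("soil_loadings must have length n_soil_vars")

    clim_er = np.outer(L, a) + rng.normal(0.0, cfg.climate_noise_sd, (nE, cfg.n_climate_vars))
    soil_er = np.outer(M, b) + rng.normal(0.0, cfg.soil_noise_sd, (nE, cfg.n_soil_vars))

    nL = cfg.n_locations_per_ecoregion
    clim_cols = [f"clim_{i + 1:02d}" for i in range(cfg.n_climate_vars)]
    soil_cols = soil_var_names(cfg.n_soil_vars, cfg.n_soil_depth_layers)
    loc_er = np.repeat(np.arange(nE), nL)
    loc_ids = [f"{er_ids[e]}_L{k}" for e in range(nE) for k in range(nL)]
    loc_lat = lat[loc_er] + rng.uniform(-1.0, 1.0, nE * nL)
    loc_lon = lon[loc_er] + rng.uniform(-1.0, 1.0, nE * nL)
    env_vals = np.hstack([clim_er[loc_er], soil_er[loc_er]])
    env_vals = env_vals + rng.normal(0.0, cfg.env_local_sd, env_vals.shape)
    env_df = pd.DataFrame(env_vals, columns=clim_cols + soil_cols)
    env_df.insert(0, "longitude", loc_lon)
    env_df.insert(0, "latitude", loc_lat)
    env_df.insert(0, "ecoregion", [er_ids[e] for e in loc_er])
    env_df.insert(0, "location_id", loc_ids)

    # --- species: scores, taxonomy, latent traits ----------------------
    home = rng.integers(0, nE, nS)
    size_scores = L[home] + rng.normal(0.0, cfg.score_noise_sd, nS)
    econ_scores = M[home] + rng.normal(0.0, cfg.score_noise_sd, nS)
    sp_ids = [f"sp{i + 1:05d}" for i in range(nS)]
    n_gen = max(1, nS // 5)
    n_fam = max(1, n_gen // 4)
    genus_idx = (np.arange(nS) * n_gen) // nS
    family_idx = (genus_idx * n_fam) // n_gen
    higher = np.where(family_idx % 2 == 0, "cladeA", "cladeB")

    gen_eff = rng.normal(0.0, cfg.taxon_sd, (n_gen, nT))
    fam_eff = rng.normal(0.0, cfg.taxon_sd, (n_fam, nT))
    mu = rng.normal(0.0, cfg.trait_scale_sd, nT)
    log_traits = (
        mu
        + np.outer(size_scores, cfg.size_loadings)
        + np.outer(econ_scores, cfg.econ_loadings)
        + gen_eff[genus_idx]
        + fam_eff[family_idx]
        + rng.normal(0.0, cfg.species_resid_sd, (nS, nT))
    )

    # --- occupancy: home plus (L, F)-similar ecoregions ----------------
    intensity = rng.lognormal(0.0, cfg.sampling_bias_sd, nE)
    tau2 = 2.0 * cfg.occupancy_tau**2
    pairs_s: list[int] = []
    pairs_e: list[int] = []
    for s in range(nS):
        occ = {int(home[s])}
        k = int(rng.poisson(cfg.mean_extra_ecoregions))
        k = min(k, nE - 1)
        if k > 0:
            d2 = (L - L[home[s]]) ** 2 + (F - F[home[s]]) ** 2
            wts = np.exp(-d2 / tau2)
            wts[home[s]] = 0.0
            tot = wts.sum()
            if tot > 0:
                extra = rng.choice(nE, size=k, replace=False, p=wts / tot)
                occ.update(int(e) for e in extra)
        for e in sorted(occ):
            pairs_s.append(s)
            pairs_e.append(e)
    pairs_s_arr = np.asarray(pairs_s)
    pairs_e_arr = np.asarray(pairs_e)

    # --- observations ---------------------------------------------------
    rate = rng.lognormal(cfg.obs_log_mean, cfg.obs_log_sd, len(pairs_s_arr))
    n_obs = 1 + rng.poisson(rate * intensity[pairs_e_arr])
    n_obs = np.minimum(n_obs, cfg.max_obs_per_pair)
    obs_s = np.repeat(pairs_s_arr, n_obs)
    obs_e = np.repeat(pairs_e_arr, n_obs)
    n_total = len(obs_s)
    obs_loc_k = rng.integers(0, nL, n_total)
    obs_loc_idx = obs_e * nL + obs_loc_k

    values = log_traits[obs_s] + rng.normal(0.0, cfg.trait_noise_sd, (n_total, nT))
    signed_idx = (
        cfg.trait_names.index(cfg.signed_trait) if cfg.signed_trait is not None else -1
    )
    positive = np.ones(nT, dtype=bool)
    if signed_idx >= 0:
        positive[signed_idx] = False
    values[:, positive] = np.exp(values[:, positive])

    obs_df = pd.DataFrame(values, columns=list(cfg.trait_names))
    obs_df.insert(0, "longitude", np.asarray(loc_lon)[obs_loc_idx])
    obs_df.insert(0, "latitude", np.asarray(loc_lat)[obs_loc_idx])
    obs_df.insert(0, "location_id", [loc_ids[i] for i in obs_loc_idx])
    obs_df.insert(0, "ecoregion", [er_ids[e] for e in obs_e])
    obs_df.insert(0, "higher", higher[obs_s])
    obs_df.insert(0, "family", [f"fam{family_idx[s] + 1:03d}" for s in obs_s])
    obs_df.insert(0, "genus", [f"gen{genus_idx[s] + 1:04d}" for s in obs_s])
    obs_df.insert(0, "species", [sp_ids[s] for s in obs_s])
    obs_df.insert(0, "obs_id", [f"obs{i + 1:07d}" for i in range(n_total)])

    # --- ecoregion metadata --------------------------------------------
    n_sp_er = (
        pd.Series(pairs_e_arr).value_counts().reindex(range(nE), fill_value=0).to_numpy()
    )
    factor = rng.lognormal(np.log(20.0), 1.0, nE)
    richness = np.ceil(np.maximum(n_sp_er, 5) * factor).astype(int)
    eco_df = pd.DataFrame(
        {
            "ecoregion": er_ids,
            "latitude": lat,
            "longitude": lon,
            "biome": _biome(abs_lat),
            "richness_estimate": richness,
        }
    )

    truth = WorldTruth(
        ecoregion_ids=er_ids,
        latitudes=lat,
        lat_factor=L,
        fertility=F,
        soil_driver=M,
        species_ids=sp_ids,
        size_scores=size_scores,
        econ_scores=econ_scores,
        species_log_traits=log_traits,
        climate_loadings=a,
        soil_loadings=b,
        config=cfg,
    )

    if cfg.missing_rate > 0:
        obs_df = inject_missingness(
            obs_df, cfg.missing_rate, seed=cfg.seed + 1, trait_cols=list(cfg.trait_names)
        )
    return obs_df, env_df, eco_df, truth


def inject_missingness(
    obs: pd.DataFrame,
    rate: float,
    seed: int,
    trait_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Blank out ~``rate`` of trait cells, keeping >=1 value per row and column.

    The realized missing count is exactly ``round(rate * n_cells)`` (up to
    the protected-cell constraint); deterministic under ``seed``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate!r}")
    out = obs.copy()
    if trait_cols is None:
        trait_cols = [c for c in obs.columns if obs[c].dtype.kind == "f"]
    mat = out[list(trait_cols)].to_numpy(dtype=float)
    n, p = mat.shape
    observed = np.isfinite(mat)
    if (~observed).all(axis=1).any() or (~observed).all(axis=0).any():
        raise ValueError(
            "input already violates the >=1-value-per-row/column requirement"
        )
    if rate == 0.0:
        return out

    rng = np.random.default_rng(seed)
    target = int(round(rate * n * p))
    # protect one observed cell per row, then one per uncovered column
    protected = np.zeros_like(observed)
    for i in range(n):
        cols = np.flatnonzero(observed[i])
        protected[i, rng.choice(cols)] = True
    for j in range(p):
        if not protected[:, j].any():
            rows = np.flatnonzero(observed[:, j])
            protected[rng.choice(rows), j] = True
    eligible = np.flatnonzero(observed.ravel() & ~protected.ravel())
    already_missing = int((~observed).sum())
    need = target - already_missing
    if need > len(eligible):
        raise ValueError(
            f"missingness rate {rate} unsatisfiable: would leave an empty "
            "row or trait column"
        )
    if need > 0:
        kill = rng.choice(eligible, size=need, replace=False)
        flat = mat.ravel()
        flat[kill] = np.nan
        mat = flat.reshape(n, p)
    out[list(trait_cols)] = mat
    return out


def truth_summary(truth: WorldTruth) -> pd.DataFrame:
    """Per-trait generative group and expected dominant environmental driver.

    Size traits track the latitude-linked climate factor, hence driver
    "climate".  Economics traits track the soil driver, whose information
    is shared with climate in proportion to ``shared_latent_weight``:
    below 0.5 the soil block holds mostly private information
    ("soil-independent"), from 0.5 up the two blocks are largely
    redundant ("joint").
    """
    w = truth.config.shared_latent_weight
    rows = []
    for name, group in truth.trait_groups.items():
        if group == "size":
            driver = "climate"
        elif group == "economics":
            driver = "joint" if w >= 0.5 else "soil-independent"
        else:
            driver = "none"
        rows.append({"trait": name, "group": group, "expected_driver": driver})
    return pd.DataFrame(rows)


_SCHEMA = {
    "observations.tsv": {
        "obs_id": "unique observation id",
        "species": "species id",
        "genus": "genus id",
        "family": "family id",
        "higher": "higher clade label",
        "ecoregion": "ecoregion id",
        "location_id": "sampling-location id (key into environment.tsv)",
        "latitude": "decimal degrees",
        "longitude": "decimal degrees",
        "<trait columns>": "one column per trait; empty field = missing",
    },
    "environment.tsv": {
        "location_id": "sampling-location id",
        "ecoregion": "ecoregion id",
        "latitude": "decimal degrees",
        "longitude": "decimal degrees",
        "clim_*": "climate variables",
        "soil_p*_d*": "soil variables; suffix _d<k> is the depth layer, _d0 = topsoil",
    },
    "ecoregions.tsv": {
        "ecoregion": "ecoregion id",
        "latitude": "representative latitude (decimal degrees)",
        "longitude": "representative longitude (decimal degrees)",
        "biome": "biome label",
        "richness_estimate": "estimated total species richness",
    },
}


def write_world(
    outdir: str | Path,
    obs: pd.DataFrame,
    env: pd.DataFrame,
    eco: pd.DataFrame,
    truth: WorldTruth | None = None,
) -> None:
    """Write the three tables (tab-delimited, empty field = missing) + schema."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obs.to_csv(outdir / "observations.tsv", sep="\t", index=False)
    env.to_csv(outdir / "environment.tsv", sep="\t", index=False)
    eco.to_csv(outdir / "ecoregions.tsv", sep="\t", index=False)
    (outdir / "schema.json").write_text(json.dumps(_SCHEMA, indent=2))
    if truth is not None:
        summary = truth_summary(truth)
        summary.to_csv(outdir / "truth_summary.tsv", sep="\t", index=False)
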