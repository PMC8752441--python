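"""Aggregation of observations to species-per-ecoregion (A1) and
ecoregion (A2) tables, with inclusion filters and observation-weighted
environment averaging."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "species_medians",
    "ecoregion_medians",
    "aggregate_environment",
]


def species_medians(
    obs: pd.DataFrame,
    trait_cols: Sequence[str],
    species_col: str = "species",
    ecoregion_col: str = "ecoregion",
    latitude_col: str = "latitude",
) -> pd.DataFrame:
    """Species-median trait vectors per ecoregion (the A1 table).

    One output row per distinct (species, ecoregion) pair: per-trait
    median over that pair's non-missing observations, the mean
    observation latitude as representative latitude, and the observation
    count.
    """
    for col in (species_col, ecoregion_col):
        if col not in obs.columns:
            raise ValueError(f"observation table lacks required column '{col}'")
        if obs[col].isna().any():
            raise ValueError(
                f"observations with missing '{col}' are not allowed; "
                "non-georeferenced/unassigned rows must be excluded upstream"
            )
    grouped = obs.groupby([species_col, ecoregion_col], sort=True)
    a1 = grouped[list(trait_cols)].median()
    if latitude_col in obs.columns:
        a1["latitude"] = grouped[latitude_col].mean()
    a1["n_observations"] = grouped.size()
    return a1.reset_index()


def ecoregion_medians(
    a1: pd.DataFrame,
    richness: Mapping[str, float] | pd.Series,
    trait_cols: Sequence[str],
    min_species: int = 20,
    min_fraction: float = 0.01,
    species_col: str = "species",
    ecoregion_col: str = "ecoregion",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ecoregion medians of species medians (A2) with inclusion filters.

    An ecoregion is kept only if it holds strictly more than
    ``min_species`` species AND those represent strictly more than
    ``min_fraction`` of its richness estimate.

    Returns ``(a2, exclusions)`` where ``exclusions`` lists one row per
    (excluded ecoregion, failed criterion).
    """
    richness = pd.Series(richness)
    grouped = a1.groupby(ecoregion_col, sort=True)
    med = grouped[list(trait_cols)].median()
    n_species = grouped[species_col].nunique()
    missing = med.index.difference(richness.index)
    if len(missing):
        raise ValueError(f"no richness estimate for ecoregion {missing[0]!r}")
    rich = richness.loc[med.index].astype(float)
    frac = n_species / rich

    keep = (n_species > min_species) & (frac > min_fraction)
    excl_rows = []
    for er in med.index[~keep]:
        if not n_species.loc[er] > min_species:
            excl_rows.append(
                {
                    "ecoregion": er,
                    "criterion": f"n_species > {min_species}",
                    "value": int(n_species.loc[er]),
                }
            )
        if not frac.loc[er] > min_fraction:
            excl_rows.append(
                {
                    "ecoregion": er,
                    "criterion": f"richness fraction > {min_fraction}",
                    "value": float(frac.loc[er]),
                }
            )
    a2 = med.loc[keep].copy()
    a2["n_species"] = n_species.loc[keep]
    a2["richness_estimate"] = rich.loc[keep]
    exclusions = pd.DataFrame(excl_rows, columns=["ecoregion", "criterion", "value"])
    return a2.reset_index(), exclusions


def aggregate_environment(
    obs: pd.DataFrame,
    env: pd.DataFrame,
    env_cols: Sequence[str] | None = None,
    location_col: str = "location_id",
    ecoregion_col: str = "ecoregion",
) -> pd.DataFrame:
    """Per-ecoregion mean environment over trait-observation locations.

    Each observation contributes its location's environment values, so
    densely sampled locations weigh proportionally more.
    """
    if env_cols is None:
        env_cols = [
            c
            for c in env.columns
            if c not in (location_col, ecoregion_col) and env[c].dtype.kind == "f"
        ]
    env_keyed = env.set_index(location_col)
    unknown = obs.loc[~obs[location_col].isin(env_keyed.index), location_col]
    if len(unknown):
        raise ValueError(
            f"no environment values for observation location {unknown.iloc[0]!r}"
        )
    joined = obs[[ecoregion_col, location_col]].join(
        env_keyed[list(env_cols)], on=location_col
    )
    return joined.groupby(ecoregion_col, sort=True)[list(env_cols)].mean().reset_index()
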