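"""Synthetic donor-population generator.

Emulates a returning whole-blood donor cohort: sex, age, ethnicity, ABO/RhD
blood group, an index-donation hemoglobin measured by hematology analyzer,
and a hidden donor-level recovery offset.  Every downstream stage of the
pipeline (recovery modelling, policies, the event simulation) is testable on
these cohorts without any external data.

Populations are plain pandas DataFrames with columns
``id, sex, age, ethnicity, blood_group, index_hb, latent_offset``.
``latent_offset`` is simulation-internal state (the realization of the
donor's random intercept); it is regenerated from a seed, never serialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import ConfigurationError, PopulationConfig, _packaged_defaults
from .recovery import RecoveryModel, linear_predictor_frame

__all__ = [
    "Donor",
    "COLUMNS",
    "generate_reference_population",
    "resample_population",
    "redraw_latent_offsets",
    "generate_two_visit_dataset",
    "read_donor_table",
    "write_donor_table",
]

COLUMNS = ["id", "sex", "age", "ethnicity", "blood_group", "index_hb", "latent_offset"]

# Columns serialized to donor-table CSVs (latent state stays internal).
CSV_COLUMNS = ["id", "sex", "age", "ethnicity", "blood_group", "index_hb"]


@dataclass(frozen=True)
class Donor:
    """One simulated donor; attribute layout matches a population-table row."""

    id: int
    sex: str
    age: float
    ethnicity: str
    blood_group: str
    index_hb: float
    latent_offset: float = 0.0

    def __post_init__(self):
        if self.index_hb <= 0:
            raise ConfigurationError("index hemoglobin must be positive")
        if self.age < 18:
            raise ConfigurationError("donors must be at least 18")


def _truncated_normal(rng, mean, sd, lower, upper, size):
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _latent_sds(latent_sd, params) -> dict:
    if latent_sd is None:
        rec = (params or _packaged_defaults())["recovery"]
        return {sex: float(rec[sex]["latent_sd"]) for sex in rec}
    if isinstance(latent_sd, dict):
        return dict(latent_sd)
    return {"female": float(latent_sd), "male": float(latent_sd)}


def generate_reference_population(
    config: PopulationConfig,
    latent_sd: float | dict | None = None,
    params: dict | None = None,
) -> pd.DataFrame:
    """Draw a reference cohort of ``config.n`` donors.

    Covariates are drawn independently from the configured category
    frequencies; index hemoglobin from the sex-specific truncated normal;
    the latent recovery offset from N(0, latent_sd) (default: the packaged
    recovery model's between-donor sd for that sex).  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    sexes = sorted(config.sex_mix)
    sex = rng.choice(sexes, size=n, p=[config.sex_mix[s] for s in sexes])

    age = np.empty(n)
    index_hb = np.empty(n)
    latent = np.empty(n)
    sds = _latent_sds(latent_sd, params)
    for s in sexes:  # fixed stratum order keeps draws reproducible
        mask = sex == s
        k = int(mask.sum())
        dist = config.distributions[s]
        age[mask] = _truncated_normal(rng, dist.age_mean, dist.age_sd, dist.age_min, dist.age_max, k)
        index_hb[mask] = _truncated_normal(
            rng, dist.index_hb_mean, dist.index_hb_sd, dist.index_hb_floor, np.inf, k
        )
        latent[mask] = rng.normal(0.0, sds.get(s, 0.0), size=k) if sds.get(s, 0.0) > 0 else 0.0

    eth_levels = sorted(config.ethnicity_freqs)
    ethnicity = rng.choice(eth_levels, size=n, p=[config.ethnicity_freqs[e] for e in eth_levels])
    bg_levels = sorted(config.blood_group_freqs)
    blood_group = rng.choice(bg_levels, size=n, p=[config.blood_group_freqs[g] for g in bg_levels])

    return pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "age": age,
            "ethnicity": ethnicity,
            "blood_group": blood_group,
            "index_hb": index_hb,
            "latent_offset": latent,
        }
    )


def resample_population(reference: pd.DataFrame, m: int, seed: int) -> pd.DataFrame:
    """Sample ``m`` donors with replacement from a reference cohort.

    Rows are copied whole, so the joint covariate structure of the reference
    (correlations between age, ethnicity, blood group and index hemoglobin)
    is preserved exactly.  Resampled donors get fresh sequential ids.
    """
    if len(reference) == 0:
        raise ValueError("cannot resample from an empty reference population")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(reference), size=m)
    out = reference.iloc[idx].reset_index(drop=True)
    out["id"] = np.arange(m, dtype=np.int64)
    return out


def redraw_latent_offsets(
    population: pd.DataFrame, latent_sd: float | dict, seed: int
) -> pd.DataFrame:
    """Fresh latent offsets (e.g., under a perturbed between-donor sd)."""
    rng = np.random.default_rng(seed)
    sds = latent_sd if isinstance(latent_sd, dict) else {s: latent_sd for s in ("female", "male")}
    out = population.copy()
    latent = np.zeros(len(out))
    for s in sorted(out["sex"].unique()):
        mask = (out["sex"] == s).to_numpy()
        sd = float(sds.get(s, 0.0))
        if sd > 0:
            latent[mask] = rng.normal(0.0, sd, size=int(mask.sum()))
    out["latent_offset"] = latent
    return out


def generate_two_visit_dataset(
    model: RecoveryModel,
    donors: pd.DataFrame,
    return_times,
    seed: int = 0,
) -> pd.DataFrame:
    """Index + one return measurement per donor, for fitting tests.

    The return hemoglobin is the model's linear predictor at the donor's
    return time plus the donor's latent offset plus fresh residual noise.
    ``return_times`` may be a scalar (weeks) or one value per donor.
    """
    rng = np.random.default_rng(seed)
    t = np.broadcast_to(np.asarray(return_times, float), (len(donors),)).copy()
    if np.any(t < 0):
        raise ValueError("return times must be non-negative")
    mu = linear_predictor_frame(model, donors, t)
    noise = rng.normal(0.0, model.residual_sd, size=len(donors)) if model.residual_sd > 0 else 0.0
    out = donors[["id", "sex", "age", "ethnicity", "blood_group", "index_hb"]].copy()
    out["t_weeks"] = t
    out["return_hb"] = mu + donors["latent_offset"].to_numpy(float) + noise
    return out


def write_donor_table(population: pd.DataFrame, path) -> None:
    """Serialize a donor table to CSV (hidden latent state is dropped)."""
    population[CSV_COLUMNS].to_csv(path, index=False)


def read_donor_table(path, latent_sd: float | dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Read a donor-table CSV; latent offsets are regenerated from ``seed``."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"donor table is missing columns {missing}")
    df["latent_offset"] = 0.0
    sds = _latent_sds(latent_sd, None)
    return redraw_latent_offsets(df, sds, seed)
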