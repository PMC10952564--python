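"""Parameter containers and the packaged default parameter set.

Every numeric constant in the simulation — donation thresholds, recall
floors, certainty levels, deferral intervals, unit costs, recovery-model
coefficients, behavioral rates and population distributions — lives in the
packaged ``data/defaults.yaml`` and can be overridden from a user YAML file.
This module loads that file and exposes typed accessors for the simple
parameter blocks; the recovery model itself lives in
:mod:`donorsim.recovery`.
"""

from __future__ import annotations

import copy
import functools
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import yaml

SEXES = ("female", "male")

__all__ = [
    "SEXES",
    "ThresholdSpec",
    "DeferralRules",
    "CostTable",
    "BehaviorParams",
    "PopulationConfig",
    "defaults",
    "load_parameters",
    "thresholds_for",
    "deferral_rules",
    "cost_table",
    "behavior_for",
    "population_config",
    "config_hash",
]


class ConfigurationError(ValueError):
    """Raised when a parameter block fails validation."""


@functools.cache
def _packaged_defaults() -> dict:
    text = resources.files("donorsim").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def defaults() -> dict:
    """A deep copy of the packaged default parameter dictionary."""
    return copy.deepcopy(_packaged_defaults())


def load_parameters(path=None, overrides: Mapping | None = None) -> dict:
    """Packaged defaults, deep-merged with a user YAML file and/or a dict."""
    params = _packaged_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config file {path!r} must contain a mapping")
        params = _deep_merge(params, user)
    if overrides:
        params = _deep_merge(params, overrides)
    return copy.deepcopy(params)


def config_hash(params: Mapping) -> str:
    """Stable SHA-256 over the canonical YAML form of a parameter dict."""
    canon = yaml.safe_dump(params, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ConfigurationError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return sex


@dataclass(frozen=True)
class ThresholdSpec:
    """Donation threshold and the 'very low' cut-off triggering a 52-week deferral.

    England uses 125 g/L (women) and 135 g/L (men) as the minimum hemoglobin
    to donate; a measured value more than 10 g/L below that (115/125 g/L)
    earns the long deferral.
    """

    donation_threshold: float
    severe_low: float

    def __post_init__(self):
        if not self.severe_low < self.donation_threshold:
            raise ConfigurationError(
                f"severe_low ({self.severe_low}) must be below the donation "
                f"threshold ({self.donation_threshold})"
            )


@dataclass(frozen=True)
class DeferralRules:
    """Fixed re-invitation intervals (weeks) after each deferral type."""

    low_hb_weeks: int = 12
    low_hb_severe_weeks: int = 52
    other_weeks: int = 4

    def __post_init__(self):
        if self.low_hb_severe_weeks < self.low_hb_weeks:
            raise ConfigurationError("severe low-Hb deferral must be at least the standard one")


@dataclass(frozen=True)
class CostTable:
    """Unit costs to the blood service, GBP (2019 prices).

    Money is handled internally in integer pence so that total cost is an
    exact sum of unit costs times event counts.
    """

    onsite_test: float = 1.08
    offsite_test: float = 0.79
    donation: float = 26.49
    deferral_low_hb: float = 9.21
    deferral_other: float = 0.97

    def __post_init__(self):
        for name in ("onsite_test", "offsite_test", "donation", "deferral_low_hb", "deferral_other"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cost {name} must be non-negative")

    def pence(self, name: str) -> int:
        return round(getattr(self, name) * 100)


@dataclass(frozen=True)
class BehaviorParams:
    """Donor-behavior and screening-error parameters for one sex stratum.

    dropout_prob
        Probability that an invited donor never attends (lapses), per
        invitation.
    other_deferral_prob
        Probability that an attendee is deferred for a reason unrelated to
        hemoglobin, per attendance.
    delay_mean_weeks / delay_cap_weeks
        Attendance happens at the invited week plus a geometric whole-week
        delay with this mean, capped.
    onsite_sigma / onsite_offset
        Parameters of the on-site false-pass curve: a donor whose true
        hemoglobin sits ``d`` g/L below threshold still passes screening
        with probability ``1/(1 + exp(d/onsite_sigma - onsite_offset))``.
    hemocue_over_fraction
        Under the current strategy the venous-HemoCue cost is charged to
        attendees who fail the initial gravimetric screen; by default all
        truly-under donors plus this fraction of over-threshold donors.
    """

    dropout_prob: float
    other_deferral_prob: float
    delay_mean_weeks: float = 2.0
    delay_cap_weeks: int = 36
    onsite_sigma: float = 4.0
    onsite_offset: float = 2.0
    hemocue_over_fraction: float = 0.10
    ses: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("dropout_prob", "other_deferral_prob", "hemocue_over_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.delay_mean_weeks < 0:
            raise ConfigurationError("delay_mean_weeks must be non-negative")


@dataclass(frozen=True)
class SexDistribution:
    """Index-Hb and age marginals for one sex."""

    index_hb_mean: float
    index_hb_sd: float
    index_hb_floor: float = 100.0
    age_mean: float = 43.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 75.0

    def __post_init__(self):
        if self.index_hb_sd <= 0 or self.age_sd <= 0:
            raise ConfigurationError("distribution sd must be positive")
        if self.age_min < 18:
            raise ConfigurationError("donors must be at least 18")


def _check_freqs(name: str, freqs: Mapping[str, float]) -> dict:
    if not freqs:
        raise ConfigurationError(f"{name} frequencies are empty")
    total = sum(freqs.values())
    if any(v < 0 for v in freqs.values()) or abs(total - 1.0) > 1e-6:
        raise ConfigurationError(f"{name} frequencies must be non-negative and sum to 1 (got {total})")
    return dict(freqs)


@dataclass(frozen=True)
class PopulationConfig:
    """Everything needed to draw a synthetic reference cohort."""

    n: int
    sex_mix: Mapping[str, float]
    distributions: Mapping[str, SexDistribution]
    ethnicity_freqs: Mapping[str, float]
    blood_group_freqs: Mapping[str, float]
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("population size must be non-negative")
        object.__setattr__(self, "sex_mix", _check_freqs("sex_mix", self.sex_mix))
        for sex in self.sex_mix:
            _check_sex(sex)
            if sex not in self.distributions:
                raise ConfigurationError(f"no index-Hb/age distribution for sex {sex!r}")
        object.__setattr__(self, "ethnicity_freqs", _check_freqs("ethnicity", self.ethnicity_freqs))
        object.__setattr__(self, "blood_group_freqs", _check_freqs("blood_group", self.blood_group_freqs))


# ---------------------------------------------------------------------------
# Typed accessors over a (possibly merged) parameter dictionary.

def thresholds_for(sex: str, params: Mapping | None = None) -> ThresholdSpec:
    params = params or _packaged_defaults()
    block = params["thresholds"][_check_sex(sex)]
    return ThresholdSpec(**block)


def deferral_rules(params: Mapping | None = None) -> DeferralRules:
    params = params or _packaged_defaults()
    return DeferralRules(**params["deferral_rules"])


def cost_table(params: Mapping | None = None) -> CostTable:
    params = params or _packaged_defaults()
    return CostTable(**params["costs"])


def behavior_for(sex: str, params: Mapping | None = None) -> BehaviorParams:
    params = params or _packaged_defaults()
    return BehaviorParams(**params["behavior"][_check_sex(sex)])


def population_config(
    params: Mapping | None = None,
    *,
    n: int | None = None,
    sex: str | None = None,
    seed: int | None = None,
) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from a parameter dict.

    ``sex`` forces a single-sex cohort (the simulation's normal mode —
    strategies and recovery models are sex-stratified).
    """
    params = params or _packaged_defaults()
    block = params["population"]
    mix = {sex: 1.0} if sex is not None else dict(block["sex_mix"])
    dists = {
        s: SexDistribution(**block[s])
        for s in SEXES
        if s in block
    }
    return PopulationConfig(
        n=n if n is not None else int(block["n"]),
        sex_mix=mix,
        distributions=dists,
        ethnicity_freqs=block["ethnicity_freqs"],
        blood_group_freqs=block["blood_group_freqs"],
        seed=seed if seed is not None else int(block.get("seed", 0)),
    )
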