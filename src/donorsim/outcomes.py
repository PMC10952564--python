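"""Costing, outcome summaries, bootstrap uncertainty and internal validation.

Event counts are reported per 1000 donors over the one-year horizon; costs
are held in integer pence so total cost is an exact sum of unit costs times
event counts; the mean cost per donation and the donations-per-adverse-event
ratio follow the published reporting conventions (2 d.p. GBP; ratios to
1 d.p.; percent differences to the nearest integer).

An *adverse event* is an inappropriate bleed (donation under the threshold)
or a low-hemoglobin deferral.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (
    BehaviorParams,
    CostTable,
    DeferralRules,
    ThresholdSpec,
    _packaged_defaults,
)
from .engine import DEFERRED_LOW, DONATED, EventLog, VisitEvent, run_population
from .policies import StrategySpec, make_strategy
from .population import redraw_latent_offsets, resample_population
from .recovery import RecoveryModel

__all__ = [
    "INTERVAL_BANDS",
    "OutcomeSummary",
    "UncertaintySummary",
    "cost_event",
    "apply_costs",
    "summarize",
    "donations_per_adverse_event",
    "first_return_mode",
    "observed_first_return",
    "published_predicted_first_return",
    "validation_report",
    "perturb_parameters",
    "bootstrap_uncertainty",
]

# Inter-donation interval bands (weeks) used in reporting, by sex.
INTERVAL_BANDS = {
    "female": (("12", 12, 12), ("13-15", 13, 15), ("16", 16, 16), ("17-23", 17, 23), ("24+", 24, None)),
    "male": (("8", 8, 8), ("9-11", 9, 11), ("12", 12, 12), ("13-17", 13, 17), ("18+", 18, None)),
}

VALIDATION_CATEGORIES = (
    "dropout",
    "returned",
    "other_deferrals",
    "donations_over",
    "donations_under",
    "low_hb_deferrals",
)


def cost_event(event: VisitEvent, strategy: StrategySpec, costs: CostTable) -> int:
    """Cost of one visit event, in integer pence.

    Donations cost the donation unit cost, plus the off-site analyzer test
    under post-donation strategies (every donation is Sysmex-tested), plus
    the on-site test where one was costed (strategy A's HemoCue slice, or a
    tested attendance under E).  Deferrals carry their own bundled unit
    costs; lapses and pending invitations cost nothing.
    """
    out = event.outcome
    if out in DONATED:
        pence = costs.pence("donation")
        if strategy.personalized:
            pence += costs.pence("offsite_test")
        if event.hemocue_costed:
            pence += costs.pence("onsite_test")
        return pence
    if out in DEFERRED_LOW:
        return costs.pence("deferral_low_hb")
    if out == "deferred_other":
        return costs.pence("deferral_other")
    if out in ("lapsed", "pending"):
        return 0
    raise ValueError(f"unknown outcome {out!r}")


def apply_costs(log: EventLog, strategy: StrategySpec | None = None, costs: CostTable | None = None) -> int:
    """Fill ``cost_pence`` on every event; returns the total in pence."""
    strategy = strategy or make_strategy(log.meta["strategy"])
    costs = costs or CostTable()
    total = 0
    for ev in log.events:
        ev.cost_pence = cost_event(ev, strategy, costs)
        total += ev.cost_pence
    return total


@dataclass
class OutcomeSummary:
    """Per-1000 event counts, headline ratios and the interval-band mix."""

    strategy: str
    sex: str
    n: int
    scale_to: int
    counts: Mapping[str, float]          # per-scale_to counts by category
    adverse_events: float                # per-scale_to
    donations_total: float               # per-scale_to, excluding the index donation
    donations_per_adverse_event: float   # ratio (nan when no adverse events)
    mean_cost_per_donation: float        # GBP (nan when no donations)
    total_cost_gbp: float                # per-scale_to
    band_distribution: Mapping[str, float] = field(default_factory=dict)
    raw: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "sex": self.sex,
            "n": self.n,
            "scale_to": self.scale_to,
            "counts": dict(self.counts),
            "adverse_events": self.adverse_events,
            "donations_total": self.donations_total,
            "donations_per_adverse_event": self.donations_per_adverse_event,
            "mean_cost_per_donation": self.mean_cost_per_donation,
            "total_cost_gbp": self.total_cost_gbp,
            "band_distribution": dict(self.band_distribution),
            "raw": dict(self.raw),
        }

    def summary(self) -> str:
        """Aligned text table of the per-1000 counts and headline figures."""
        lines = [
            f"Strategy {self.strategy} ({self.sex}, n={self.n}, scaled to {self.scale_to})",
            "-" * 56,
        ]
        for key in (
            "invitations", "return_visits", "lapses", "donations_over", "donations_under",
            "low_hb_deferrals", "other_deferrals", "pending",
        ):
            lines.append(f"{key:<28}{self.counts[key]:>10.1f}")
        lines.append(f"{'adverse events':<28}{self.adverse_events:>10.1f}")
        lines.append(f"{'total donations (excl index)':<28}{self.donations_total:>10.1f}")
        dpae = self.donations_per_adverse_event
        lines.append(f"{'donations / adverse event':<28}{dpae:>10.1f}" if not math.isnan(dpae)
                     else f"{'donations / adverse event':<28}{'--':>10}")
        cost = self.mean_cost_per_donation
        lines.append(f"{'mean cost per donation':<28}{'£' + format(cost, '.2f'):>10}" if not math.isnan(cost)
                     else f"{'mean cost per donation':<28}{'--':>10}")
        lines.append("interval bands (non-deferral recall invitations):")
        for label, frac in self.band_distribution.items():
            lines.append(f"  {label + ' weeks':<26}{frac:>9.1%}")
        return "\n".join(lines)


def _band_distribution(df: pd.DataFrame, sex: str, horizon: int) -> dict:
    """Share of recall invitations per interval band.

    Counts post-donation recall invitations issued before the horizon;
    re-invitations after a deferral are excluded, per the reporting
    convention.
    """
    mask = (~df["post_deferral"]) & (df["invitation_day"] < horizon)
    weeks = df.loc[mask, "interval_weeks"]
    total = len(weeks)
    dist = {}
    for label, lo, hi in INTERVAL_BANDS[sex]:
        sel = (weeks >= lo) if hi is None else ((weeks >= lo) & (weeks <= hi))
        dist[label] = float(sel.sum() / total) if total else 0.0
    return dist


def summarize(
    log: EventLog,
    costs: CostTable | None = None,
    scale_to: int = 1000,
    strategy: StrategySpec | None = None,
) -> OutcomeSummary:
    """Reduce an event log to per-1000 counts, ratios, costs and bands."""
    if len(log) == 0:
        raise ValueError("event log is empty")
    strategy = strategy or make_strategy(log.meta["strategy"])
    costs = costs or CostTable()
    total_pence = apply_costs(log, strategy, costs)
    df = log.to_dataframe()
    n = int(log.meta["n"])
    sex = log.meta["sex"]
    horizon = int(log.meta.get("horizon", 365))
    k = scale_to / n

    by_outcome = df["outcome"].value_counts()
    raw = {
        "invitations": len(df),
        "lapses": int(by_outcome.get("lapsed", 0)),
        "pending": int(by_outcome.get("pending", 0)),
        "donations_over": int(by_outcome.get("donated_over", 0)),
        "donations_under": int(by_outcome.get("donated_under", 0)),
        "low_hb_deferrals": int(by_outcome.get("deferred_low_hb", 0) + by_outcome.get("deferred_low_hb_severe", 0)),
        "other_deferrals": int(by_outcome.get("deferred_other", 0)),
    }
    raw["return_visits"] = raw["invitations"] - raw["lapses"] - raw["pending"]
    donations = raw["donations_over"] + raw["donations_under"]
    adverse = raw["donations_under"] + raw["low_hb_deferrals"]

    counts = {key: val * k for key, val in raw.items()}
    dpae = donations / adverse if adverse else math.nan
    mean_cost = total_pence / donations / 100.0 if donations else math.nan

    return OutcomeSummary(
        strategy=strategy.name,
        sex=sex,
        n=n,
        scale_to=scale_to,
        counts=counts,
        adverse_events=adverse * k,
        donations_total=donations * k,
        donations_per_adverse_event=dpae,
        mean_cost_per_donation=mean_cost,
        total_cost_gbp=total_pence / 100.0 * k,
        band_distribution=_band_distribution(df, sex, horizon),
        raw=raw,
    )


def donations_per_adverse_event(
    donations_over: float, donations_under: float, low_hb_deferrals: float
) -> float:
    """(all donations) / (under-threshold donations + low-Hb deferrals).

    NaN when there are no adverse events.
    """
    denom = donations_under + low_hb_deferrals
    if denom == 0:
        return math.nan
    return (donations_over + donations_under) / denom


# ---------------------------------------------------------------------------
# Internal validation (first-return mode)


def first_return_mode(
    population: pd.DataFrame,
    model: RecoveryModel,
    behavior: BehaviorParams,
    rules: DeferralRules,
    thresholds: ThresholdSpec,
    seed: int = 0,
    *,
    female_floor_weeks: int = 12,
    params: Mapping | None = None,
) -> EventLog:
    """Current-strategy run restricted to each donor's first return.

    Mirrors the internal-validation design: one invitation cycle per donor
    under the fixed-interval strategy, with the women's floor lowered to 12
    weeks so that the early-return window seen in practice (women returning
    between 12 and 16 weeks) is represented.
    """
    strategy = make_strategy("A", params)
    sex = population["sex"].unique()
    floor = female_floor_weeks if list(sex) == ["female"] else None
    log = run_population(
        population, strategy, model, behavior, rules, thresholds, seed,
        max_visits=1, floor_override=floor,
    )
    log.meta["mode"] = "first_return"
    return log


def _validation_table() -> pd.DataFrame:
    text = resources.files("donorsim").joinpath("data/first_return_validation.csv").read_text()
    from io import StringIO

    return pd.read_csv(StringIO(text), comment="#")


def observed_first_return(sex: str) -> pd.Series:
    """Published observed first-return counts per 1000 donors, by category."""
    df = _validation_table()
    sub = df[df["sex"] == sex].set_index("category")["observed"]
    return sub.reindex(VALIDATION_CATEGORIES).astype(float)


def published_predicted_first_return(sex: str) -> pd.Series:
    """The original model's published predicted counts per 1000 donors."""
    df = _validation_table()
    sub = df[df["sex"] == sex].set_index("category")["published_predicted"]
    return sub.reindex(VALIDATION_CATEGORIES).astype(float)


def first_return_counts(summary: OutcomeSummary) -> pd.Series:
    """Map a first-return summary onto the validation categories."""
    c = summary.counts
    return pd.Series(
        {
            "dropout": c["lapses"],
            "returned": c["return_visits"],
            "other_deferrals": c["other_deferrals"],
            "donations_over": c["donations_over"],
            "donations_under": c["donations_under"],
            "low_hb_deferrals": c["low_hb_deferrals"],
        }
    ).reindex(VALIDATION_CATEGORIES)


def validation_report(predicted: pd.Series, observed: pd.Series) -> pd.DataFrame:
    """Predicted vs observed per-1000 counts with integer percent differences.

    The difference column is ``round(100 * (predicted - observed) / observed)``
    per category (NaN where the observed count is zero), plus a
    donations-per-adverse-event ratio row for each side.
    """
    predicted = predicted.reindex(VALIDATION_CATEGORIES).astype(float)
    observed = observed.reindex(VALIDATION_CATEGORIES).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = 100.0 * (predicted - observed) / observed
    diff = pd.Series(
        [round(d) if np.isfinite(d) else math.nan for d in diff], index=predicted.index, dtype=float
    )
    table = pd.DataFrame({"predicted": predicted, "observed": observed, "pct_difference": diff})
    ratio = pd.DataFrame(
        {
            "predicted": [donations_per_adverse_event(
                predicted["donations_over"], predicted["donations_under"], predicted["low_hb_deferrals"]
            )],
            "observed": [donations_per_adverse_event(
                observed["donations_over"], observed["donations_under"], observed["low_hb_deferrals"]
            )],
            "pct_difference": [math.nan],
        },
        index=["donations_per_adverse_event"],
    )
    return pd.concat([table, ratio])


# ---------------------------------------------------------------------------
# Bootstrap uncertainty


@dataclass(frozen=True)
class UncertaintySummary:
    """Median and central 95% range of an outcome across bootstrap draws."""

    point: float
    lower: float
    upper: float
    draws: int

    def __post_init__(self):
        if not (self.lower <= self.point <= self.upper):
            raise ValueError("uncertainty interval must bracket its point estimate")


def perturb_parameters(
    model: RecoveryModel, behavior: BehaviorParams, rng: np.random.Generator
) -> tuple[RecoveryModel, BehaviorParams]:
    """One draw from the parameter sampling distributions.

    Coefficients are perturbed on the natural scale (normal), standard
    deviations on the log scale, probabilities on the logit scale, each
    using the stored standard errors.  Parameters without a standard error
    stay fixed.
    """
    ses = dict(model.ses)
    changes = {}
    for name in ("intercept", "coef_index_hb", "coef_age", "slope"):
        se = ses.get(name, 0.0)
        if se > 0:
            changes[name] = getattr(model, name) + rng.normal(0.0, se)
    for name, se_key in (("latent_sd", "latent_sd_log"), ("residual_sd", "residual_sd_log")):
        se = ses.get(se_key, 0.0)
        if se > 0:
            changes[name] = getattr(model, name) * float(np.exp(rng.normal(0.0, se)))
    model2 = model.replace(**changes) if changes else model

    bses = dict(behavior.ses)
    bchanges = {}
    for name, se_key in (("dropout_prob", "dropout_logit"), ("other_deferral_prob", "other_deferral_logit")):
        se = bses.get(se_key, 0.0)
        p = getattr(behavior, name)
        if se > 0 and 0.0 < p < 1.0:
            bchanges[name] = float(expit(logit(p) + rng.normal(0.0, se)))
    from dataclasses import replace as _replace

    behavior2 = _replace(behavior, **bchanges) if bchanges else behavior
    if not changes and not bchanges:
        warnings.warn(
            "no standard errors supplied; bootstrap draws use fixed parameters",
            stacklevel=2,
        )
    return model2, behavior2


BOOTSTRAP_OUTCOMES = (
    "donations_total",
    "donations_under",
    "low_hb_deferrals",
    "adverse_events",
    "donations_per_adverse_event",
    "mean_cost_per_donation",
)


def bootstrap_uncertainty(
    reference: pd.DataFrame,
    strategy: StrategySpec,
    model: RecoveryModel,
    behavior: BehaviorParams,
    rules: DeferralRules,
    thresholds: ThresholdSpec,
    costs: CostTable | None = None,
    draws: int = 1000,
    size: int = 1000,
    seed: int = 0,
) -> dict[str, UncertaintySummary]:
    """Bootstrap uncertainty intervals for the headline outcomes.

    Per draw: perturb the data-informed parameters, resample ``size`` donors
    with replacement from the reference cohort (latent offsets redrawn under
    the perturbed between-donor sd), simulate a year, and summarize.  The
    point estimate is the median across draws; the interval the 2.5th and
    97.5th percentiles.
    """
    costs = costs or CostTable()
    ss = np.random.SeedSequence(seed)
    results: dict[str, list[float]] = {k: [] for k in BOOTSTRAP_OUTCOMES}
    for draw, child in enumerate(ss.spawn(draws)):
        sub_seeds = child.generate_state(3)
        rng = np.random.default_rng(child)
        m2, b2 = perturb_parameters(model, behavior, rng)
        pop = resample_population(reference, size, int(sub_seeds[0] % (2**31)))
        pop = redraw_latent_offsets(pop, {str(pop["sex"].iloc[0]): m2.latent_sd}, int(sub_seeds[1] % (2**31)))
        log = run_population(pop, strategy, m2, b2, rules, thresholds, int(sub_seeds[2] % (2**31)))
        s = summarize(log, costs, scale_to=1000, strategy=strategy)
        for key in BOOTSTRAP_OUTCOMES:
            if key in ("donations_total", "adverse_events"):
                results[key].append(getattr(s, key))
            elif key in ("donations_per_adverse_event", "mean_cost_per_donation"):
                results[key].append(getattr(s, key))
            else:
                results[key].append(s.counts[key])
    out = {}
    for key, vals in results.items():
        arr = np.asarray(vals, float)
        arr = arr[np.isfinite(arr)]
        if len(arr) == 0:
            continue
        lo, mid, hi = np.percentile(arr, [2.5, 50.0, 97.5])
        out[key] = UncertaintySummary(point=float(mid), lower=float(lo), upper=float(hi), draws=draws)
    return out
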