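"""Recall strategies and re-invitation rules.

Five strategies are modeled:

======  =============================================  ==========  =========
name    description                                    floor f/m   p_min
======  =============================================  ==========  =========
A       current fixed-interval recall, on-site screen  16 / 12     —
B       post-donation testing, medium certainty        16 / 12     0.7
C       post-donation testing, high certainty          16 / 12     0.9
D       high certainty, early recall permitted         12 / 8      0.9
E       medium certainty + on-site test in [0.7, 0.9)  16 / 12     0.7
======  =============================================  ==========  =========

Under A the donor is invited back at a fixed floor and screened on site at
every attendance (at most 4 invitations per year).  Under B–E the next
invitation lands at the personalized interval: the first whole week at
which the modeled probability of being over the donation threshold reaches
p_min (never earlier than the floor, capped at a maximum interval; at most
6 invitations per year).  E additionally administers an on-site test to
attendees whose modeled probability sits in the medium-certainty band.

After a deferral, fixed re-invitation intervals apply: 4 weeks for
non-hemoglobin deferrals, 12 weeks for a low-hemoglobin deferral, 52 weeks
when the modeled hemoglobin is very low (below 115 g/L women / 125 g/L men).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .config import (
    ConfigurationError,
    DeferralRules,
    ThresholdSpec,
    _packaged_defaults,
)
from .recovery import IntervalResult, RecoveryModel, personalized_interval, prob_over_threshold

__all__ = [
    "StrategySpec",
    "STRATEGY_NAMES",
    "make_strategy",
    "next_invitation_time",
    "requires_onsite_test",
    "deferral_reinvite_interval",
]

STRATEGY_NAMES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class StrategySpec:
    """One recall strategy row."""

    name: str
    min_interval: Mapping[str, int]     # floor in weeks, by sex
    p_min: float | None                 # None => fixed-interval recall
    onsite_band: tuple[float, float] | None
    onsite_always: bool
    max_invitations_per_year: int
    max_interval_weeks: int = 52

    def __post_init__(self):
        object.__setattr__(self, "min_interval", dict(self.min_interval))
        if any(v <= 0 for v in self.min_interval.values()):
            raise ConfigurationError("recall floors must be positive")
        if self.onsite_band is not None:
            lo, hi = self.onsite_band
            object.__setattr__(self, "onsite_band", (float(lo), float(hi)))
            if self.p_min is None or abs(lo - self.p_min) > 1e-12:
                raise ConfigurationError(
                    "the on-site band must start at the strategy's certainty level"
                )

    @property
    def personalized(self) -> bool:
        return self.p_min is not None

    def floor(self, sex: str) -> int:
        return int(self.min_interval[sex])

    def replace(self, **changes) -> "StrategySpec":
        return replace(self, **changes)


def make_strategy(name: str, params: Mapping | None = None) -> StrategySpec:
    """Build a strategy from the packaged (or overridden) strategy table."""
    params = params or _packaged_defaults()
    table = params["strategies"]
    if name not in table:
        raise ConfigurationError(f"unknown strategy {name!r}; expected one of {sorted(table)}")
    row = table[name]
    band = row.get("onsite_band")
    return StrategySpec(
        name=name,
        min_interval=row["min_interval"],
        p_min=row.get("p_min"),
        onsite_band=tuple(band) if band else None,
        onsite_always=bool(row.get("onsite_always", False)),
        max_invitations_per_year=int(row["max_invitations_per_year"]),
        max_interval_weeks=int(params.get("max_interval_weeks", 52)),
    )


def next_invitation_time(
    strategy: StrategySpec,
    model: RecoveryModel,
    donor,
    anchor_day: int,
    last_hb: float,
    thresholds: ThresholdSpec,
) -> tuple[int, bool]:
    """Day of the next recall invitation after a donation at ``anchor_day``.

    Fixed strategies invite at the floor; personalized strategies at 7x the
    personalized interval (whole weeks).  Returns ``(day, capped)`` where
    ``capped`` marks a donor whose certainty level was never reached before
    the maximum interval.
    """
    floor = strategy.floor(donor.sex)
    if not strategy.personalized:
        return anchor_day + 7 * floor, False
    interval: IntervalResult = personalized_interval(
        model,
        donor,
        thresholds.donation_threshold,
        strategy.p_min,
        floor,
        strategy.max_interval_weeks,
        last_hb=last_hb,
    )
    return anchor_day + 7 * interval.weeks, interval.capped


def requires_onsite_test(
    strategy: StrategySpec,
    model: RecoveryModel,
    donor,
    anchor_day: int,
    last_hb: float,
    attendance_day: int,
    thresholds: ThresholdSpec,
) -> bool:
    """Whether this attendance gets an on-site hemoglobin screen.

    A tests everyone; B–D never test.  E tests attendees whose modeled
    probability of being over threshold — evaluated at the actual attendance
    time, since late attendance moves the probability — falls in the
    medium-certainty band [0.7, 0.9).
    """
    if strategy.onsite_always:
        return True
    if strategy.onsite_band is None:
        return False
    t = (attendance_day - anchor_day) / 7.0
    p = prob_over_threshold(model, donor, t, thresholds.donation_threshold, last_hb)
    lo, hi = strategy.onsite_band
    return lo <= p < hi


def deferral_reinvite_interval(
    reason: str,
    true_hb: float | None,
    thresholds: ThresholdSpec,
    rules: DeferralRules | None = None,
) -> int:
    """Weeks until re-invitation after a deferral.

    ``reason`` is ``"low_hb"`` or ``"other"``.  Low-hemoglobin deferrals use
    the long interval when the modeled hemoglobin is below the severe cut-off.
    """
    rules = rules or DeferralRules()
    if reason == "other":
        return rules.other_weeks
    if reason == "low_hb":
        if true_hb is None:
            raise ValueError("a low-hemoglobin deferral needs the modeled hemoglobin value")
        if true_hb < thresholds.severe_low:
            return rules.low_hb_severe_weeks
        return rules.low_hb_weeks
    raise ValueError(f"unknown deferral reason {reason!r}")
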