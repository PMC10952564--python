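"""One-year discrete event simulation of donor recall.

Each donor starts with an index donation at day 0 and is then pushed
through invitation → attendance → screening/donation cycles until the next
invitation would fall on or after the one-year horizon (day 365) or the
strategy's invitation cap is reached.  The clock runs in integer days
(1 week = 7 days).  Invitations issued before day 365 are simulated even
when the attendance itself falls after the horizon (such events are
flagged), matching the "all recalls in 1 year" accounting convention.

Randomness contract: every donor gets an independent substream derived from
``(master seed, donor id)``, so population size and iteration order never
perturb an individual donor's trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import BehaviorParams, DeferralRules, ThresholdSpec
from .policies import StrategySpec, deferral_reinvite_interval, next_invitation_time, requires_onsite_test
from .recovery import RecoveryModel, simulate_true_hb

__all__ = [
    "OUTCOMES",
    "VisitEvent",
    "EventLog",
    "false_pass_probability",
    "onsite_test_result",
    "simulate_visit",
    "run_donor",
    "run_population",
    "donor_rng",
]

HORIZON_DAYS = 365

OUTCOMES = (
    "donated_over",
    "donated_under",
    "deferred_low_hb",
    "deferred_low_hb_severe",
    "deferred_other",
    "lapsed",
    "pending",
)

DONATED = ("donated_over", "donated_under")
DEFERRED_LOW = ("deferred_low_hb", "deferred_low_hb_severe")


@dataclass
class VisitEvent:
    """One invitation → outcome record."""

    donor_id: int
    strategy: str
    invitation_day: int
    attendance_day: int | None
    outcome: str
    true_hb: float | None = None
    onsite_tested: bool = False
    hemocue_costed: bool = False
    interval_weeks: int | None = None
    interval_capped: bool = False
    post_deferral: bool = False
    after_horizon: bool = False
    cost_pence: int | None = None


@dataclass
class EventLog:
    """Time-ordered visit events for a whole population run, plus metadata."""

    events: list[VisitEvent]
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f.name for f in VisitEvent.__dataclass_fields__.values()]
        if not self.events:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([asdict(e) for e in self.events], columns=cols)

    def write_csv(self, path, metadata_path=None) -> None:
        """One CSV row per event; metadata sidecar as JSON."""
        self.to_dataframe().to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.meta, fh, indent=2, sort_keys=True, default=str)


def donor_rng(master_seed: int, donor_id: int) -> np.random.Generator:
    """The donor's private random stream (stable across population layouts)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(donor_id,)))


def false_pass_probability(deficit: float, behavior: BehaviorParams) -> float:
    """P(pass on-site screen) for a donor ``deficit`` g/L below threshold.

    Logistic decay in the deficit: near-threshold donors frequently slip
    through (screening error), deeply low donors almost never do.
    """
    if behavior.onsite_sigma <= 0:
        return 0.0
    return 1.0 / (1.0 + np.exp(deficit / behavior.onsite_sigma - behavior.onsite_offset))


def onsite_test_result(
    true_hb: float,
    threshold: float,
    behavior: BehaviorParams,
    rng: np.random.Generator,
) -> str:
    """``"pass"`` or ``"fail"`` of the on-site hemoglobin screen.

    Donors at or above the threshold always pass; below-threshold donors
    pass with probability :func:`false_pass_probability` (an inappropriate
    bleed) and otherwise fail (a low-hemoglobin deferral).
    """
    if true_hb >= threshold:
        return "pass"
    if rng.random() < false_pass_probability(threshold - true_hb, behavior):
        return "pass"
    return "fail"


def _delay_days(behavior: BehaviorParams, rng: np.random.Generator) -> int:
    """Whole-week attendance delay beyond the invited day, in days."""
    if behavior.delay_mean_weeks <= 0:
        return 0
    p = 1.0 / (1.0 + behavior.delay_mean_weeks)
    weeks = min(int(rng.geometric(p)) - 1, behavior.delay_cap_weeks)
    return 7 * weeks


def simulate_visit(
    donor,
    strategy: StrategySpec,
    model: RecoveryModel,
    behavior: BehaviorParams,
    thresholds: ThresholdSpec,
    invitation_day: int,
    anchor_day: int,
    last_hb: float,
    rng: np.random.Generator,
    *,
    interval_weeks: int | None = None,
    interval_capped: bool = False,
    post_deferral: bool = False,
    horizon: int = HORIZON_DAYS,
) -> VisitEvent:
    """Simulate one invitation through to its outcome.

    Sequence: lapse check → attendance delay → non-hemoglobin deferral check
    → true-hemoglobin realization → on-site screen where the strategy
    requires one → outcome.  Under pure post-donation strategies every
    attendee not deferred for other reasons donates, including those whose
    true hemoglobin is under threshold (an inappropriate bleed).
    """
    ev = VisitEvent(
        donor_id=int(donor.id),
        strategy=strategy.name,
        invitation_day=int(invitation_day),
        attendance_day=None,
        outcome="lapsed",
        interval_weeks=interval_weeks,
        interval_capped=interval_capped,
        post_deferral=post_deferral,
    )
    if rng.random() < behavior.dropout_prob:
        return ev

    attendance_day = invitation_day + _delay_days(behavior, rng)
    ev.attendance_day = int(attendance_day)
    ev.after_horizon = attendance_day >= horizon

    if rng.random() < behavior.other_deferral_prob:
        ev.outcome = "deferred_other"
        return ev

    t = (attendance_day - anchor_day) / 7.0
    true_hb = simulate_true_hb(model, donor, t, rng, last_hb=last_hb)
    ev.true_hb = float(true_hb)

    onsite = requires_onsite_test(
        strategy, model, donor, anchor_day, last_hb, attendance_day, thresholds
    )
    ev.onsite_tested = onsite
    if onsite and onsite_test_result(true_hb, thresholds.donation_threshold, behavior, rng) == "fail":
        ev.outcome = (
            "deferred_low_hb_severe" if true_hb < thresholds.severe_low else "deferred_low_hb"
        )
        return ev

    under = true_hb < thresholds.donation_threshold
    ev.outcome = "donated_under" if under else "donated_over"
    if strategy.onsite_always:
        # Current strategy: venous-HemoCue cost hits gravimetry failures —
        # all truly-under donors plus a slice of over-threshold ones.
        ev.hemocue_costed = bool(under or rng.random() < behavior.hemocue_over_fraction)
    elif onsite:
        ev.hemocue_costed = True
    return ev


def run_donor(
    donor,
    strategy: StrategySpec,
    model: RecoveryModel,
    behavior: BehaviorParams,
    rules: DeferralRules,
    thresholds: ThresholdSpec,
    rng: np.random.Generator,
    *,
    horizon: int = HORIZON_DAYS,
    max_visits: int | None = None,
    floor_override: int | None = None,
) -> list[VisitEvent]:
    """All visit events for one donor over the simulation year.

    The index donation happens at day 0 with the donor's index hemoglobin as
    the first trajectory anchor.  After each completed donation the realized
    true hemoglobin (the post-donation analyzer measurement) becomes the new
    anchor; deferrals keep the previous anchor, with the trajectory clock
    continuing from the prior donation.  A lapse ends the donor's year.
    """
    strat = strategy
    if floor_override is not None:
        mi = dict(strat.min_interval)
        mi[donor.sex] = floor_override
        strat = strat.replace(min_interval=mi)

    events: list[VisitEvent] = []
    anchor_day, last_hb = 0, float(donor.index_hb)
    invitation_day, capped = next_invitation_time(
        strat, model, donor, anchor_day, last_hb, thresholds
    )
    interval_weeks = (invitation_day - anchor_day) // 7
    post_deferral = False
    invitations = 0
    cap = strat.max_invitations_per_year

    while invitation_day < horizon and invitations < cap:
        if max_visits is not None and invitations >= max_visits:
            break
        invitations += 1
        ev = simulate_visit(
            donor, strat, model, behavior, thresholds,
            invitation_day, anchor_day, last_hb, rng,
            interval_weeks=interval_weeks, interval_capped=capped,
            post_deferral=post_deferral, horizon=horizon,
        )
        events.append(ev)
        if ev.outcome == "lapsed":
            break
        if ev.outcome in DONATED:
            anchor_day, last_hb = ev.attendance_day, float(ev.true_hb)
            invitation_day, capped = next_invitation_time(
                strat, model, donor, anchor_day, last_hb, thresholds
            )
            interval_weeks = (invitation_day - anchor_day) // 7
            post_deferral = False
        else:
            reason = "other" if ev.outcome == "deferred_other" else "low_hb"
            weeks = deferral_reinvite_interval(reason, ev.true_hb, thresholds, rules)
            invitation_day = ev.attendance_day + 7 * weeks
            interval_weeks, capped, post_deferral = weeks, False, True
    return events


def run_population(
    population: pd.DataFrame,
    strategy: StrategySpec,
    model: RecoveryModel,
    behavior: BehaviorParams,
    rules: DeferralRules,
    thresholds: ThresholdSpec,
    seed: int = 0,
    *,
    horizon: int = HORIZON_DAYS,
    max_visits: int | None = None,
    floor_override: int | None = None,
) -> EventLog:
    """Run the simulation for a whole (single-sex) population.

    Every donor draws from an independent substream of ``seed``; two runs
    with the same seed and population produce identical logs.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    sexes = population["sex"].unique()
    if len(sexes) != 1:
        raise ValueError("run_population expects a single-sex population (models are sex-stratified)")
    events: list[VisitEvent] = []
    for donor in population.itertuples(index=False):
        rng = donor_rng(seed, int(donor.id))
        events.extend(
            run_donor(
                donor, strategy, model, behavior, rules, thresholds, rng,
                horizon=horizon, max_visits=max_visits, floor_override=floor_override,
            )
        )
    meta = {
        "strategy": strategy.name,
        "sex": str(sexes[0]),
        "n": int(len(population)),
        "seed": int(seed),
        "horizon": int(horizon),
        "max_visits": max_visits,
        "floor_override": floor_override,
    }
    return EventLog(events=events, meta=meta)
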