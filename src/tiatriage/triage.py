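"""Weighted triage score, dynamic referral queue, and unit simulator.

The weighted triage score for a referral at elapsed time t since symptom
onset is

    w(t) = p_TIA × remaining_risk(stratum(ABCD2), t)

— the classifier's probability that the referral is a true TIA/minor
stroke times the conditional recurrent-stroke risk left in the actionable
window for the patient's ABCD2 band.  Both factors live in [0, 1], so
w ∈ [0, 1]; mimic-likely referrals and referrals whose risk window has
largely elapsed sink in the ranking, while recent, TIA-likely referrals
rise.  Because remaining risk is non-increasing in t, refreshing the
queue at a later clock time can only lower (or preserve) every entry's w.

The discrete-event simulator models unit operation: triage sessions run
each business-day morning (weekend faxes wait for Monday's session); at
each session every unbooked referral is (re)scored, ranked under the
active policy, and the top ``daily_capacity`` entries are booked into the
earliest free appointment slots on subsequent business days.  Policies:

* ``FIFO`` — referral order (no triage);
* ``ABCD_DESC`` — the historical practice: recorded ABCD score
  descending;
* ``WEIGHTED_QUEUE`` — weighted triage score descending.

Ties break by earlier symptom onset, then lexicographic id.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta

import numpy as np

from .classifier import ClassifierModel, predict_probability
from .referrals import CohortDataset, Referral
from .risk import RiskCurve
from .scoring import compute_abcd2, impute_missing, risk_stratum

DAY_SECONDS = 86400.0


class TriageError(ValueError):
    pass


class Policy(enum.Enum):
    FIFO = "fifo"
    ABCD_DESC = "abcd"
    WEIGHTED_QUEUE = "queue"


@dataclass(frozen=True)
class WeightedTriageScore:
    w: float
    p_tia: float
    remaining_risk: float
    abcd2: int
    t_days: float


@dataclass(frozen=True)
class QueueEntry:
    referral_id: str
    score: WeightedTriageScore
    booked: bool
    onset: datetime


@dataclass(frozen=True)
class QueueState:
    """Live snapshot of the unit's referrals at clock time ``now``."""

    now: datetime
    entries: dict[str, QueueEntry] = field(default_factory=dict)


@dataclass(frozen=True)
class UnitConfig:
    """Operating parameters of the assessment unit.

    ``daily_capacity`` is both the number of appointment slots per
    business day and the number of bookings staff make per triage
    session.  Business days default to Monday–Friday.
    """

    daily_capacity: int
    business_days: frozenset[int] = frozenset({0, 1, 2, 3, 4})
    triage_hour: int = 8
    first_slot_hour: int = 9
    slot_minutes: int = 30

    def __post_init__(self) -> None:
        if self.daily_capacity < 1:
            raise TriageError("daily_capacity must be >= 1")


def elapsed_days(onset: datetime, now: datetime) -> float:
    return max((now - onset).total_seconds() / DAY_SECONDS, 0.0)


def weighted_triage_score(
    p_tia: float,
    abcd2: int,
    t_days: float,
    curves: dict,
) -> WeightedTriageScore:
    """w = p_TIA × remaining recurrent-stroke risk at t for the ABCD2 band."""
    stratum = risk_stratum(abcd2)
    try:
        curve: RiskCurve = curves[stratum]
    except KeyError:
        raise TriageError(f"no risk curve for stratum {stratum.name}") from None
    rem = float(curve.remaining_risk(float(t_days)))
    return WeightedTriageScore(
        w=p_tia * rem, p_tia=p_tia, remaining_risk=rem, abcd2=abcd2, t_days=float(t_days)
    )


def _rank_key(entry: QueueEntry) -> tuple:
    return (-entry.score.w, entry.onset, entry.referral_id)


def rank_referrals(state: QueueState) -> list[str]:
    """Unbooked referral ids by descending w; ties by earlier onset, then id."""
    unbooked = [e for e in state.entries.values() if not e.booked]
    return [e.referral_id for e in sorted(unbooked, key=_rank_key)]


def refresh_scores(
    state: QueueState,
    referrals: list[Referral],
    model: ClassifierModel,
    curves: dict,
    now: datetime,
) -> QueueState:
    """Advance the queue clock: rescore every unbooked entry at ``now``
    and insert any new referrals.  The clock may not run backwards."""
    if now < state.now:
        raise TriageError(f"clock regression: {now} < {state.now}")
    by_id = {r.id: r for r in referrals}
    entries = dict(state.entries)
    for rid, referral in by_id.items():
        if rid in entries and entries[rid].booked:
            continue
        scored = impute_missing(referral)
        p = predict_probability(model, scored).p
        abcd2 = compute_abcd2(scored).value
        score = weighted_triage_score(p, abcd2, elapsed_days_for(referral, now), curves)
        entries[rid] = QueueEntry(rid, score, booked=False, onset=referral.onset_datetime)
    return QueueState(now=now, entries=entries)


def elapsed_days_for(referral: Referral, now: datetime) -> float:
    if referral.onset_datetime is None:
        raise TriageError(f"referral {referral.id} has no onset timestamp")
    return elapsed_days(referral.onset_datetime, now)


# ---------------------------------------------------------------------------
# Discrete-event simulation of unit operation
# ---------------------------------------------------------------------------


def _next_business_day(day, business_days):
    day = day + timedelta(days=1)
    while day.weekday() not in business_days:
        day = day + timedelta(days=1)
    return day


@dataclass
class _Slots:
    """Appointment calendar: per-business-day slot occupancy."""

    capacity: int
    business_days: frozenset[int]
    used: dict = field(default_factory=dict)

    def book(self, after_day):
        day = _next_business_day(after_day, self.business_days)
        while self.used.get(day, 0) >= self.capacity:
            day = _next_business_day(day, self.business_days)
        index = self.used.get(day, 0)
        self.used[day] = index + 1
        return day, index


def simulate_unit(
    stream: CohortDataset,
    unit: UnitConfig,
    policy: Policy,
    seed: int = 0,
    model: ClassifierModel | None = None,
    curves: dict | None = None,
    dropout_rate: float = 0.0,
    end: datetime | None = None,
) -> dict[str, datetime | None]:
    """Simulate triage-and-booking for a referral stream; returns the
    appointment (arrival) datetime per referral id.

    Deterministic given the stream, config, policy and seed; the seed
    only drives the optional no-show draw (``dropout_rate`` > 0 makes a
    booked patient never arrive, mapped to ``None``, while still
    consuming the slot).
    """
    if policy is Policy.WEIGHTED_QUEUE and (model is None or curves is None):
        raise TriageError("WEIGHTED_QUEUE requires a classifier model and risk curves")

    referrals = list(stream.referrals)
    if end is not None:
        late = [r for r in referrals if r.referral_datetime > end]
        if late:
            warnings.warn(
                f"excluding {len(late)} referral(s) dated after simulation end {end}"
            )
            referrals = [r for r in referrals if r.referral_datetime <= end]
    if not referrals:
        return {}
    for r in referrals:
        if r.onset_datetime is None:
            raise TriageError(f"referral {r.id} has no onset timestamp")

    rng = np.random.default_rng(seed)

    # Static per-referral priority inputs, computed once.
    prepared = {}
    for r in referrals:
        scored = impute_missing(r)
        abcd2 = compute_abcd2(scored).value
        if r.abcd_score_recorded is not None:
            abcd = r.abcd_score_recorded
        else:
            abcd = abcd2 - (1 if r.diabetes else 0)
        p_tia = (
            predict_probability(model, scored).p
            if policy is Policy.WEIGHTED_QUEUE
            else None
        )
        prepared[r.id] = (r, abcd2, abcd, p_tia)

    by_arrival = sorted(referrals, key=lambda r: (r.referral_datetime, r.id))
    incoming = iter(by_arrival)
    next_referral = next(incoming, None)

    slots = _Slots(capacity=unit.daily_capacity, business_days=unit.business_days)
    arrivals: dict[str, datetime | None] = {}
    pending: list[str] = []

    day = by_arrival[0].referral_datetime.date()
    while day.weekday() not in unit.business_days:
        day = day + timedelta(days=1)

    guard = 0
    while next_referral is not None or pending:
        guard += 1
        if guard > 200_000:  # pragma: no cover - defensive bound
            raise TriageError("simulation failed to terminate")
        session = datetime.combine(day, time(hour=unit.triage_hour))
        while next_referral is not None and next_referral.referral_datetime < session:
            pending.append(next_referral.id)
            next_referral = next(incoming, None)

        if pending:
            if policy is Policy.FIFO:
                def key(rid):
                    r = prepared[rid][0]
                    return (r.referral_datetime, rid)
            elif policy is Policy.ABCD_DESC:
                def key(rid):
                    r, _, abcd, _ = prepared[rid]
                    return (-abcd, r.onset_datetime, rid)
            else:
                def key(rid):
                    r, abcd2, _, p_tia = prepared[rid]
                    score = weighted_triage_score(
                        p_tia, abcd2, elapsed_days(r.onset_datetime, session), curves
                    )
                    return (-score.w, r.onset_datetime, rid)

            pending.sort(key=key)
            for rid in pending[: unit.daily_capacity]:
                slot_day, index = slots.book(day)
                appointment = datetime.combine(
                    slot_day, time(hour=unit.first_slot_hour)
                ) + timedelta(minutes=unit.slot_minutes * index)
                if dropout_rate > 0 and rng.random() < dropout_rate:
                    arrivals[rid] = None
                else:
                    arrivals[rid] = appointment
            pending = pending[unit.daily_capacity:]

        day = _next_business_day(day, unit.business_days)

    return arrivals
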