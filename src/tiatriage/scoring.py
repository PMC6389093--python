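"""ABCD2 scoring with mean-substitution imputation and risk strata.

The ABCD2 score (0–7) is the standard prognostic marker for recurrent
stroke risk after TIA/minor stroke, summing five components: Age ≥ 60
(1 pt), Blood pressure ≥ 140/90 mmHg (1 pt), Clinical presentation
(unilateral weakness 2 pts, speech disturbance without weakness 1 pt),
Duration of symptoms (≥ 60 min 2 pts, 10–59 min 1 pt), and Diabetes
(1 pt).  Thresholds are inclusive.  The point rules are config-overridable
via :class:`RuleTable`.

Missing age and blood pressure are replaced by fixed historical means
before scoring (mean substitution), mirroring how a live triage system
must score incomplete faxes; missing symptom duration is a scoring error
rather than being silently imputed.

The legacy ABCD score (0–6) omits the diabetes point; adding diabetes
status converts it to an ABCD2 score, which is how pre-queue-era referrals
(whose forms predate ABCD2 capture) are stratified.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .referrals import Referral


class ScoringError(ValueError):
    """Raised when required inputs are missing; names the blocking fields."""

    def __init__(self, missing: list[str]):
        self.missing = tuple(missing)
        super().__init__(f"cannot score: missing field(s) {', '.join(missing)}")


@dataclass(frozen=True)
class ImputationConstants:
    """Historical cohort means substituted for missing age and BP."""

    mean_age_years: float = 68.277
    mean_systolic_mmHg: float = 141.606
    mean_diastolic_mmHg: float = 78.042

    def __post_init__(self) -> None:
        if min(self.mean_age_years, self.mean_systolic_mmHg, self.mean_diastolic_mmHg) <= 0:
            raise ValueError("imputation constants must be positive")


DEFAULT_IMPUTATION = ImputationConstants()


@dataclass(frozen=True)
class RuleTable:
    """Component point thresholds; all comparisons are inclusive (>=)."""

    age_threshold_years: float = 60.0
    systolic_threshold_mmHg: float = 140.0
    diastolic_threshold_mmHg: float = 90.0
    duration_long_minutes: float = 60.0
    duration_short_minutes: float = 10.0
    weakness_symptom: str = "unilateral_weakness"
    speech_symptom: str = "speech_disturbance"


DEFAULT_RULES = RuleTable()


@dataclass(frozen=True)
class Abcd2Score:
    value: int
    components: dict[str, int] = field(default_factory=dict)
    imputed_fields: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.components and sum(self.components.values()) != self.value:
            raise ValueError("ABCD2 value must equal the component sum")
        if not 0 <= self.value <= 7:
            raise ValueError(f"ABCD2 value {self.value} outside [0, 7]")


class RiskStratum(enum.Enum):
    """The conventional ABCD2 risk bands used for stratified reporting."""

    LOW = (0, 3)
    MODERATE = (4, 5)
    HIGH = (6, 7)

    @property
    def score_range(self) -> tuple[int, int]:
        return self.value


def risk_stratum(score: int) -> RiskStratum:
    """Map an ABCD2 score to its band: low 0–3, moderate 4–5, high 6–7."""
    if not isinstance(score, (int,)) or isinstance(score, bool):
        raise ValueError(f"ABCD2 score must be an integer, got {score!r}")
    for stratum in RiskStratum:
        lo, hi = stratum.score_range
        if lo <= score <= hi:
            return stratum
    raise ValueError(f"ABCD2 score {score} outside [0, 7]")


def impute_missing(
    referral: Referral, constants: ImputationConstants = DEFAULT_IMPUTATION
) -> Referral:
    """Mean-substitute missing age and blood pressure; total function.

    Only age_years, systolic_mmHg and diastolic_mmHg are ever imputed;
    the substitutions are recorded in ``imputed_fields`` on the copy.
    """
    updates: dict = {}
    imputed = set(referral.imputed_fields)
    if referral.age_years is None:
        updates["age_years"] = constants.mean_age_years
        imputed.add("age_years")
    if referral.systolic_mmHg is None:
        updates["systolic_mmHg"] = constants.mean_systolic_mmHg
        imputed.add("systolic_mmHg")
    if referral.diastolic_mmHg is None:
        updates["diastolic_mmHg"] = constants.mean_diastolic_mmHg
        imputed.add("diastolic_mmHg")
    if not updates:
        return referral
    return replace(referral, imputed_fields=frozenset(imputed), **updates)


def compute_abcd2(
    referral: Referral,
    rules: RuleTable = DEFAULT_RULES,
    duration_default_minutes: float | None = None,
) -> Abcd2Score:
    """Score a referral; raises :class:`ScoringError` naming any missing
    inputs (run :func:`impute_missing` first for age/BP)."""
    missing = [
        name
        for name, value in (
            ("age_years", referral.age_years),
            ("systolic_mmHg", referral.systolic_mmHg),
            ("diastolic_mmHg", referral.diastolic_mmHg),
        )
        if value is None
    ]
    duration = referral.duration_minutes
    if duration is None:
        if duration_default_minutes is not None:
            duration = duration_default_minutes
        else:
            missing.append("duration_minutes")
    if missing:
        raise ScoringError(missing)

    age_pt = 1 if referral.age_years >= rules.age_threshold_years else 0
    bp_pt = (
        1
        if (
            referral.systolic_mmHg >= rules.systolic_threshold_mmHg
            or referral.diastolic_mmHg >= rules.diastolic_threshold_mmHg
        )
        else 0
    )
    if referral.symptoms.get(rules.weakness_symptom, 0):
        clinical_pt = 2
    elif referral.symptoms.get(rules.speech_symptom, 0):
        clinical_pt = 1
    else:
        clinical_pt = 0
    if duration >= rules.duration_long_minutes:
        duration_pt = 2
    elif duration >= rules.duration_short_minutes:
        duration_pt = 1
    else:
        duration_pt = 0
    diabetes_pt = 1 if referral.diabetes else 0

    components = {
        "age": age_pt,
        "bp": bp_pt,
        "clinical": clinical_pt,
        "duration": duration_pt,
        "diabetes": diabetes_pt,
    }
    return Abcd2Score(
        value=sum(components.values()),
        components=components,
        imputed_fields=referral.imputed_fields,
    )


def abcd_to_abcd2(abcd: int, diabetes: int) -> int:
    """Convert a legacy ABCD score (0–6) to ABCD2 by adding the diabetes
    point."""
    if not 0 <= abcd <= 6:
        raise ValueError(f"ABCD score {abcd} outside [0, 6]")
    return abcd + (1 if diabetes else 0)


def referral_abcd2(referral: Referral) -> Abcd2Score:
    """The ABCD2 score used for stratified evaluation of a referral.

    Pre-queue-era referrals are scored from the staff-recorded ABCD score
    plus diabetes status; post-queue referrals are scored from form fields
    after mean substitution.
    """
    from .referrals import Cohort

    if referral.cohort is Cohort.PRE_QUEUE and referral.abcd_score_recorded is not None:
        value = abcd_to_abcd2(referral.abcd_score_recorded, referral.diabetes)
        return Abcd2Score(value=value)
    return compute_abcd2(impute_missing(referral))
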