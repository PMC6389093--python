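"""Synthetic referral streams with the marginal structure of a regional
TIA unit's pre- and post-queue cohorts.

The generator emulates an 18-month referral stream: a mix of true
TIA/minor-stroke and mimic referrals (with small fractions of "Other"
and charted-as-Unknown diagnoses), symptom checkboxes drawn from
diagnosis-conditional Bernoulli profiles, ABCD2-relevant fields (age,
blood pressure, clinical presentation, duration, diabetes) constructed
so the induced ABCD2 distribution matches a target distribution, a
right-skewed onset-to-referral delay, per-field missingness, and a flag
for referrals co-enrolled in a concurrent imaging study.

Internal consistency is kept by composing each referral's ABCD2 score
from component points first (a target score is drawn, then split into
age/BP/clinical/duration points using diagnosis-conditional priors) and
only then realising continuous field values inside the corresponding
component band — the generator never writes a score that the scoring
rules would not reproduce from the fields.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
from scipy.stats import truncnorm

from . import features as _features
from .referrals import Cohort, CohortDataset, Diagnosis, Referral


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """Target marginals and nuisance parameters for one synthetic cohort."""

    n: int
    label: Cohort
    tia_prevalence: float
    abcd2_distribution: tuple[float, ...]
    diabetes_rate: float = 0.18
    age_mean: float = 70.54
    age_sd: float = 13.17
    sbp_mean: float = 146.5
    sbp_sd: float = 23.0
    dbp_mean: float = 80.1
    dbp_sd: float = 11.5
    # lognormal onset-to-referral delay, in days
    delay_meanlog: float = 0.70
    delay_sdlog: float = 0.90
    # week-to-week referral-volume burstiness: weekly intensities are
    # gamma-distributed with this coefficient of variation (0 = uniform
    # inflow); real units see seasonal and weekly surges
    weekly_intensity_cv: float = 0.6
    start: datetime = datetime(2014, 11, 1)
    end: datetime = datetime(2016, 5, 1)
    other_rate: float = 0.03
    unknown_rate: float = 0.06
    spectra_rate: float = 0.02
    missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.02,
            "systolic": 0.03,
            "diastolic": 0.03,
            "onset": 0.04,
            "abcd_recorded": 0.05,
        }
    )
    symptom_profiles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_features.SYMPTOM_RATES)
    )
    # P(component point) priors used to split a target score into
    # components; the clinical-component prior is diagnosis-conditional
    # (focal deficits are commoner in true TIA).
    age_point_prior: float = 0.78
    bp_point_prior: float = 0.55
    duration_point_prior: tuple[float, float, float] = (0.15, 0.30, 0.55)
    clinical_point_prior_tia: tuple[float, float, float] = (0.30, 0.25, 0.45)
    clinical_point_prior_mimic: tuple[float, float, float] = (0.55, 0.28, 0.17)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise SpecError("n must be non-negative")
        dist = np.asarray(self.abcd2_distribution, dtype=float)
        if dist.shape != (8,):
            raise SpecError("abcd2_distribution must have 8 entries (scores 0-7)")
        if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-6:
            raise SpecError("abcd2_distribution must be a probability vector")
        for name, rate in {
            "tia_prevalence": self.tia_prevalence,
            "diabetes_rate": self.diabetes_rate,
            "other_rate": self.other_rate,
            "unknown_rate": self.unknown_rate,
            "spectra_rate": self.spectra_rate,
            **{f"missing_rates[{k}]": v for k, v in self.missing_rates.items()},
        }.items():
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"{name} must lie in [0, 1], got {rate}")
        if self.end <= self.start:
            raise SpecError("referral window must have positive length")


def _component_table(clin_prior, age_p, bp_p, dur_prior):
    """For each achievable component sum 0-6, the (combo, probability)
    pairs over (age, bp, clinical, duration) points."""
    table: dict[int, tuple[list[tuple[int, int, int, int]], np.ndarray]] = {}
    combos = list(itertools.product((0, 1), (0, 1), (0, 1, 2), (0, 1, 2)))
    weights = {
        combo: (age_p if combo[0] else 1 - age_p)
        * (bp_p if combo[1] else 1 - bp_p)
        * clin_prior[combo[2]]
        * dur_prior[combo[3]]
        for combo in combos
    }
    for total in range(7):
        matching = [c for c in combos if sum(c) == total]
        probs = np.array([weights[c] for c in matching])
        table[total] = (matching, probs / probs.sum())
    return table


def _truncnorm_draws(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortDataset:
    """Draw a full referral stream from the spec; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    dist = np.asarray(spec.abcd2_distribution, dtype=float)
    dist = dist / dist.sum()

    # Diagnosis: carve out Other/Unknown, then split the remainder by
    # TIA prevalence.
    u = rng.random(n)
    diagnosis = np.full(n, Diagnosis.MIMIC, dtype=object)
    diagnosis[u < spec.other_rate] = Diagnosis.OTHER
    unknown_band = (u >= spec.other_rate) & (u < spec.other_rate + spec.unknown_rate)
    diagnosis[unknown_band] = Diagnosis.UNKNOWN
    rest = u >= spec.other_rate + spec.unknown_rate
    is_tia = rest & (rng.random(n) < spec.tia_prevalence)
    diagnosis[is_tia] = Diagnosis.TIA_MINOR_STROKE

    # Target ABCD2 score, then diabetes conditional on it: a score of 7
    # requires the diabetes point and a score of 0 forbids it, so the
    # conditional rate for scores 1-6 is solved to hit the marginal
    # diabetes rate while keeping both marginals on target.
    score = rng.choice(8, size=n, p=dist)
    p7, p0 = dist[7], dist[0]
    if p7 > spec.diabetes_rate + 1e-9:
        raise SpecError(
            "abcd2_distribution places more mass on score 7 than the "
            "diabetes_rate can supply (score 7 requires the diabetes point)"
        )
    mid_mass = 1.0 - p7 - p0
    p_mid = 0.0 if mid_mass <= 0 else min((spec.diabetes_rate - p7) / mid_mass, 1.0)
    dia_rate_by_score = np.array([0.0] + [p_mid] * 6 + [1.0])
    diabetes = (rng.random(n) < dia_rate_by_score[score]).astype(int)

    # Split (score - diabetes) into age/BP/clinical/duration points.
    tables = {
        True: _component_table(
            spec.clinical_point_prior_tia,
            spec.age_point_prior,
            spec.bp_point_prior,
            spec.duration_point_prior,
        ),
        False: _component_table(
            spec.clinical_point_prior_mimic,
            spec.age_point_prior,
            spec.bp_point_prior,
            spec.duration_point_prior,
        ),
    }
    remainder = score - diabetes
    age_pt = np.zeros(n, dtype=int)
    bp_pt = np.zeros(n, dtype=int)
    clin_pt = np.zeros(n, dtype=int)
    dur_pt = np.zeros(n, dtype=int)
    for tia_flag in (True, False):
        for rem in range(7):
            mask = (remainder == rem) & (is_tia == tia_flag)
            count = int(mask.sum())
            if not count:
                continue
            combos, probs = tables[tia_flag][rem]
            idx = rng.choice(len(combos), size=count, p=probs)
            chosen = np.array(combos)[idx]
            age_pt[mask], bp_pt[mask] = chosen[:, 0], chosen[:, 1]
            clin_pt[mask], dur_pt[mask] = chosen[:, 2], chosen[:, 3]

    # Realise continuous fields inside each component band.
    # Band upper limits sit 0.1 below each scoring threshold so the
    # 1-decimal rounding applied on output cannot flip a component point.
    age = np.empty(n)
    age[age_pt == 1] = _truncnorm_draws(
        rng, spec.age_mean, spec.age_sd, 60.0, 105.0, int((age_pt == 1).sum())
    )
    age[age_pt == 0] = _truncnorm_draws(
        rng, spec.age_mean, spec.age_sd, 18.0, 59.9, int((age_pt == 0).sum())
    )
    sbp = np.empty(n)
    dbp = np.empty(n)
    hi, lo = bp_pt == 1, bp_pt == 0
    sbp[hi] = _truncnorm_draws(rng, spec.sbp_mean, spec.sbp_sd, 140.0, 260.0, int(hi.sum()))
    dbp[hi] = _truncnorm_draws(rng, spec.dbp_mean, spec.dbp_sd, 40.0, 140.0, int(hi.sum()))
    sbp[lo] = _truncnorm_draws(rng, spec.sbp_mean, spec.sbp_sd, 85.0, 139.9, int(lo.sum()))
    dbp[lo] = _truncnorm_draws(rng, spec.dbp_mean, spec.dbp_sd, 40.0, 89.9, int(lo.sum()))
    duration = np.empty(n)
    duration[dur_pt == 0] = rng.uniform(1.0, 9.9, int((dur_pt == 0).sum()))
    duration[dur_pt == 1] = rng.uniform(10.0, 59.9, int((dur_pt == 1).sum()))
    duration[dur_pt == 2] = rng.uniform(60.0, 720.0, int((dur_pt == 2).sum()))

    # Symptom checkboxes: clinical-component deficits are score-linked;
    # the rest follow the diagnosis-conditional profiles.
    weakness = (clin_pt == 2).astype(int)
    speech = np.where(clin_pt == 1, 1, np.where(weakness & (rng.random(n) < 0.4), 1, 0))
    profile_names = [
        name
        for name in spec.symptom_profiles
        if name not in _features.SCORE_LINKED_SYMPTOMS
    ]
    checkbox = {}
    for name in profile_names:
        p_tia_rate, p_mimic_rate = spec.symptom_profiles[name]
        rates = np.where(is_tia, p_tia_rate, p_mimic_rate)
        checkbox[name] = (rng.random(n) < rates).astype(int)

    # Timestamps: referral moments over the window with gamma-weighted
    # weekly intensities (bursty inflow); onset lags the referral by a
    # right-skewed (lognormal) delay in days.
    window = (spec.end - spec.start).total_seconds()
    week = 7 * 86400.0
    n_weeks = int(np.ceil(window / week))
    cv = spec.weekly_intensity_cv
    if cv > 0:
        shape = 1.0 / (cv * cv)
        weights = rng.gamma(shape, 1.0 / shape, n_weeks)
    else:
        weights = np.ones(n_weeks)
    # partial final week gets proportionally less intensity
    weights[-1] *= (window - (n_weeks - 1) * week) / week
    week_idx = rng.choice(n_weeks, size=n, p=weights / weights.sum())
    referral_offsets = week_idx * week + rng.uniform(0.0, week, n)
    referral_offsets = np.minimum(referral_offsets, window - 1.0)
    referral_offsets = np.sort(referral_offsets)
    delays_days = rng.lognormal(spec.delay_meanlog, spec.delay_sdlog, n)

    # Missingness masks.
    miss = {
        key: rng.random(n) < spec.missing_rates.get(key, 0.0)
        for key in ("age", "systolic", "diastolic", "onset", "abcd_recorded")
    }
    spectra = (rng.random(n) < spec.spectra_rate).astype(int)

    short = "pre" if spec.label is Cohort.PRE_QUEUE else "post"
    referrals = []
    for i in range(n):
        referral_dt = spec.start + timedelta(seconds=float(referral_offsets[i]))
        referral_dt = referral_dt.replace(microsecond=0)
        onset_dt = referral_dt - timedelta(days=float(delays_days[i]))
        onset_dt = onset_dt.replace(microsecond=0)
        symptoms = {name: int(checkbox[name][i]) for name in profile_names}
        symptoms["unilateral_weakness"] = int(weakness[i])
        symptoms["speech_disturbance"] = int(speech[i])
        referrals.append(
            Referral(
                id=f"{short}-{i:06d}",
                cohort=spec.label,
                diagnosis=diagnosis[i],
                age_years=None if miss["age"][i] else float(round(age[i], 1)),
                systolic_mmHg=None if miss["systolic"][i] else float(round(sbp[i], 1)),
                diastolic_mmHg=None if miss["diastolic"][i] else float(round(dbp[i], 1)),
                duration_minutes=float(round(duration[i], 1)),
                diabetes=int(diabetes[i]),
                onset_datetime=None if miss["onset"][i] else onset_dt,
                referral_datetime=referral_dt,
                abcd_score_recorded=(
                    None if miss["abcd_recorded"][i] else int(score[i] - diabetes[i])
                ),
                symptoms=symptoms,
                spectra_flag=int(spectra[i]),
            )
        )
    return CohortDataset(referrals=referrals, label=spec.label)


# Printed cohort marginals used as generator targets: TIA prevalence
# 65.4% pre / 58.0% post, diabetes ~18%, age mean 70.54 (sd 13.17), and
# the per-cohort ABCD2 percentage columns (normalised below).
_PRE_ABCD2 = (0.9, 5.1, 11.9, 19.4, 26.7, 19.9, 13.5, 2.7)
_POST_ABCD2 = (1.2, 7.9, 19.1, 21.3, 24.9, 15.3, 8.6, 1.5)


def _normalised(percentages: tuple[float, ...]) -> tuple[float, ...]:
    total = sum(percentages)
    return tuple(p / total for p in percentages)


def default_specs(n_pre: int = 2942, n_post: int = 2929) -> tuple[CohortSpec, CohortSpec]:
    """Bundled spec pair emulating the historical (ABCD-triaged) and
    prospective (weighted-queue) cohorts' published marginals."""
    pre = CohortSpec(
        n=n_pre,
        label=Cohort.PRE_QUEUE,
        tia_prevalence=0.654,
        abcd2_distribution=_normalised(_PRE_ABCD2),
        diabetes_rate=0.188,
        start=datetime(2013, 5, 1),
        end=datetime(2014, 11, 1),
        other_rate=0.03,
        unknown_rate=0.06,
        spectra_rate=0.02,
        missing_rates={
            "age": 0.02,
            "systolic": 0.03,
            "diastolic": 0.03,
            "onset": 0.04,
            "abcd_recorded": 0.05,
        },
        seed=20130501,
    )
    post = CohortSpec(
        n=n_post,
        label=Cohort.POST_QUEUE,
        tia_prevalence=0.580,
        abcd2_distribution=_normalised(_POST_ABCD2),
        diabetes_rate=0.174,
        start=datetime(2014, 11, 1),
        end=datetime(2016, 5, 1),
        other_rate=0.03,
        unknown_rate=0.20,
        spectra_rate=0.03,
        missing_rates={
            "age": 0.04,
            "systolic": 0.06,
            "diastolic": 0.06,
            "onset": 0.05,
            # the post-queue-era form has no legacy ABCD field
            "abcd_recorded": 1.0,
        },
        seed=20141101,
    )
    return pre, post


def spec_with(spec: CohortSpec, **overrides) -> CohortSpec:
    """Convenience for overriding spec fields (e.g. n or seed)."""
    return replace(spec, **overrides)
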