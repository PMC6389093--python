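"""Calendar-day outcomes, censoring, KM estimation, and the Peto–Peto test."""

import itertools
from datetime import datetime
from fractions import Fraction

import numpy as np
import pytest

from tiatriage.referrals import Cohort, CohortDataset, Diagnosis
from tiatriage.survival import (
    SurvivalData,
    SurvivalError,
    censor_at,
    days_to_unit,
    km_coordinates,
    km_estimate,
    peto_peto_test,
    stratified_report,
)

from conftest import make_referral


def sdata(days, events):
    return SurvivalData(days=np.asarray(days), events=np.asarray(events))


class TestDaysToUnit:
    def test_midnight_boundary_counts_one_day(self):
        onset = datetime(2015, 3, 2, 23, 50)
        arrival = datetime(2015, 3, 3, 0, 10)
        assert days_to_unit(onset, arrival) == 1

    def test_same_calendar_date_is_zero(self):
        assert days_to_unit(datetime(2015, 3, 2, 1), datetime(2015, 3, 2, 23)) == 0

    def test_week_apart(self):
        assert days_to_unit(datetime(2015, 3, 1, 12), datetime(2015, 3, 8, 9)) == 7

    def test_arrival_before_onset_rejected(self):
        with pytest.raises(SurvivalError):
            days_to_unit(datetime(2015, 3, 2), datetime(2015, 3, 1))


class TestCensoring:
    def test_late_arrival_censored(self):
        out = censor_at([30])
        assert (out.days[0], out.events[0]) == (28, 0)

    def test_day_28_arrival_is_event_inclusive(self):
        out = censor_at([28])
        assert (out.days[0], out.events[0]) == (28, 1)

    def test_day_28_censored_when_exclusive(self):
        out = censor_at([28], inclusive=False)
        assert (out.days[0], out.events[0]) == (28, 0)

    def test_never_arrived_censored_at_horizon(self):
        out = censor_at([None])
        assert (out.days[0], out.events[0]) == (28, 0)

    def test_idempotent(self):
        once = censor_at([3, 30, None, 28])
        twice = censor_at(
            [d if e else None for d, e in zip(once.days, once.events)]
        )
        assert np.array_equal(once.days, twice.days)
        assert np.array_equal(once.events, twice.events)


def km_oracle(days, events):
    """Brute-force product-limit in exact rational arithmetic."""
    times = sorted({d for d, e in zip(days, events) if e})
    s = Fraction(1)
    curve = []
    for t in times:
        n = sum(1 for d in days if d >= t)
        d_t = sum(1 for d, e in zip(days, events) if d == t and e)
        s *= Fraction(n - d_t, n)
        curve.append((t, s))
    median = next((t for t, s_t in curve if s_t <= Fraction(1, 2)), None)
    return curve, median


class TestKaplanMeier:
    def test_all_events_same_day_degenerate(self):
        curve = km_estimate(sdata([5, 5, 5], [1, 1, 1]))
        assert list(curve.times) == [5]
        assert curve.survival == pytest.approx([0.0])
        assert curve.median_days == 5

    def test_hand_example_four_events(self):
        curve = km_estimate(sdata([1, 2, 3, 4], [1, 1, 1, 1]))
        assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert curve.median_days == 2

    def test_hand_example_with_censoring(self):
        curve = km_estimate(sdata([1, 28], [1, 0]))
        assert curve.survival == pytest.approx([0.5])
        assert curve.median_days == 1

    def test_median_not_reached(self):
        curve = km_estimate(sdata([1, 28, 28, 28], [1, 0, 0, 0]))
        assert curve.survival == pytest.approx([0.75])
        assert curve.median_days is None

    def test_empty_dataset_rejected(self):
        with pytest.raises(SurvivalError):
            km_estimate(sdata([], []))

    def test_matches_lifelines_on_random_data(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(2, 50)
            days = rng.integers(1, 20, n)
            events = rng.integers(0, 2, n)
            mine = km_estimate(sdata(days, events))
            kmf = KaplanMeierFitter().fit(days, events)
            for t, s in zip(mine.times, mine.survival):
                assert s == pytest.approx(float(kmf.predict(int(t))), abs=1e-12)

    def test_coordinates_start_at_one(self):
        frame = km_coordinates(sdata([1, 2], [1, 1]))
        assert frame["survival"].iloc[0] == 1.0
        assert frame["days"].iloc[0] == 0


def peto_oracle(days_a, events_a, days_b, events_b):
    """Hand transcription of the weighted observed-minus-expected sum in
    exact rational arithmetic, independent of the implementation."""
    pooled = [(d, e, "A") for d, e in zip(days_a, events_a)] + [
        (d, e, "B") for d, e in zip(days_b, events_b)
    ]
    times = sorted({d for d, e, _ in pooled if e})
    u, v, s = Fraction(0), Fraction(0), Fraction(1)
    for t in times:
        at_risk = [(d, e, g) for d, e, g in pooled if d >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == "A")
        d_t = sum(1 for d, e, _ in pooled if d == t and e)
        d_a = sum(1 for d, e, g in pooled if d == t and e and g == "A")
        s *= 1 - Fraction(d_t, n + 1)
        u += s * (d_a - Fraction(d_t * n_a, n))
        if n > 1:
            v += s * s * d_t * Fraction(n_a, n) * (1 - Fraction(n_a, n)) * Fraction(n - d_t, n - 1)
    return u, v


class TestPetoPeto:
    def test_identical_groups_give_null_statistic(self):
        g = sdata([2, 5, 9, 28], [1, 1, 1, 0])
        result = peto_peto_test(g, g)
        assert result.chi_squared == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_six_record_toy_matches_hand_computation(self):
        """Hand-worked toy: A = {1*, 3*, 5}, B = {2*, 4, 6*} (* = event).
        The weighted sum U = 3/7 and variance V = 19/49 give
        chi-squared = 9/19."""
        a = sdata([1, 3, 5], [1, 1, 0])
        b = sdata([2, 4, 6], [1, 0, 1])
        result = peto_peto_test(a, b)
        assert result.chi_squared == pytest.approx(9 / 19, rel=1e-12)
        u, v = peto_oracle([1, 3, 5], [1, 1, 0], [2, 4, 6], [1, 0, 1])
        assert u == Fraction(3, 7) and v == Fraction(19, 49)
        assert result.chi_squared == pytest.approx(float(u * u / v), rel=1e-12)

    def test_matches_rational_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            na, nb = rng.integers(2, 12, 2)
            da, db = rng.integers(1, 9, na), rng.integers(1, 9, nb)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            u, v = peto_oracle(da.tolist(), ea.tolist(), db.tolist(), eb.tolist())
            if v == 0:
                continue
            result = peto_peto_test(sdata(da, ea), sdata(db, eb))
            assert result.chi_squared == pytest.approx(float(u * u / v), rel=1e-9)

    def test_symmetric_and_order_invariant(self):
        rng = np.random.default_rng(3)
        da, ea = rng.integers(1, 15, 20), rng.integers(0, 2, 20)
        db, eb = rng.integers(1, 15, 25), rng.integers(0, 2, 25)
        ab = peto_peto_test(sdata(da, ea), sdata(db, eb))
        ba = peto_peto_test(sdata(db, eb), sdata(da, ea))
        assert ab.chi_squared == pytest.approx(ba.chi_squared, rel=1e-12)
        perm = rng.permutation(20)
        shuffled = peto_peto_test(sdata(da[perm], ea[perm]), sdata(db, eb))
        assert shuffled.chi_squared == pytest.approx(ab.chi_squared, rel=1e-12)

    def test_strong_shift_alternative_detected(self):
        rng = np.random.default_rng(5)
        early = censor_at(np.ceil(rng.exponential(3, 150)).astype(int).tolist())
        late = censor_at(np.ceil(rng.exponential(12, 150)).astype(int).tolist())
        result = peto_peto_test(early, late)
        assert result.p_value < 0.05

    def test_no_events_rejected(self):
        g = sdata([28, 28], [0, 0])
        with pytest.raises(SurvivalError, match="no events"):
            peto_peto_test(g, g)

    def test_empty_group_rejected(self):
        with pytest.raises(SurvivalError):
            peto_peto_test(sdata([], []), sdata([1], [1]))


def tiny_cohort(label, shift=0):
    """Six referrals spanning all strata, hand-checkable arrivals."""
    refs = []
    onset = datetime(2015, 3, 2, 9, 0)
    configs = [
        ("low_tia", 2, Diagnosis.TIA_MINOR_STROKE, dict(weakness=0, speech=0, diabetes=0, duration=30, age=50, sbp=120, dbp=70)),
        ("low_mim", 3, Diagnosis.MIMIC, dict(weakness=0, speech=0, diabetes=0, duration=30, age=50, sbp=120, dbp=70)),
        ("mod_tia", 4, Diagnosis.TIA_MINOR_STROKE, dict(weakness=1, speech=0, diabetes=0, duration=70, age=70, sbp=120, dbp=70)),
        ("mod_mim", 5, Diagnosis.MIMIC, dict(weakness=1, speech=0, diabetes=0, duration=70, age=70, sbp=120, dbp=70)),
        ("high_tia", 6, Diagnosis.TIA_MINOR_STROKE, dict(weakness=1, speech=0, diabetes=1, duration=70, age=70, sbp=150, dbp=95)),
        ("high_mim", 7, Diagnosis.MIMIC, dict(weakness=1, speech=0, diabetes=1, duration=70, age=70, sbp=150, dbp=95)),
    ]
    from datetime import timedelta

    for rid, day, dx, kw in configs:
        refs.append(
            make_referral(
                id=f"{label.value}_{rid}",
                onset=onset,
                referral=onset + timedelta(hours=1),
                arrival=onset + timedelta(days=day + shift, hours=2),
                diagnosis=dx,
                cohort=label,
                **kw,
            )
        )
    return CohortDataset(refs, label)


class TestStratifiedReport:
    def test_shape_and_populated_cells(self):
        report = stratified_report(
            tiny_cohort(Cohort.PRE_QUEUE, shift=2), tiny_cohort(Cohort.POST_QUEUE)
        )
        assert len(report) == 6
        assert set(report["abcd2_group"]) == {"LOW", "MODERATE", "HIGH"}
        assert set(report["diagnosis"]) == {"TIA", "Mimic"}
        assert (report["n_pre"] == 1).all() and (report["n_post"] == 1).all()

    def test_identical_cohorts_null_chi_squared(self):
        same = tiny_cohort(Cohort.POST_QUEUE)
        report = stratified_report(same, same)
        assert report["chi_squared"].to_numpy() == pytest.approx(np.zeros(6), abs=1e-12)

    def test_hand_computable_medians(self):
        report = stratified_report(
            tiny_cohort(Cohort.PRE_QUEUE, shift=2), tiny_cohort(Cohort.POST_QUEUE)
        ).set_index(["abcd2_group", "diagnosis"])
        assert report.loc[("LOW", "TIA"), "median_pre"] == 4  # day 2 + shift 2
        assert report.loc[("LOW", "TIA"), "median_post"] == 2
        assert report.loc[("HIGH", "Mimic"), "median_post"] == 7

    def test_empty_stratum_flagged_not_fatal(self):
        only_low = CohortDataset(
            [r for r in tiny_cohort(Cohort.POST_QUEUE) if "low" in r.id],
            Cohort.POST_QUEUE,
        )
        report = stratified_report(only_low, only_low)
        high = report[report["abcd2_group"] == "HIGH"]
        assert (high["n_pre"] == 0).all()
        assert high["chi_squared"].isna().all()
        assert (high["note"] != "").all()
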