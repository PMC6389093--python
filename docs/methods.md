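# Methods

## The triage problem

An outpatient TIA unit receives faxed referrals for suspected transient
ischemic attack (TIA) or minor stroke from emergency departments and
general practice, and books a finite number of appointments per business
day by telephone. Two facts make triage hard. First, 40–50% of referrals
are *mimics* — migraine, seizure, syncope and other non-cerebrovascular
conditions that present like TIA — and the ABCD2 score cannot separate
them from true events. Second, recurrent-stroke risk after a true
TIA/minor stroke is front-loaded in time, so two patients with the same
score are not at the same risk if their symptom onsets differ by days.
The package implements a triage score that addresses both, plus the
machinery to evaluate it.

## The weighted triage score

For a referral with classifier probability `p` of being a true
TIA/minor stroke, ABCD2 score `s`, and elapsed time `t` (days, real
valued) since symptom onset:

    w(t) = p × R_strat(s)(t)

where `R_b(t)` is the *remaining* recurrent-stroke risk of ABCD2 band
`b ∈ {low 0–3, moderate 4–5, high 6–7}`: the conditional probability of
recurrence in `(t, h_max]` given event-free survival to `t`,

    R_b(t) = 1 − S_b(h_max) / S_b(t).

Conditioning (rather than the unconditional residual incidence) encodes
the triage intuition that a patient seen late has a shrinking actionable
window; `R_b` is non-increasing in `t` for any non-negative hazard, so
re-ranking the queue at a later time can only demote entries. `w` is the
product of two probabilities and lives in `[0, 1]`.

### Risk curves

Each band's survival `S_b` is piecewise exponential, fitted so the
implied cumulative incidence passes exactly through a set of anchor
points `(h_j, r_j)` (cumulative risk `r` at horizon `h` days): with
`H_j = −log(1 − r_j)`, the hazard on `(h_{j−1}, h_j]` is
`(H_j − H_{j−1})/(h_j − h_{j−1})`, and zero beyond the last anchor.
This form was chosen because it interpolates any non-decreasing anchor
set exactly and gives closed-form conditional risks; it is deliberately
isolated behind the `RiskCurve` interface so a different time-dependent
model can be substituted. The bundled default anchors are the canonical
ABCD2 validation risks at 2/7/90 days (low 1.0/1.2/3.1%, moderate
4.1/5.9/9.8%, high 8.1/11.7/17.8%); deployments should treat them as a
template and substitute their preferred literature values via the
anchors YAML.

### Classifier

The diagnostic component is a logistic regression over form checkboxes:
50 main effects and 12 pairwise interactions, of which 31 and 8 carry
positive (TIA-indicating) coefficients. Fitted clinical coefficients
are not public, so the model is entirely configuration-driven
(`load_model`), and the package bundles a synthetic example with the
same structure whose coefficients are naive-Bayes log odds ratios
derived from the synthetic symptom profiles in `tiatriage.features`
(intercept calibrated to 58% prevalence). The example model is for
simulation and testing only — it discriminates well on streams drawn
from those same profiles (AUC ≈ 0.95) precisely because it shares them,
and nothing clinical should be inferred from it. Absent checkboxes
encode as 0 (an unchecked fax box means "not reported"); the logistic
link uses a numerically stable sigmoid.

## ABCD2 scoring

Component rules (inclusive thresholds, overridable via `RuleTable`):
age ≥ 60 → 1; systolic ≥ 140 or diastolic ≥ 90 mmHg → 1; unilateral
weakness → 2, else isolated speech disturbance → 1; duration ≥ 60 min →
2, 10–59 min → 1; diabetes → 1. Missing age and blood pressure are
mean-substituted with fixed historical constants (68.277 years,
141.606/78.042 mmHg) before scoring, mirroring a live system that must
score incomplete faxes; missing duration is an explicit scoring error
because no historical mean for it is established. Legacy ABCD scores
(0–6, pre-ABCD2 forms) convert to ABCD2 by adding the diabetes point.
Whether "speech disturbance" requires the absence of weakness varies in
the literature; the implementation uses weakness-dominates
(weakness → 2 regardless of speech), the conventional reading.

## Unit simulation

Triage sessions run each business-day morning (Mon–Fri, 08:00);
referrals faxed after a session — including all weekend faxes — wait
for the next one. At a session every unbooked referral is (re)scored at
the session clock and ranked under the active policy; the top
`daily_capacity` entries are booked into the earliest free slots on
subsequent business days (`daily_capacity` slots per day; same-day
booking is disallowed because patients are phoned — a documented
simplification). Policies: `FIFO`; `ABCD_DESC` (the historical
practice, recorded ABCD score descending); `WEIGHTED_QUEUE` (`w`
descending). Ties break by earlier onset then lexicographic id —
deterministic and clinically conservative; the historical unit could
not break score ties at all, which is part of what the weighted queue
fixes. An optional per-referral no-show probability exists for
sensitivity runs (the slot is consumed, the arrival is recorded as
none).

## Evaluation

The outcome is *time-to-unit*: calendar days between symptom onset and
unit arrival, ignoring time of day. Records are right-censored at 28
days — the guideline bound for assessing even low-risk patients — with
day-28 arrivals counted as events (the inclusive boundary is a
documented choice and is switchable). Kaplan–Meier curves are estimated
per stratum with the median defined as the smallest `t` with
`S(t) ≤ 0.5`, reported as "not reached" when `S` never falls that far.
Cohorts are compared within each of six strata (ABCD2 band × TIA/mimic)
by the Peto & Peto modification of the Gehan–Wilcoxon test: a weighted
log-rank statistic with weight `S̃(t_j) = Π_{i≤j} (1 − d_i/(n_i+1))`
(the G-rho family at rho = 1), referred to chi-squared on 1 df,
two-sided via the upper tail. The weighting emphasises early event
times, which is where a triage intervention should act. No multiplicity
correction is applied across the six strata. The product-limit
estimator and the weighted log-rank statistic are implemented in the
package with the exact conventions above; the test suite verifies both
against exhaustive exact-arithmetic oracles on small instances and
against lifelines (`KaplanMeierFitter`, `logrank_test(weightings=
"peto")`) on random data, keeping implementation and oracle on separate
routes.

Evaluation strata are assigned from the staff-recorded ABCD score plus
diabetes for pre-queue-era referrals, and from form fields after mean
substitution otherwise.

## Synthetic cohorts

The generator emulates two 18-month referral streams with published
cohort marginals as targets: TIA prevalence 65.4% (historical) / 58.0%
(prospective); age mean 70.54 (sd 13.17); diabetes 18.8% / 17.4%; and
the per-cohort ABCD2 score distributions. Internal consistency is
maintained by construction: a target ABCD2 score is drawn first,
diabetes is drawn conditionally on it (a score of 7 requires the
diabetes point, a score of 0 forbids it; the conditional rate for
scores 1–6 is solved so the marginal diabetes rate is preserved), the
remainder is split into age/BP/clinical/duration points using
diagnosis-conditional priors (focal deficits commoner in true TIA), and
continuous fields are then drawn inside the corresponding band from
truncated normals/uniforms — so the scoring rules always reproduce the
intended score from the fields, and the recorded legacy ABCD field
always equals the ABCD2 value minus the diabetes point.

Study conditions not derivable from published marginals were fixed once
at realistic values and are spec fields, not code constants:

* **Onset-to-referral delay**: lognormal, meanlog 0.7, sdlog 0.9
  (median ≈ 2 days, mean ≈ 3). Shorter delays put even top-priority
  patients at the unit by day 3, inconsistent with observed
  high-stratum medians around 5 days.
* **Referral-volume burstiness**: weekly intensities gamma-distributed
  with CV 0.6. Uniform inflow leaves permanent capacity headroom for
  moderate/high scores, which would make any policy difference vanish
  for them; real units see seasonal surges during which backlogs form
  and ranking order matters.
* **Unit capacity**: 5 appointments/business day against ≈ 4.9
  scoreable referrals/business day at the default experiment size of
  2000 referrals per cohort — a near-critical, intermittently congested
  unit.
* **Missingness and diagnosis-mix rates** (Other ≈ 3%, Unknown 6% /
  20%, missing onset 4–5%, missing recorded ABCD 5% pre-era and 100%
  post-era since the new form has no legacy field, co-enrolment flag
  2–3%) were set so the exclusion cascade's losses approximate the
  published raw→final cohort reductions (2942→~2465 and 2929→~1992).

What the generator does **not** emulate: correlations between
checkboxes beyond the diagnosis conditioning, secular trends in
referral practice, no-show behaviour (off by default), multi-site
routing, and any real covariance between symptoms and the
onset-to-referral delay. Consequently, passing tests demonstrate that
the triage mechanism produces the expected ordering effects under
plausible conditions — not that effect sizes transfer to any real
unit's data, and the large low-stratum improvements seen under the
default congested conditions should be read as mechanism, not
magnitude.

## Experiment pipeline and reproducibility

`run_experiment` generates both cohorts, simulates the historical
cohort under `ABCD_DESC` and the prospective one under
`WEIGHTED_QUEUE`, and reports the six-stratum comparison. Simulation
operates on every scoreable referral (onset present); the analysis
cascade — diagnosis restriction, missing dates, era-specific listwise
deletion, co-enrolment exclusion, in that fixed logged order — is
applied afterwards to the arrival-augmented datasets, because final
diagnosis is unknown at triage time and pre-filtering would understate
the unit's true load. All randomness derives from one seed through
named `SeedSequence` child streams; two runs from the same config and
seed produce byte-identical output bundles, and the run log records the
version, seed, and config hash needed to re-run.

## Numerical notes and edge cases

* Anchor fits reproduce every anchor to 1e−10 relative; anchor risks
  must be non-decreasing and < 1, horizons strictly increasing.
* The weighted log-rank variance term skips event times with one
  subject at risk; a zero-variance, zero-score comparison (e.g., two
  identical single-record groups) returns chi-squared 0 rather than
  0/0; zero variance with a non-zero score is an error.
* Empty report strata yield flagged rows with NaN statistics, not
  failures; unreached medians are NaN with a "not reached" note.
* Generated continuous fields are rounded to one decimal; band limits
  sit 0.1 below each scoring threshold so rounding can never flip a
  component point.
* File I/O stores missing values as empty cells (never 0) and floats
  via `repr`, making text round-trips bit-exact.
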