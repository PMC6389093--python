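"""Referral records, cohort containers, filter cascade, and file I/O.

A referral is one faxed request for a TIA-unit appointment: demographics,
blood pressure, symptom checkboxes, diabetes status, the symptom-onset and
referral timestamps, and (once the patient has been seen) the unit-arrival
timestamp and final neurologist diagnosis.

Cohort preparation follows a fixed, logged cascade:

1. ``diagnosis`` — keep only TIA/minor-stroke and mimic diagnoses
   (``OTHER`` and ``UNKNOWN`` are dropped);
2. ``dates`` — drop referrals missing the symptom-onset timestamp (and,
   when the dataset carries arrivals, missing the arrival timestamp);
3. ``abcd`` — in the pre-queue era only, drop referrals missing the
   staff-recorded ABCD score (listwise deletion; the post-queue era
   mean-imputes instead, downstream of this module);
4. ``spectra`` — drop referrals flagged as co-enrolled in the concurrent
   imaging study, whose early imaging could bias booking priority.

Files are plain delimited text (RFC-4180 CSV with a header row) or JSON
records; missing values are empty cells / nulls, never zeroes.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Sequence


class Diagnosis(enum.Enum):
    """Final neurologist diagnosis; UNKNOWN is the default null when no
    diagnosis was charted (e.g. the patient never attended)."""

    TIA_MINOR_STROKE = "TIA_MINOR_STROKE"
    MIMIC = "MIMIC"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class Cohort(enum.Enum):
    PRE_QUEUE = "PRE_QUEUE"
    POST_QUEUE = "POST_QUEUE"


ANALYSIS_DIAGNOSES = frozenset({Diagnosis.TIA_MINOR_STROKE, Diagnosis.MIMIC})


class SchemaError(ValueError):
    """A referral file is missing a mandatory column."""


class MalformedRowError(ValueError):
    """A referral file row could not be parsed; carries the line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class Referral:
    """One referred patient.

    All clinical fields may be missing (``None``); timestamps are
    timezone-naive local times (the unit is a single site).
    """

    id: str
    referral_datetime: datetime
    age_years: float | None = None
    systolic_mmHg: float | None = None
    diastolic_mmHg: float | None = None
    symptoms: dict[str, int] = field(default_factory=dict)
    duration_minutes: float | None = None
    diabetes: int = 0
    onset_datetime: datetime | None = None
    arrival_datetime: datetime | None = None
    abcd_score_recorded: int | None = None
    diagnosis: Diagnosis = Diagnosis.UNKNOWN
    cohort: Cohort = Cohort.POST_QUEUE
    spectra_flag: int = 0
    imputed_fields: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.onset_datetime is not None and self.onset_datetime > self.referral_datetime:
            raise ValueError(
                f"referral {self.id}: onset {self.onset_datetime} after "
                f"referral {self.referral_datetime}"
            )
        if (
            self.arrival_datetime is not None
            and self.arrival_datetime < self.referral_datetime
        ):
            raise ValueError(
                f"referral {self.id}: arrival {self.arrival_datetime} before "
                f"referral {self.referral_datetime}"
            )
        if self.abcd_score_recorded is not None and not (
            0 <= self.abcd_score_recorded <= 6
        ):
            raise ValueError(
                f"referral {self.id}: recorded ABCD score "
                f"{self.abcd_score_recorded} outside [0, 6]"
            )


@dataclass
class CohortDataset:
    """An ordered collection of referrals with a cohort tag and, once
    filtered, the per-step removal counts of the cascade."""

    referrals: list[Referral]
    label: Cohort
    filter_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.referrals)

    def __iter__(self):
        return iter(self.referrals)


FILTER_STEPS = ("diagnosis", "dates", "abcd", "spectra")


def apply_cohort_filters(
    raw: CohortDataset,
    era: Cohort | None = None,
    require_arrival: bool = False,
) -> CohortDataset:
    """Run the four-step exclusion cascade and log removals per step.

    ``era`` defaults to the dataset's own label.  ``require_arrival``
    extends the missing-dates step to referrals without an arrival
    timestamp — used when filtering an evaluation dataset that already
    carries arrivals, not a pre-booking referral stream.

    Idempotent: filtering an already-filtered dataset removes nothing.
    """
    era = era if era is not None else raw.label
    if not isinstance(era, Cohort):
        raise ValueError(f"unknown cohort era: {era!r}")

    log = {step: 0 for step in FILTER_STEPS}
    kept = list(raw.referrals)

    def drop(step: str, predicate) -> None:
        nonlocal kept
        survivors = [r for r in kept if not predicate(r)]
        log[step] = len(kept) - len(survivors)
        kept = survivors

    drop("diagnosis", lambda r: r.diagnosis not in ANALYSIS_DIAGNOSES)
    drop(
        "dates",
        lambda r: r.onset_datetime is None
        or (require_arrival and r.arrival_datetime is None),
    )
    if era is Cohort.PRE_QUEUE:
        drop("abcd", lambda r: r.abcd_score_recorded is None)
    drop("spectra", lambda r: bool(r.spectra_flag))

    return CohortDataset(referrals=kept, label=era, filter_log=log)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ("id", "cohort", "diagnosis", "referral_datetime")
_SCALAR_COLUMNS = (
    "id",
    "cohort",
    "diagnosis",
    "age_years",
    "systolic_mmHg",
    "diastolic_mmHg",
    "duration_minutes",
    "diabetes",
    "onset_datetime",
    "referral_datetime",
    "arrival_datetime",
    "abcd_score_recorded",
    "spectra_flag",
    "imputed_fields",
)
_SYMPTOM_PREFIX = "sym_"


def _fmt_float(x: float | None) -> str:
    return "" if x is None else repr(float(x))


def _fmt_dt(x: datetime | None) -> str:
    return "" if x is None else x.isoformat()


def _parse_float(s: str) -> float | None:
    return None if s == "" else float(s)


def _parse_int(s: str) -> int | None:
    return None if s == "" else int(s)


def _parse_dt(s: str) -> datetime | None:
    return None if s == "" else datetime.fromisoformat(s)


def _referral_row(r: Referral, symptom_keys: Sequence[str]) -> dict[str, str]:
    row = {
        "id": r.id,
        "cohort": r.cohort.value,
        "diagnosis": r.diagnosis.value,
        "age_years": _fmt_float(r.age_years),
        "systolic_mmHg": _fmt_float(r.systolic_mmHg),
        "diastolic_mmHg": _fmt_float(r.diastolic_mmHg),
        "duration_minutes": _fmt_float(r.duration_minutes),
        "diabetes": str(int(r.diabetes)),
        "onset_datetime": _fmt_dt(r.onset_datetime),
        "referral_datetime": _fmt_dt(r.referral_datetime),
        "arrival_datetime": _fmt_dt(r.arrival_datetime),
        "abcd_score_recorded": "" if r.abcd_score_recorded is None else str(r.abcd_score_recorded),
        "spectra_flag": str(int(r.spectra_flag)),
        "imputed_fields": ";".join(sorted(r.imputed_fields)),
    }
    for key in symptom_keys:
        row[_SYMPTOM_PREFIX + key] = (
            "" if key not in r.symptoms else str(int(r.symptoms[key]))
        )
    return row


def _row_to_referral(row: dict[str, str], symptom_keys: Sequence[str], line: int) -> Referral:
    try:
        symptoms = {}
        for key in symptom_keys:
            cell = row.get(_SYMPTOM_PREFIX + key, "")
            if cell != "":
                symptoms[key] = int(cell)
        imputed = row.get("imputed_fields", "")
        return Referral(
            id=row["id"],
            cohort=Cohort(row["cohort"]),
            diagnosis=Diagnosis(row["diagnosis"]),
            age_years=_parse_float(row.get("age_years", "")),
            systolic_mmHg=_parse_float(row.get("systolic_mmHg", "")),
            diastolic_mmHg=_parse_float(row.get("diastolic_mmHg", "")),
            duration_minutes=_parse_float(row.get("duration_minutes", "")),
            diabetes=int(row.get("diabetes", "0") or 0),
            onset_datetime=_parse_dt(row.get("onset_datetime", "")),
            referral_datetime=_parse_dt(row["referral_datetime"]),
            arrival_datetime=_parse_dt(row.get("arrival_datetime", "")),
            abcd_score_recorded=_parse_int(row.get("abcd_score_recorded", "")),
            spectra_flag=int(row.get("spectra_flag", "0") or 0),
            symptoms=symptoms,
            imputed_fields=frozenset(imputed.split(";")) if imputed else frozenset(),
        )
    except (KeyError, ValueError) as exc:
        raise MalformedRowError(line, str(exc)) from exc


def symptom_keys(dataset: CohortDataset) -> list[str]:
    keys: set[str] = set()
    for r in dataset.referrals:
        keys.update(r.symptoms)
    return sorted(keys)


def write_referrals(dataset: CohortDataset, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    keys = symptom_keys(dataset)
    if format == "csv":
        header = list(_SCALAR_COLUMNS) + [_SYMPTOM_PREFIX + k for k in keys]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=header)
            writer.writeheader()
            for r in dataset.referrals:
                writer.writerow(_referral_row(r, keys))
    elif format == "json":
        records = []
        for r in dataset.referrals:
            rec = dataclasses.asdict(r)
            rec["cohort"] = r.cohort.value
            rec["diagnosis"] = r.diagnosis.value
            for f in ("onset_datetime", "referral_datetime", "arrival_datetime"):
                rec[f] = _fmt_dt(getattr(r, f)) or None
            rec["imputed_fields"] = sorted(r.imputed_fields)
            records.append(rec)
        payload = {
            "label": dataset.label.value,
            "filter_log": dataset.filter_log,
            "referrals": records,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_referrals(
    path: str | Path, format: str = "csv", label: Cohort | None = None
) -> CohortDataset:
    """Read a referral table; malformed rows raise with their line number."""
    path = Path(path)
    if format == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file")
            missing = [c for c in _MANDATORY_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(
                    f"{path}: missing mandatory column(s): {', '.join(missing)}"
                )
            keys = [
                c[len(_SYMPTOM_PREFIX):]
                for c in reader.fieldnames
                if c.startswith(_SYMPTOM_PREFIX)
            ]
            referrals = []
            for line, row in enumerate(reader, start=2):
                if None in row or None in row.values():
                    raise MalformedRowError(line, "field count differs from header")
                referrals.append(_row_to_referral(row, keys, line))
    elif format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        referrals = []
        for i, rec in enumerate(payload["referrals"]):
            for col in _MANDATORY_COLUMNS:
                if col not in rec:
                    raise SchemaError(f"{path}: record {i} missing column: {col}")
            referrals.append(
                Referral(
                    id=rec["id"],
                    cohort=Cohort(rec["cohort"]),
                    diagnosis=Diagnosis(rec["diagnosis"]),
                    age_years=rec.get("age_years"),
                    systolic_mmHg=rec.get("systolic_mmHg"),
                    diastolic_mmHg=rec.get("diastolic_mmHg"),
                    duration_minutes=rec.get("duration_minutes"),
                    diabetes=int(rec.get("diabetes", 0)),
                    onset_datetime=_parse_dt(rec.get("onset_datetime") or ""),
                    referral_datetime=_parse_dt(rec["referral_datetime"]),
                    arrival_datetime=_parse_dt(rec.get("arrival_datetime") or ""),
                    abcd_score_recorded=rec.get("abcd_score_recorded"),
                    spectra_flag=int(rec.get("spectra_flag", 0)),
                    symptoms={k: int(v) for k, v in (rec.get("symptoms") or {}).items()},
                    imputed_fields=frozenset(rec.get("imputed_fields") or ()),
                )
            )
        if label is None and "label" in payload:
            label = Cohort(payload["label"])
    else:
        raise ValueError(f"unknown format: {format!r}")

    if label is None:
        label = referrals[0].cohort if referrals else Cohort.POST_QUEUE
    return CohortDataset(referrals=referrals, label=label)


def with_arrivals(dataset: CohortDataset, arrivals: dict[str, datetime | None]) -> CohortDataset:
    """Return a copy of the dataset with arrival timestamps attached
    (ids absent from ``arrivals``, or mapped to None, stay unarrived)."""
    updated = [
        replace(r, arrival_datetime=arrivals.get(r.id)) if arrivals.get(r.id) else r
        for r in dataset.referrals
    ]
    return CohortDataset(updated, dataset.label, dict(dataset.filter_log))
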