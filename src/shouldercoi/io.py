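"""Reading and writing cohorts as delimited-text tables.

A cohort is stored as four CSV files with ISO-8601 dates:

* ``patients.csv``  -- patient_id, age, sex, municipality, referrals,
  surgeries, postoperative_rehab
* ``visits.csv``    -- patient_id, date, provider, codes (``;``-separated)
* ``sickleave.csv`` -- patient_id, start, end, grade
* ``events.csv``    -- patient_id, date, kind (xray/ultrasound/prescription),
  detail (drug class for prescriptions)
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import (
    DrugClass,
    ImagingEvent,
    MedicationPrescription,
    Modality,
    PatientRecord,
    Provider,
    Sex,
    SickLeavePrescription,
    VisitEvent,
)
from .costing import PatientCostSummary
from .errors import InputError

__all__ = ["COHORT_TABLES", "write_cohort", "read_cohort", "summaries_to_frame"]

COHORT_TABLES = ("patients.csv", "visits.csv", "sickleave.csv", "events.csv")


def write_cohort(records: Sequence[PatientRecord], outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as the four delimited-text tables; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    patients = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex.value for r in records],
            "municipality": [r.municipality for r in records],
            "referrals": [r.referrals for r in records],
            "surgeries": [r.surgeries for r in records],
            "postoperative_rehab": [int(r.postoperative_rehab) for r in records],
        }
    )
    visits = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "date": v.date.isoformat(),
                "provider": v.provider.value,
                "codes": ";".join(v.codes),
            }
            for r in records
            for v in r.visits
        ],
        columns=["patient_id", "date", "provider", "codes"],
    )
    sickleave = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "start": s.start.isoformat(),
                "end": s.end.isoformat(),
                "grade": s.grade,
            }
            for r in records
            for s in r.sick_leaves
        ],
        columns=["patient_id", "start", "end", "grade"],
    )
    events = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "date": ev.date.isoformat(),
                "kind": ev.modality.value,
                "detail": "",
            }
            for r in records
            for ev in r.imaging
        ]
        + [
            {
                "patient_id": r.patient_id,
                "date": p.date.isoformat(),
                "kind": "prescription",
                "detail": p.drug_class.value,
            }
            for r in records
            for p in r.prescriptions
        ],
        columns=["patient_id", "date", "kind", "detail"],
    )

    paths = {}
    for name, df in (
        ("patients.csv", patients),
        ("visits.csv", visits),
        ("sickleave.csv", sickleave),
        ("events.csv", events),
    ):
        path = outdir / name
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{table}: missing columns {missing}")


def _parse_date(value: str, table: str, row: int, column: str) -> date:
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise InputError(f"{table} row {row}, column '{column}': invalid date {value!r}") from exc


def read_cohort(indir: str | Path) -> list[PatientRecord]:
    """Read a cohort from the four delimited-text tables.

    Schema violations raise :class:`InputError` naming the table, row and
    column.
    """
    indir = Path(indir)
    frames = {}
    for name in COHORT_TABLES:
        path = indir / name
        if not path.exists():
            raise InputError(f"cohort table missing: {path}")
        frames[name] = pd.read_csv(path, dtype=str, keep_default_na=False)

    pats = frames["patients.csv"]
    _require_columns(
        pats,
        ["patient_id", "age", "sex", "municipality", "referrals", "surgeries", "postoperative_rehab"],
        "patients.csv",
    )

    visits_by_pid: dict[str, list[VisitEvent]] = {}
    vis = frames["visits.csv"]
    _require_columns(vis, ["patient_id", "date", "provider", "codes"], "visits.csv")
    for i, row in vis.iterrows():
        try:
            provider = Provider(row["provider"])
        except ValueError as exc:
            raise InputError(
                f"visits.csv row {i}, column 'provider': unknown provider {row['provider']!r}"
            ) from exc
        visits_by_pid.setdefault(row["patient_id"], []).append(
            VisitEvent(
                date=_parse_date(row["date"], "visits.csv", i, "date"),
                provider=provider,
                codes=tuple(c for c in str(row["codes"]).split(";") if c),
            )
        )

    sl_by_pid: dict[str, list[SickLeavePrescription]] = {}
    sl = frames["sickleave.csv"]
    _require_columns(sl, ["patient_id", "start", "end", "grade"], "sickleave.csv")
    for i, row in sl.iterrows():
        try:
            grade = int(row["grade"])
        except ValueError as exc:
            raise InputError(
                f"sickleave.csv row {i}, column 'grade': not an integer {row['grade']!r}"
            ) from exc
        sl_by_pid.setdefault(row["patient_id"], []).append(
            SickLeavePrescription(
                start=_parse_date(row["start"], "sickleave.csv", i, "start"),
                end=_parse_date(row["end"], "sickleave.csv", i, "end"),
                grade=grade,
            )
        )

    imaging_by_pid: dict[str, list[ImagingEvent]] = {}
    rx_by_pid: dict[str, list[MedicationPrescription]] = {}
    ev = frames["events.csv"]
    _require_columns(ev, ["patient_id", "date", "kind", "detail"], "events.csv")
    for i, row in ev.iterrows():
        d = _parse_date(row["date"], "events.csv", i, "date")
        kind = row["kind"]
        if kind in (Modality.XRAY.value, Modality.ULTRASOUND.value):
            imaging_by_pid.setdefault(row["patient_id"], []).append(
                ImagingEvent(d, Modality(kind))
            )
        elif kind == "prescription":
            drug = DrugClass(row["detail"]) if row["detail"] else DrugClass.OTHER
            rx_by_pid.setdefault(row["patient_id"], []).append(
                MedicationPrescription(d, drug)
            )
        else:
            raise InputError(f"events.csv row {i}, column 'kind': unknown kind {kind!r}")

    records = []
    for i, row in pats.iterrows():
        pid = row["patient_id"]
        try:
            age = int(row["age"])
            sex = Sex(row["sex"])
            referrals = int(row["referrals"])
            surgeries = int(row["surgeries"])
            postop = bool(int(row["postoperative_rehab"]))
        except ValueError as exc:
            raise InputError(f"patients.csv row {i}: {exc}") from exc
        records.append(
            PatientRecord(
                patient_id=pid,
                age=age,
                sex=sex,
                municipality=row["municipality"],
                visits=visits_by_pid.get(pid, []),
                sick_leaves=sl_by_pid.get(pid, []),
                prescriptions=rx_by_pid.get(pid, []),
                imaging=imaging_by_pid.get(pid, []),
                referrals=referrals,
                surgeries=surgeries,
                postoperative_rehab=postop,
            )
        )
    return records


def summaries_to_frame(summaries: Sequence[PatientCostSummary]) -> pd.DataFrame:
    """Per-patient cost table, one row per patient, components in table order."""
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in summaries],
            "gp": [s.gp for s in summaries],
            "pt": [s.pt for s in summaries],
            "xray": [s.xray for s in summaries],
            "ultrasound": [s.ultrasound for s in summaries],
            "medicine": [s.medicine for s in summaries],
            "healthcare_total": [s.healthcare_total for s in summaries],
            "sick_leave_day_equivalents": [s.sick_leave_day_equivalents for s in summaries],
            "sick_leave": [s.sick_leave for s in summaries],
            "total": [s.total for s in summaries],
        }
    )
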