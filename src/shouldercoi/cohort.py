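"""Patient records, ICD-10 shoulder-diagnosis classification and treatment episodes.

The study population is adults (20-64 years) consulting primary care --
general practitioner (GP) or physiotherapist (PT) -- for shoulder pain in
two municipalities, observed over a six-month window.  Visits carry ICD-10
codes; 29 codes qualify a visit, grouped into four diagnosis categories
(subacromial/nonspecific pain, stiffness, fractures, dislocations).  A
treatment episode spans consecutive qualifying visits with no gap longer
than one month, except across the summer-holiday period where the allowed
gap doubles.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from .errors import InputError

__all__ = [
    "Provider",
    "Sex",
    "Modality",
    "DrugClass",
    "DiagnosisCategory",
    "DurationCategory",
    "Window",
    "VisitEvent",
    "SickLeavePrescription",
    "MedicationPrescription",
    "ImagingEvent",
    "EpisodeSummary",
    "PatientRecord",
    "CATEGORY_CODES",
    "DEFAULT_MUNICIPALITIES",
    "DEFAULT_GAP_DAYS",
    "normalize_code",
    "classify_diagnosis",
    "include_patient",
    "assign_category",
    "qualifying_visits",
    "duration_category",
    "build_episode",
    "default_holiday_window",
]


class Provider(str, enum.Enum):
    GP = "GP"
    PT = "PT"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Modality(str, enum.Enum):
    XRAY = "xray"
    ULTRASOUND = "ultrasound"


class DrugClass(str, enum.Enum):
    ANALGESIC = "analgesic"
    NSAID = "NSAID"
    OTHER = "other"


class DiagnosisCategory(str, enum.Enum):
    SUBACROMIAL_PAIN = "subacromial_pain"
    STIFFNESS = "stiffness"
    FRACTURE = "fracture"
    DISLOCATION = "dislocation"
    NOT_QUALIFYING = "not_qualifying"


class DurationCategory(str, enum.Enum):
    W0_6 = "w0_6"
    W7_12 = "w7_12"
    W12_26 = "w12_26"
    GT_6M = "gt_6m"


DEFAULT_MUNICIPALITIES: tuple[str, ...] = ("municipality_a", "municipality_b")

#: Default gap rule: "at least one visit per month" read as <= 31 days.
DEFAULT_GAP_DAYS = 31


def _expand_code_range(token: str) -> list[str]:
    """Expand a compact ICD-10 range like ``M751-9`` to M751..M759."""
    m = re.fullmatch(r"([A-Z]\d{2})(\d)-(\d)", token)
    if not m:
        return [token]
    stem, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
    return [f"{stem}{d}" for d in range(lo, hi + 1)]


def _expand_all(tokens: Iterable[str]) -> frozenset[str]:
    out: set[str] = set()
    for t in tokens:
        out.update(_expand_code_range(t))
    return frozenset(out)


# The 29 qualifying codes, grouped into the four diagnosis categories.
CATEGORY_CODES: dict[DiagnosisCategory, frozenset[str]] = {
    DiagnosisCategory.SUBACROMIAL_PAIN: _expand_all(
        ["M751-9", "M759P", "M709", "M779", "M791", "M799",
         "M255", "M255B", "M629", "M795", "M796B"]
    ),
    DiagnosisCategory.STIFFNESS: _expand_all(["M750", "M190B", "M192B"]),
    DiagnosisCategory.FRACTURE: _expand_all(["S420", "S4200", "S429"]),
    DiagnosisCategory.DISLOCATION: _expand_all(["S430", "S431", "S435", "S460"]),
}

_CODE_TO_CATEGORY: dict[str, DiagnosisCategory] = {
    code: cat for cat, codes in CATEGORY_CODES.items() for code in codes
}


def normalize_code(code: str) -> str:
    """Normalize an ICD-10 code string: strip dots/whitespace, upper-case."""
    return code.replace(".", "").replace(" ", "").strip().upper()


def classify_diagnosis(code: str) -> DiagnosisCategory:
    """Map an ICD-10 code to its shoulder-pain diagnosis category.

    Matching is case-insensitive on the normalized code (dots removed).
    Codes outside the 29 qualifying ones map to ``NOT_QUALIFYING``.
    """
    if not isinstance(code, str) or not code.strip():
        raise InputError("diagnosis code must be a non-empty string")
    return _CODE_TO_CATEGORY.get(normalize_code(code), DiagnosisCategory.NOT_QUALIFYING)


@dataclass(frozen=True)
class Window:
    """A closed calendar interval [start, end], e.g. the 6-month study period."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(f"window end {self.end} precedes start {self.start}")

    @property
    def n_days(self) -> int:
        """Number of calendar days in the window, inclusive of both ends."""
        return (self.end - self.start).days + 1

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


def default_holiday_window(window: Window) -> Window:
    """Swedish primary-care holiday season (July 1 - August 15) of the window's start year."""
    y = window.start.year
    return Window(date(y, 7, 1), date(y, 8, 15))


@dataclass(frozen=True)
class VisitEvent:
    date: date
    provider: Provider
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.codes:
            raise InputError("visit must carry at least one diagnostic code")

    def qualifies(self) -> bool:
        return any(
            classify_diagnosis(c) is not DiagnosisCategory.NOT_QUALIFYING
            for c in self.codes
        )


#: Sick-leave grades a physician can prescribe (% of full working time).
ALLOWED_GRADES = (25, 50, 75, 100)


@dataclass(frozen=True)
class SickLeavePrescription:
    start: date
    end: date
    grade: int  # percent of full working time

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError("sick-leave end precedes start")
        if self.grade not in ALLOWED_GRADES:
            raise InputError(f"sick-leave grade must be one of {ALLOWED_GRADES}, got {self.grade}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class MedicationPrescription:
    date: date
    drug_class: DrugClass = DrugClass.ANALGESIC


@dataclass(frozen=True)
class ImagingEvent:
    date: date
    modality: Modality


@dataclass(frozen=True)
class EpisodeSummary:
    """A treatment episode: first to last qualifying visit under the gap rule."""

    first_visit: date
    last_visit: date
    duration_days: int
    duration_category: DurationCategory
    left_censored: bool
    right_censored: bool


@dataclass
class PatientRecord:
    """One insured person's demographics plus all shoulder-related events."""

    patient_id: str
    age: int
    sex: Sex
    municipality: str
    visits: list[VisitEvent] = field(default_factory=list)
    sick_leaves: list[SickLeavePrescription] = field(default_factory=list)
    prescriptions: list[MedicationPrescription] = field(default_factory=list)
    imaging: list[ImagingEvent] = field(default_factory=list)
    referrals: int = 0
    surgeries: int = 0
    postoperative_rehab: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.age <= 120:
            raise InputError(f"age {self.age} outside [0, 120] for patient {self.patient_id}")
        if self.referrals < 0 or self.surgeries < 0:
            raise InputError(f"negative event count for patient {self.patient_id}")
        self.visits = sorted(self.visits, key=lambda v: v.date)

    @property
    def n_gp_visits(self) -> int:
        return sum(1 for v in self.visits if v.provider is Provider.GP)

    @property
    def n_pt_visits(self) -> int:
        return sum(1 for v in self.visits if v.provider is Provider.PT)

    def n_imaging(self, modality: Modality) -> int:
        return sum(1 for ev in self.imaging if ev.modality is modality)


def qualifying_visits(record: PatientRecord) -> list[VisitEvent]:
    """Visits carrying at least one qualifying shoulder code, in date order."""
    return [v for v in record.visits if v.qualifies()]


def include_patient(
    record: PatientRecord,
    window: Window,
    municipalities: Sequence[str] = DEFAULT_MUNICIPALITIES,
    age_range: tuple[int, int] = (20, 64),
) -> bool:
    """Study inclusion: age 20-64 (inclusive), resident in a study municipality,
    and at least one in-window visit with a qualifying code."""
    lo, hi = age_range
    if not lo <= record.age <= hi:
        return False
    if record.municipality not in municipalities:
        return False
    return any(window.contains(v.date) for v in qualifying_visits(record))


def assign_category(record: PatientRecord, window: Window | None = None) -> DiagnosisCategory:
    """Diagnosis category of the first qualifying (in-window, if given) visit."""
    for v in qualifying_visits(record):
        if window is not None and not window.contains(v.date):
            continue
        for c in v.codes:
            cat = classify_diagnosis(c)
            if cat is not DiagnosisCategory.NOT_QUALIFYING:
                return cat
    return DiagnosisCategory.NOT_QUALIFYING


def duration_category(duration_days: int) -> DurationCategory:
    """Bucket an episode duration: 0-6 weeks, 7-12 weeks, 12-26 weeks, > 6 months.

    Half-open day intervals: [0, 42] -> w0_6, (42, 84] -> w7_12,
    (84, 182] -> w12_26, > 182 -> gt_6m.
    """
    if duration_days < 0:
        raise InputError(f"duration_days must be >= 0, got {duration_days}")
    if duration_days <= 42:
        return DurationCategory.W0_6
    if duration_days <= 84:
        return DurationCategory.W7_12
    if duration_days <= 182:
        return DurationCategory.W12_26
    return DurationCategory.GT_6M


def _gap_allowance(prev: date, nxt: date, gap_days: int, holiday: Window | None) -> int:
    """Allowed inter-visit gap; doubled when the gap interval overlaps the holiday window."""
    if holiday is not None and prev <= holiday.end and nxt >= holiday.start:
        return 2 * gap_days
    return gap_days


def build_episode(
    visits: Sequence[VisitEvent],
    window: Window,
    gap_days: int = DEFAULT_GAP_DAYS,
    holiday_window: Window | None = None,
) -> EpisodeSummary:
    """Construct the treatment episode containing the first in-window visit.

    Visits are chained while each inter-visit gap is at most ``gap_days``
    (default 31: "at least one visit per month"); a gap that overlaps the
    holiday window may be up to twice that.  Censoring flags mark episodes
    touching a window boundary.  The result does not depend on the input
    ordering of ``visits``.
    """
    if not visits:
        raise InputError("build_episode requires at least one visit")
    if holiday_window is None:
        holiday_window = default_holiday_window(window)

    dates = sorted({v.date for v in visits})
    # Split the full visit history into maximal chains under the gap rule.
    chains: list[list[date]] = [[dates[0]]]
    for prev, nxt in zip(dates, dates[1:]):
        allowance = _gap_allowance(prev, nxt, gap_days, holiday_window)
        if (nxt - prev).days <= allowance:
            chains[-1].append(nxt)
        else:
            chains.append([nxt])

    episode = next(
        (c for c in chains if any(window.contains(d) for d in c)), None
    )
    if episode is None:
        raise InputError("no visit falls inside the measurement window")

    first, last = episode[0], episode[-1]
    dur = (last - first).days
    return EpisodeSummary(
        first_visit=first,
        last_visit=last,
        duration_days=dur,
        duration_category=duration_category(dur),
        left_censored=first <= window.start,
        right_censored=last >= window.end,
    )
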