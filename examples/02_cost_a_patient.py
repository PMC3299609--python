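"""Bottom-up costing of a single patient, human-capital vs friction valuation.

One GP visit, four physiotherapy sessions, an x-ray and two weeks of sick
leave (the second week at 50% grade) are valued with the default 2009 unit
prices.
"""

from dataclasses import replace
from datetime import date

from shouldercoi import (
    PatientRecord,
    ProductivityParameters,
    Provider,
    Sex,
    UnitCostSchedule,
    ValuationMethod,
    VisitEvent,
    Window,
    cost_patient,
    daily_productivity_cost,
)
from shouldercoi.cohort import ImagingEvent, Modality, SickLeavePrescription

window = Window(date(2009, 1, 1), date(2009, 6, 30))
record = PatientRecord(
    patient_id="example",
    age=45,
    sex=Sex.FEMALE,
    municipality="municipality_a",
    visits=[VisitEvent(date(2009, 3, 2), Provider.GP, ("M751",))]
    + [VisitEvent(date(2009, 3, 9 + 7 * k), Provider.PT, ("M751",)) for k in range(4)],
    imaging=[ImagingEvent(date(2009, 3, 2), Modality.XRAY)],
    sick_leaves=[
        SickLeavePrescription(date(2009, 3, 2), date(2009, 3, 8), grade=100),
        SickLeavePrescription(date(2009, 3, 9), date(2009, 3, 15), grade=50),
    ],
)

summary = cost_patient(record, window)
print(f"healthcare total : EUR {summary.healthcare_total:8.2f}")
print(f"  GP {summary.gp:.0f} + PT {summary.pt:.0f} + x-ray {summary.xray:.0f}")
print(f"sick leave       : EUR {summary.sick_leave:8.2f} "
      f"({summary.sick_leave_day_equivalents:.1f} day equivalents x EUR 205)")
print(f"total            : EUR {summary.total:8.2f}")
# 7 full days + 7 half days = 10.5 day equivalents; the 50% week costs half.

friction = replace(ProductivityParameters(), valuation_method=ValuationMethod.FRICTION)
summary_fr = cost_patient(record, window, params=friction)
print(f"friction method  : EUR {summary_fr.total:8.2f} "
      "(sick leave scaled by 0.387; healthcare unchanged)")

print(f"\nEUR/day behind the default price: a mean daily income of 122.02 "
      f"loaded with 40% social fares and 28% indirect taxes is "
      f"{daily_productivity_cost(122.02, ProductivityParameters()):.0f}")
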