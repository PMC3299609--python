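"""Classify ICD-10 codes and build a treatment episode from visit dates.

Demonstrates the two building blocks upstream of costing: mapping diagnosis
codes to the four shoulder-pain categories, and chaining visits into an
episode under the one-visit-per-month gap rule.
"""

from datetime import date

from shouldercoi import Provider, VisitEvent, Window, build_episode, classify_diagnosis

for code in ["M751", "M75.9P", "M750", "S420", "S430", "J069"]:
    print(f"{code:8s} -> {classify_diagnosis(code).value}")
# M-codes are soft-tissue diagnoses (subacromial pain, stiffness); S-codes are
# trauma (fracture, dislocation); J069 is unrelated and does not qualify.

window = Window(date(2009, 1, 1), date(2009, 6, 30))
visits = [
    VisitEvent(date(2009, 2, 2), Provider.GP, ("M751",)),
    VisitEvent(date(2009, 2, 24), Provider.PT, ("M751",)),
    VisitEvent(date(2009, 3, 20), Provider.PT, ("M751",)),
    VisitEvent(date(2009, 5, 28), Provider.PT, ("M751",)),  # 69-day gap: new episode
]
ep = build_episode(visits, window)
print(
    f"\nepisode: {ep.first_visit} .. {ep.last_visit} "
    f"({ep.duration_days} days, category {ep.duration_category.value})"
)
# The May visit is more than a month after the previous one (and not over the
# summer holiday), so the episode ends in March: 46 days, i.e. 7-12 weeks.
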