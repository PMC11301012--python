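"""Triage period averages under both notification policies and render a letter.

The morning average is Grade III on three readings, so it triggers under
either policy; an average resting on two readings would never trigger.
"""

from hbpnotify import (
    CategoryFlags,
    NotificationPolicy,
    PeriodAverage,
    compose_letter,
    evaluate_notification,
)

averages = [
    PeriodAverage("demo", "morning", 3, 185.0, 111.0),
    PeriodAverage("demo", "midday", 0, None, None),
    PeriodAverage("demo", "evening", 5, 162.0, 99.0),
]

for label in ("GRADE_II_PLUS", "GRADE_III_ONLY"):
    result = evaluate_notification(averages, NotificationPolicy(label))
    print(f"{label}: triggered={result.triggered}, grade={result.grade}, "
          f"periods={list(result.qualifying_periods)}")

result = evaluate_notification(averages, NotificationPolicy("GRADE_III_ONLY"))
flags = CategoryFlags(blood_sugar=True, renal=False, lipid=True, hematological=False, liver=False)
print("\n" + compose_letter(result, flags, averages))
print("Under the stricter policy only the Grade III morning average "
      "qualifies; the evening Grade II average alone would not.")
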