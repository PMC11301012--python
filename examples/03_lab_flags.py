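"""Flag a lab panel against the reference ranges and roll up categories.

A male panel with creatinine 1.20 mg/dL (above the male upper bound 1.04)
and blood sugar 126 mg/dL (above 109) flags the renal and blood-sugar
categories; everything else is mid-range.
"""

from hbpnotify import LabPanel, categorize, flag_analyte

panel = LabPanel(
    participant_id="demo",
    sex="male",
    crp=0.1, hemoglobin=15.0, platelets=24.0, leukocytes=6000,
    blood_sugar=126, ast=25, alt=25, creatinine=1.20, bun=14.0,
    uric_acid=5.0, sodium=141,
)

for analyte in ("creatinine", "blood_sugar", "hemoglobin"):
    print(f"{analyte}: {flag_analyte(analyte, getattr(panel, analyte), panel.sex)}")

flags = categorize(panel)
print("\ncategory flags:", flags.as_dict())
print("\nRenal and blood-sugar categories are abnormal; these are the lines "
      "an urgent notification letter would carry alongside the BP result.")
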