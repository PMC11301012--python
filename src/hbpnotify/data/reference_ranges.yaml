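# Blood test reference ranges (inclusive bounds), as used for flagging
# accompanying abnormalities in the urgent notification letters.
# A null bound means unbounded on that side. Sex-specific analytes carry
# separate male/female entries. Units noted per analyte.
version: 1
analytes:
  crp:                 # mg/dL
    both: {low: null, high: 0.30}
  hemoglobin:          # g/dL
    male: {low: 13.5, high: 17.5}
    female: {low: 11.5, high: 15.0}
  platelets:           # 10^4/uL
    both: {low: 14.0, high: 34.0}
  leukocytes:          # /uL
    both: {low: 3300, high: 9000}
  blood_sugar:         # mg/dL, nonfasting sample
    both: {low: 70, high: 109}
  ast:                 # IU/L (GOT)
    both: {low: 10, high: 40}
  alt:                 # IU/L (GPT)
    both: {low: 5, high: 45}
  creatinine:          # mg/dL
    male: {low: 0.61, high: 1.04}
    female: {low: 0.47, high: 0.79}
  bun:                 # mg/dL
    both: {low: 8.0, high: 20.0}
  uric_acid:           # mg/dL
    male: {low: 3.8, high: 7.0}
    female: {low: 2.5, high: 7.0}
  sodium:              # mEq/L
    both: {low: 137, high: 147}
# Morphology rule (not a numeric range): abnormal cells are present when
# immature blast cells are seen, multiple atypical cells are seen, or more
# than 30 erythroblasts are counted per 200 nucleated cells.
erythroblast_limit_per_200: 30
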