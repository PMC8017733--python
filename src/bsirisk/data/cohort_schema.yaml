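# Canonical cohort CSV schema: one row per blood-culture event.
# Dialect: comma-separated, UTF-8, "." decimal separator, header required.
# Empty cells mean missing. Booleans accept 0/1/true/false/yes/no (any case).
dialect:
  separator: ","
  encoding: utf-8
  decimal: "."
  header: required
units:
  creatinine: umol/L   # may be declared "mg/dL" in a per-file schema_config (x 88.4 on read)
columns:
  - {name: event_id, type: str, unit: "", required: true, description: unique event identifier}
  - {name: age, type: float, unit: years, description: ">= 18 (adult inclusion criterion)"}
  - {name: sex, type: category, values: [male, female]}
  - {name: temperature, type: float, unit: C, description: "body temperature at presentation, [25, 45]"}
  - {name: systolic_bp, type: float, unit: mmHg}
  - {name: respiratory_rate, type: float, unit: breaths/min}
  - {name: heart_rate, type: float, unit: beats/min}
  - {name: wbc, type: float, unit: 1e9/L, description: white blood cell count}
  - {name: neutrophils, type: float, unit: 1e9/L, description: absolute neutrophil count}
  - {name: lymphocytes, type: float, unit: 1e9/L, description: absolute lymphocyte count}
  - {name: platelets, type: float, unit: 1e9/L}
  - {name: creatinine, type: float, unit: umol/L}
  - {name: lactate, type: float, unit: mmol/L, description: serum lactate}
  - {name: crp, type: float, unit: mg/L, description: C-reactive protein}
  - {name: bilirubin, type: float, unit: umol/L}
  - {name: chills, type: bool, description: shaking chills reported}
  - {name: suspected_endocarditis, type: bool}
  - {name: indwelling_vascular_catheter, type: bool}
  - {name: altered_mentation, type: bool, description: qSOFA mentation component}
  - {name: sofa_baseline, type: int, unit: points, description: "pre-morbid SOFA total, [0, 24]"}
  - {name: sofa_admission, type: int, unit: points, description: "SOFA total at presentation, [0, 24]"}
  - {name: culture_outcome, type: category, required: true,
     values: [positive_relevant, negative, contaminant],
     description: contaminants are grouped with negatives in all accuracy analyses}
  - {name: pathogens, type: list, format: "species|gram;species|gram",
     description: "non-empty iff culture_outcome is positive_relevant; gram in {negative, positive}"}
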