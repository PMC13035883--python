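{
  "comment": "Published country-level averages of adult weight (kg), height (m) and BMI (kg/m^2), men/women. Heights stored in metres as printed; the preset loader converts to cm.",
  "countries": {
    "Germany": {"weight_kg_men": 87.8, "weight_kg_women": 71.4, "height_m_men": 1.80, "height_m_women": 1.66, "bmi_men": 27.1, "bmi_women": 25.9},
    "USA":     {"weight_kg_men": 91.5, "weight_kg_women": 78.9, "height_m_men": 1.77, "height_m_women": 1.63, "bmi_men": 29.3, "bmi_women": 29.7},
    "Japan":   {"weight_kg_men": 70.7, "weight_kg_women": 55.3, "height_m_men": 1.72, "height_m_women": 1.58, "bmi_men": 24.0, "bmi_women": 22.1},
    "Nigeria": {"weight_kg_men": 67.9, "weight_kg_women": 62.2, "height_m_men": 1.70, "height_m_women": 1.58, "bmi_men": 23.6, "bmi_women": 25.0},
    "Brazil":  {"weight_kg_men": 82.5, "weight_kg_women": 72.9, "height_m_men": 1.75, "height_m_women": 1.62, "bmi_men": 26.9, "bmi_women": 27.8}
  }
}
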