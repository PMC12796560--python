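{
  "description": "Six study arms of the multi-country flunixin IV dataset (65 horses, four countries). Doses are mg/kg or mg/horse as stated; sampling schedules are hours after the last dose. Schedules are a package default (the source studies' schedules were not published) chosen so that observed detection-time granularity is representable.",
  "version": 1,
  "arms": [
    {
      "label": "japan_single", "country": "Japan", "n_horses": 10,
      "dose": 1.1, "dose_unit": "mg/kg", "regimen": "single",
      "plasma_loq": 0.1, "urine_loq": 3.0,
      "age_range": [4, 10], "bw_range": [428, 506],
      "sexes": ["female"], "breed": "Thoroughbred",
      "plasma_schedule": [0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168],
      "urine_schedule": [24, 36, 48, 72, 96, 120, 168]
    },
    {
      "label": "japan_multi", "country": "Japan", "n_horses": 10,
      "dose": 1.1, "dose_unit": "mg/kg", "regimen": "q24hx5",
      "plasma_loq": 0.1, "urine_loq": 3.0,
      "age_range": [4, 9], "bw_range": [442, 530],
      "sexes": ["female"], "breed": "Thoroughbred",
      "plasma_schedule": [0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168],
      "urine_schedule": [24, 36, 48, 72, 96, 120, 168]
    },
    {
      "label": "usa_mgkg", "country": "USA", "n_horses": 16,
      "dose": 1.1, "dose_unit": "mg/kg", "regimen": "single",
      "plasma_loq": 1.0, "urine_loq": 0.5,
      "age_range": [5, 8], "bw_range": [491, 626],
      "sexes": ["female", "gelding"], "breed": "Thoroughbred",
      "plasma_schedule": [0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168],
      "urine_schedule": [24, 36, 48, 72, 96, 120, 168]
    },
    {
      "label": "usa_mghorse", "country": "USA", "n_horses": 11,
      "dose": 500, "dose_unit": "mg/horse", "regimen": "single",
      "plasma_loq": 1.0, "urine_loq": 0.5,
      "age_range": [3, 8], "bw_range": [469, 592],
      "sexes": ["female", "gelding"], "breed": "Thoroughbred",
      "plasma_schedule": [0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168],
      "urine_schedule": [24, 36, 48, 72, 96, 120, 168]
    },
    {
      "label": "uk_single", "country": "UK", "n_horses": 6,
      "dose": 1.1, "dose_unit": "mg/kg", "regimen": "single",
      "plasma_loq": 1.0, "urine_loq": 0.5,
      "age_range": [10, 22], "bw_range": [434, 537],
      "sexes": ["male", "gelding"], "breed": "Thoroughbred",
      "plasma_schedule": [0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168],
      "urine_schedule": [24, 36, 48, 72, 96, 120, 168]
    },
    {
      "label": "australia_single", "country": "Australia", "n_horses": 12,
      "dose": 1.1, "dose_unit": "mg/kg", "regimen": "single",
      "plasma_loq": 1.0, "urine_loq": 1.0,
      "age_range": [4, 12], "bw_range": [421, 524],
      "sexes": ["gelding"], "breed": "Standardbred",
      "plasma_schedule": [0.083, 0.25, 0.5, 1, 2, 4, 6, 8, 12, 24, 36, 48, 72, 96, 120, 144, 168],
      "urine_schedule": [24, 36, 48, 72, 96, 120, 168]
    }
  ]
}
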