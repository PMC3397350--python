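{
  "description": "Chinese DRI zinc reference values for adults (mg/day) plus IZiNCG mixed-diet absorption fractions and absorbed-zinc inadequacy thresholds. The insufficiency cutoff is insufficiency_fraction * RNI. Note the deliberate one-year stratum mismatch: RNI switches at age 50 (18-49 vs >=50) while the UL switches after age 50 (20-50 vs >50); both rule sets are preserved as published.",
  "rni_mg_day": {
    "male": [
      {"age_min": 20, "age_max": 49, "value": 15.0},
      {"age_min": 50, "age_max": null, "value": 11.5}
    ],
    "female": [
      {"age_min": 20, "age_max": null, "value": 11.5}
    ]
  },
  "insufficiency_fraction": {"numerator": 2, "denominator": 3},
  "ul_mg_day": {
    "male": [
      {"age_min": 20, "age_max": 50, "value": 45.0},
      {"age_min": 51, "age_max": null, "value": 37.0}
    ],
    "female": [
      {"age_min": 20, "age_max": null, "value": 37.0}
    ]
  },
  "absorption_fraction": {"male": 0.26, "female": 0.34},
  "absorbed_inadequacy_mg_day": {"male": 2.69, "female": 1.86}
}
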