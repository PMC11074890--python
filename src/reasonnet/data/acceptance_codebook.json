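{
  "group": "acceptance",
  "reasons": [
    {"code": "disease_risk", "label": "(Perceived high) disease risk", "categories": ["complacency", "calculation"]},
    {"code": "protecting_others", "label": "Protecting others", "categories": ["collective_responsibility"]},
    {"code": "back_to_normal_life", "label": "Back to normal life", "categories": ["complacency", "calculation"]},
    {"code": "confidence_in_vaccines", "label": "(High) confidence in vaccines", "categories": ["confidence"]},
    {"code": "vaccine_mandates", "label": "Vaccine mandates", "categories": ["confidence", "context"]},
    {"code": "progovernment", "label": "Progovernment", "categories": ["confidence"]},
    {"code": "social_norms", "label": "Social norms", "categories": ["complacency"]},
    {"code": "convenience", "label": "Convenience", "categories": ["convenience"]},
    {"code": "incentives", "label": "Incentives", "categories": ["calculation", "context"]},
    {"code": "trust_in_experts", "label": "Trust in experts", "categories": ["confidence"]}
  ]
}
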