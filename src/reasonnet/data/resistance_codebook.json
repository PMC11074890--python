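{
  "group": "resistance",
  "reasons": [
    {"code": "lack_of_vaccine_confidence", "label": "Lack of vaccine confidence", "categories": ["confidence", "calculation"]},
    {"code": "complacency", "label": "Complacency (low disease risk, no need, and no urgency)", "categories": ["complacency"]},
    {"code": "poor_health_status", "label": "Poor health status", "categories": ["confidence", "calculation"]},
    {"code": "vaccine_mandates", "label": "(Dislike) vaccine mandates", "categories": ["confidence", "context"]},
    {"code": "distrust_in_government", "label": "Distrust in government", "categories": ["confidence"]},
    {"code": "lack_of_social_support", "label": "Lack of social support", "categories": ["complacency", "convenience"]},
    {"code": "no_incentives", "label": "No incentives", "categories": ["calculation", "context"]},
    {"code": "inconvenience", "label": "Inconvenience", "categories": ["convenience"]},
    {"code": "social_norms", "label": "(Negative) social norms", "categories": ["complacency"]},
    {"code": "medical_preference", "label": "Medical preference (dislike vaccination)", "categories": ["confidence", "context"]}
  ]
}
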