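{
  "name": "generic-risk-of-bias-v1",
  "description": "Generic diagnostic-accuracy-style risk-of-bias checklist for studies measuring head tissue electrical conductivity. Items are templates: mark each relevant/irrelevant for a given study and assign a score in [0, 1] reflecting compliance.",
  "items": [
    {"item_id": "sample_representative", "description": "The tissue sample or participant group was representative of the population the study addresses."},
    {"item_id": "selection_criteria_reported", "description": "Inclusion and exclusion criteria for participants or specimens were clearly described."},
    {"item_id": "method_described_reproducibly", "description": "The measurement methodology was described in enough detail to be reproduced."},
    {"item_id": "measurement_conditions_reported", "description": "Measurement condition (in vivo, ex vivo, in vitro), temperature and applied frequency were reported."},
    {"item_id": "instrument_calibration", "description": "Instrumentation was calibrated or validated against a known standard."},
    {"item_id": "tissue_state_controlled", "description": "Tissue handling (time since excision, storage medium, hydration) was controlled or reported."},
    {"item_id": "replicates_reported", "description": "Repeated measurements and their dispersion were reported."},
    {"item_id": "analysis_blind_or_objective", "description": "Conductivity estimation was objective or blinded to expected values."},
    {"item_id": "model_assumptions_stated", "description": "Any computational head-model assumptions involved in the estimate were stated."},
    {"item_id": "withdrawals_explained", "description": "Excluded measurements or participants were reported and explained."},
    {"item_id": "demographics_reported", "description": "Participant age, sex and pathology were reported."}
  ]
}
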