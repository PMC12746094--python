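{
  "constraints": [
    {"structure": "ctv70", "metric": "min_dose", "bound": 66.5, "robust": true},
    {"structure": "ctv70", "metric": "max_dose", "bound": 74.9, "robust": true},
    {"structure": "ctv54", "metric": "min_dose", "bound": 51.54, "robust": true},
    {"structure": "cord", "metric": "max_dose", "bound": 45.0, "robust": true},
    {"structure": "body", "metric": "max_dose", "bound": 77.0, "robust": false},
    {"structure": "body", "metric": "per_field_max_dose", "bound": 47.0, "robust": false}
  ],
  "objectives": [
    {"priority": 1, "structure": "parotid_l", "metric": "mean_dose", "goal": 10.0, "sufficient": false, "robust": false},
    {"priority": 2, "structure": "parotid_r", "metric": "mean_dose", "goal": 10.0, "sufficient": false, "robust": false},
    {"priority": 3, "structure": "constrictor", "metric": "mean_dose", "goal": 20.0, "sufficient": false, "robust": false},
    {"priority": 4, "structure": "cord", "metric": "max_dose", "goal": 30.0, "sufficient": true, "robust": false},
    {"priority": 5, "structure": "body", "metric": "mean_dose", "goal": 5.0, "sufficient": false, "robust": false}
  ]
}
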