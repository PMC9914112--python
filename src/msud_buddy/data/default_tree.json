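{
  "version": 1,
  "nodes": [
    {
      "id": "root",
      "condition": [],
      "conclusion": {
        "label": "default_limits",
        "payload": {},
        "explanation": "Plasma panel absent or within configured target bands; age/weight-scaled allowances apply unchanged."
      },
      "cornerstone": {
        "age_months": 3,
        "weight_kg": 5.0,
        "plasma_leucine": 80,
        "plasma_isoleucine": 17,
        "plasma_valine": 55
      },
      "except": "high_leucine",
      "alt": null
    },
    {
      "id": "high_leucine",
      "condition": [
        {"attr": "plasma_leucine", "op": ">", "value": 200}
      ],
      "conclusion": {
        "label": "reduce_leucine",
        "payload": {"leucine_factor": 0.5},
        "explanation": "Plasma leucine above the configured target band: halve the daily leucine allowance and consult the metabolic dietitian. NON-CLINICAL PLACEHOLDER RULE."
      },
      "cornerstone": {
        "age_months": 3,
        "weight_kg": 5.0,
        "plasma_leucine": 250,
        "plasma_isoleucine": 17,
        "plasma_valine": 55
      },
      "except": null,
      "alt": "high_isoleucine"
    },
    {
      "id": "high_isoleucine",
      "condition": [
        {"attr": "plasma_isoleucine", "op": ">", "value": 400}
      ],
      "conclusion": {
        "label": "reduce_isoleucine",
        "payload": {"isoleucine_factor": 0.5},
        "explanation": "Plasma isoleucine above the configured target band: halve the daily isoleucine allowance and consult the metabolic dietitian. NON-CLINICAL PLACEHOLDER RULE."
      },
      "cornerstone": {
        "age_months": 3,
        "weight_kg": 5.0,
        "plasma_leucine": 80,
        "plasma_isoleucine": 450,
        "plasma_valine": 55
      },
      "except": null,
      "alt": "high_valine"
    },
    {
      "id": "high_valine",
      "condition": [
        {"attr": "plasma_valine", "op": ">", "value": 400}
      ],
      "conclusion": {
        "label": "reduce_valine",
        "payload": {"valine_factor": 0.5},
        "explanation": "Plasma valine above the configured target band: halve the daily valine allowance and consult the metabolic dietitian. NON-CLINICAL PLACEHOLDER RULE."
      },
      "cornerstone": {
        "age_months": 3,
        "weight_kg": 5.0,
        "plasma_leucine": 80,
        "plasma_isoleucine": 17,
        "plasma_valine": 450
      },
      "except": null,
      "alt": null
    }
  ],
  "root": "root"
}
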