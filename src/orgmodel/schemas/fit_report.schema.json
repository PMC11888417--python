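{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ORG fit report",
  "type": "object",
  "required": [
    "model_id", "params", "ci_low", "ci_high", "r_squared",
    "rms_nm", "rms_late_nm", "converged", "n_points", "flags"
  ],
  "properties": {
    "model_id": {"type": "string"},
    "params": {"type": "object", "additionalProperties": {"type": "number"}},
    "ci_low": {"type": "object", "additionalProperties": {"type": "number"}},
    "ci_high": {"type": "object", "additionalProperties": {"type": "number"}},
    "r_squared": {"type": ["number", "null"]},
    "rms_nm": {"type": "number"},
    "rms_late_nm": {"type": ["number", "null"]},
    "weights_applied": {"type": "string"},
    "converged": {"type": "boolean"},
    "n_points": {"type": "integer"},
    "flags": {"type": "object"}
  }
}
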