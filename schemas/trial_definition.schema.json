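{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Trial definition",
  "description": "Executable eligibility criteria for one clinical trial. A file may hold one such object or an array of them.",
  "type": "object",
  "required": ["trial_id", "criteria"],
  "additionalProperties": false,
  "properties": {
    "trial_id": {"type": "string", "minLength": 1},
    "registry_id": {"type": "string", "description": "Trial registry identifier, e.g. an NCT number."},
    "title": {"type": "string"},
    "principal_investigator": {"type": "string"},
    "criteria": {
      "type": "array",
      "minItems": 1,
      "items": {"$ref": "#/$defs/criterion"}
    }
  },
  "$defs": {
    "criterion": {
      "type": "object",
      "required": ["criterion_id", "polarity", "kind"],
      "additionalProperties": false,
      "properties": {
        "criterion_id": {"type": "string", "minLength": 1},
        "polarity": {"enum": ["inclusion", "exclusion"]},
        "kind": {
          "enum": ["concept_presence", "age_threshold", "gender_equals", "temporal_order", "value_range"]
        },
        "concept_ids": {
          "type": "array",
          "items": {"type": "string"},
          "description": "Primary concept set. For gender_equals: exactly one demographic gender concept."
        },
        "include_descendants": {
          "type": "boolean",
          "default": false,
          "description": "Expand concept sets to their is-a descendant closure before matching."
        },
        "comparator": {
          "enum": ["ge", "gt", "le", "lt", "eq"],
          "description": "Required for age_threshold and value_range."
        },
        "threshold": {
          "type": "number",
          "description": "Age in years (age_threshold) or measurement value (value_range)."
        },
        "unit": {
          "type": ["string", "null"],
          "description": "Optional unit check for value_range evidence."
        },
        "second_concept_ids": {
          "type": "array",
          "items": {"type": "string"},
          "description": "temporal_order only: the B side of 'A must happen before B'."
        },
        "allow_historical": {
          "type": "boolean",
          "default": true,
          "description": "Whether mentions flagged historical may qualify as evidence."
        }
      }
    }
  }
}
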