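{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Systematic-review database interchange (canonical JSON hierarchy)",
  "description": "One issue of a systematic-review database: reviews -> comparisons -> outcomes (forest plots) -> subgroups -> study entries. Canonical serialisation sorts object keys and preserves list order. Absent optional values are serialised as explicit nulls.",
  "type": "object",
  "required": ["issue_label", "reviews"],
  "properties": {
    "issue_label": {"type": "string"},
    "reviews": {"type": "array", "items": {"$ref": "#/$defs/review"}}
  },
  "$defs": {
    "review": {
      "type": "object",
      "required": ["review_id", "status", "is_methodology_group", "comparisons"],
      "properties": {
        "review_id": {"type": "string"},
        "title": {"type": "string"},
        "review_group": {"type": "string"},
        "status": {"enum": ["full", "protocol", "withdrawn"]},
        "is_methodology_group": {"type": "boolean"},
        "specialty_label": {"type": ["string", "null"]},
        "comparisons": {"type": "array", "items": {"$ref": "#/$defs/comparison"}}
      }
    },
    "comparison": {
      "type": "object",
      "required": ["comparison_id", "outcomes"],
      "properties": {
        "comparison_id": {"type": "string"},
        "name": {"type": "string"},
        "active_intervention_label": {"type": ["string", "null"]},
        "comparator_label": {"type": ["string", "null"]},
        "outcomes": {"type": "array", "items": {"$ref": "#/$defs/outcome_plot"}}
      }
    },
    "outcome_plot": {
      "type": "object",
      "required": ["outcome_id", "data_type", "subgroups"],
      "properties": {
        "outcome_id": {"type": "string"},
        "name": {"type": ["string", "null"]},
        "data_type": {"enum": ["dichotomous", "continuous", "generic", "oe_variance"]},
        "totals_displayed": {"type": "boolean"},
        "outcome_category_label": {"type": ["string", "null"]},
        "subgroups": {"type": "array", "items": {"$ref": "#/$defs/subgroup"}}
      }
    },
    "subgroup": {
      "type": "object",
      "required": ["studies"],
      "properties": {
        "name": {"type": "string"},
        "studies": {"type": "array", "items": {"$ref": "#/$defs/study_entry"}}
      }
    },
    "study_entry": {
      "type": "object",
      "required": ["study_id", "payload"],
      "properties": {
        "study_id": {"type": "string", "minLength": 1},
        "payload": {
          "oneOf": [
            {"$ref": "#/$defs/dichotomous"},
            {"$ref": "#/$defs/continuous"},
            {"$ref": "#/$defs/generic"},
            {"$ref": "#/$defs/oe_variance"}
          ]
        }
      }
    },
    "dichotomous": {
      "type": "object",
      "required": ["kind", "events_1", "total_1", "events_2", "total_2"],
      "properties": {
        "kind": {"const": "dichotomous"},
        "events_1": {"type": "integer", "minimum": 0},
        "total_1": {"type": "integer", "minimum": 0},
        "events_2": {"type": "integer", "minimum": 0},
        "total_2": {"type": "integer", "minimum": 0}
      }
    },
    "continuous": {
      "type": "object",
      "required": ["kind", "n_1", "n_2", "mean_1", "mean_2", "sd_1", "sd_2"],
      "properties": {
        "kind": {"const": "continuous"},
        "n_1": {"type": "integer", "minimum": 0},
        "n_2": {"type": "integer", "minimum": 0},
        "mean_1": {"type": "number"},
        "mean_2": {"type": "number"},
        "sd_1": {"type": "number", "minimum": 0},
        "sd_2": {"type": "number", "minimum": 0}
      }
    },
    "generic": {
      "type": "object",
      "required": ["kind", "estimate", "standard_error", "total_n"],
      "properties": {
        "kind": {"const": "generic"},
        "estimate": {"type": "number"},
        "standard_error": {"type": "number", "minimum": 0},
        "total_n": {"type": ["integer", "null"], "minimum": 0}
      }
    },
    "oe_variance": {
      "type": "object",
      "required": ["kind", "o_minus_e", "variance", "total_n"],
      "properties": {
        "kind": {"const": "oe_variance"},
        "o_minus_e": {"type": "number"},
        "variance": {"type": "number", "minimum": 0},
        "total_n": {"type": ["integer", "null"], "minimum": 0}
      }
    }
  }
}
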