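{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Respondent",
  "description": "One questionnaire response; batch files are JSON Lines with one object per line.",
  "type": "object",
  "required": ["age", "fitzpatrick", "personal_hx", "behaviors_before", "epochs", "residences"],
  "properties": {
    "id": {"type": ["string", "null"]},
    "age": {"type": "integer", "minimum": 18},
    "fitzpatrick": {"type": "integer", "minimum": 1, "maximum": 6},
    "personal_hx": {"type": "boolean"},
    "dx_age": {"type": ["integer", "null"], "minimum": 18},
    "dx_type": {
      "type": ["string", "null"],
      "enum": ["BCC", "SCC", "melanoma", "other", "don't know", null]
    },
    "family_hx": {
      "type": "array",
      "items": {"enum": ["BCC", "SCC", "melanoma", "other", "don't know"]},
      "uniqueItems": true
    },
    "behaviors_before": {"$ref": "#/$defs/behaviorSet"},
    "behaviors_after": {
      "oneOf": [{"$ref": "#/$defs/behaviorSet"}, {"type": "null"}]
    },
    "epochs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["age_band", "weekday_hours_per_day", "weekend_hours_per_day"],
        "properties": {
          "age_band": {"enum": ["0-13", "13-20", "20-40", "40-65", "65-80", "80+"]},
          "weekday_hours_per_day": {"type": "number", "minimum": 0, "maximum": 6},
          "weekend_hours_per_day": {"type": "number", "minimum": 0, "maximum": 6}
        }
      }
    },
    "residences": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["place", "start_age", "end_age"],
        "properties": {
          "place": {"type": "string", "description": "\"City, State\""},
          "start_age": {"type": "integer", "minimum": 0},
          "end_age": {"type": "integer", "minimum": 1}
        }
      }
    }
  },
  "$defs": {
    "behaviorSet": {
      "type": "object",
      "required": [
        "tanning_bed_visits", "blistering_sunburns", "sunscreen",
        "long_sleeves", "hat", "shade_seeking"
      ],
      "properties": {
        "tanning_bed_visits": {"enum": ["0", "1-5", "6-10", "11-100", ">100"]},
        "blistering_sunburns": {"enum": ["0", "1-5", "6-10", ">10"]},
        "sunscreen": {"enum": ["never", "rarely", "sometimes", "often", "always"]},
        "long_sleeves": {"enum": ["never", "rarely", "sometimes", "often", "always"]},
        "hat": {"enum": ["never", "rarely", "sometimes", "often", "always"]},
        "shade_seeking": {"enum": ["never", "rarely", "sometimes", "often", "always"]}
      }
    }
  }
}
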