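{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/adaptiveq/rulebase.schema.json",
  "title": "Rule base document",
  "description": "A condition catalogue plus clinical rules as 6-element tuples. parse_rulebase enforces these constraints (and referential ones the schema cannot express: ids resolve, kinds match slots, roles are disjoint, premises are non-empty).",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "conditions": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "kind"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "kind": {"enum": ["clinical", "nonclinical"]},
          "label": {"type": "string"},
          "category": {"type": "string"},
          "codes": {"type": "array", "items": {"type": "string"}},
          "default_code": {"type": "integer", "minimum": 0}
        }
      }
    },
    "rules": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "present_clinical": {"$ref": "#/$defs/idList"},
          "present_nonclinical": {"$ref": "#/$defs/idList"},
          "absent_clinical": {"$ref": "#/$defs/idList"},
          "absent_nonclinical": {"$ref": "#/$defs/idList"},
          "unions": {
            "type": "array",
            "items": {
              "type": "object",
              "additionalProperties": false,
              "properties": {
                "clinical": {"$ref": "#/$defs/idList"},
                "nonclinical": {"$ref": "#/$defs/idList"}
              }
            }
          },
          "action": {"type": "string"}
        }
      }
    }
  },
  "$defs": {
    "idList": {
      "type": "array",
      "items": {"type": "string", "minLength": 1}
    }
  }
}
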