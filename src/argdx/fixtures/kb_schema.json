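{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "argdx knowledge-base document",
  "description": "Schema of the YAML knowledge-base format (after YAML loading). Condition strings use 'predicate(subject, value)', 'predicate(value)' or bare tokens; disjunctive alternatives are joined with '+/'. The parser enforces these constraints itself; this schema documents the interface.",
  "type": "object",
  "required": ["registry"],
  "additionalProperties": false,
  "properties": {
    "registry": {
      "type": "array",
      "minItems": 1,
      "items": {
        "oneOf": [
          {"type": "string"},
          {
            "type": "object",
            "required": ["code"],
            "properties": {
              "code": {"type": "string", "minLength": 1},
              "label": {"type": "string"},
              "group": {"type": "string"}
            },
            "additionalProperties": false
          }
        ]
      }
    },
    "tables": {
      "type": ["array", "null"],
      "items": {
        "type": "object",
        "required": ["table_id", "presenting", "diseases", "rows"],
        "additionalProperties": false,
        "properties": {
          "table_id": {"type": "string", "minLength": 1},
          "presenting": {"type": "string", "minLength": 1},
          "diseases": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "string", "minLength": 1}
          },
          "rows": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["row_id"],
              "additionalProperties": false,
              "properties": {
                "row_id": {"type": "string", "minLength": 1},
                "parent": {"type": ["string", "null"]},
                "adds": {"type": "array", "items": {"type": "string", "minLength": 1}},
                "select": {"type": "array", "items": {"type": "string", "minLength": 1}}
              }
            }
          }
        }
      }
    }
  }
}
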