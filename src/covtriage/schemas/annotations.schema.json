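{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "covtriage/annotations.schema.json",
  "title": "Per-document concept annotations (SciLite-like export)",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["doc_id", "annotations"],
    "additionalProperties": false,
    "properties": {
      "doc_id": {"type": "string", "minLength": 1},
      "annotations": {
        "type": "array",
        "items": {
          "type": "object",
          "required": ["exact", "concept_id", "preferred_label", "axis", "field", "start", "end"],
          "additionalProperties": false,
          "properties": {
            "exact": {"type": "string", "description": "surface text as it appears in the field"},
            "concept_id": {"type": "string"},
            "preferred_label": {"type": "string"},
            "axis": {"type": "string", "enum": ["BMV", "CE", "CL", "CT", "CHEM", "DIS", "GL", "ORG", "PG"]},
            "field": {"type": "string", "enum": ["title", "abstract", "body", "keywords"]},
            "start": {"type": "integer", "minimum": 0, "description": "0-based inclusive character offset"},
            "end": {"type": "integer", "minimum": 1, "description": "0-based exclusive character offset"}
          }
        }
      }
    }
  }
}
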