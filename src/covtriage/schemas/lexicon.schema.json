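{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "covtriage/lexicon.schema.json",
  "title": "Concept lexicon (JSON dialect)",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["id", "axis", "preferred_label"],
    "additionalProperties": false,
    "properties": {
      "id": {"type": "string", "minLength": 1, "description": "CURIE identifier, unique in the lexicon"},
      "axis": {
        "type": "string",
        "enum": ["BMV", "CE", "CL", "CT", "CHEM", "DIS", "GL", "ORG", "PG"]
      },
      "preferred_label": {"type": "string", "minLength": 1},
      "synonyms": {"type": "array", "items": {"type": "string"}},
      "xrefs": {"type": "array", "items": {"type": "string"}}
    }
  }
}
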