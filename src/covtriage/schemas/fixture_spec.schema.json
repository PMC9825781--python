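{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "covtriage/fixture_spec.schema.json",
  "title": "Synthetic fixture specification",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "n_concepts_per_axis": {"type": "integer", "minimum": 0, "default": 2},
    "n_docs": {"type": "integer", "minimum": 0, "default": 60},
    "doc_length": {
      "type": "array", "items": {"type": "integer", "minimum": 1},
      "minItems": 2, "maxItems": 2, "default": [40, 80],
      "description": "inclusive [min, max] filler-token count per document"
    },
    "plant_rate": {"type": "number", "minimum": 0, "default": 0.6,
      "description": "expected distinct planted concepts per document per axis"},
    "relevance_slope": {"type": "number", "default": 1.2},
    "relevance_offset": {"type": "number", "default": 1.0},
    "n_topics": {"type": "integer", "minimum": 0, "default": 6},
    "ref_corpus_docs": {"type": "integer", "minimum": 0, "default": 200},
    "seed": {"type": "integer", "default": 0}
  }
}
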