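{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "lingsum serialized quantified sentence",
  "type": "object",
  "required": ["form", "quantifier", "scope", "summarizer",
               "summ_connective", "truth", "undefined", "text"],
  "properties": {
    "form": {"enum": ["type1", "type2"]},
    "quantifier": {"type": "string"},
    "scope": {"enum": ["ASD", "TD", "all"]},
    "pre_summarizer": {
      "type": ["array", "null"],
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "string"}],
        "minItems": 2,
        "maxItems": 2
      }
    },
    "pre_connective": {"enum": ["and", "or", null]},
    "summarizer": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "string"}],
        "minItems": 2,
        "maxItems": 2
      }
    },
    "summ_connective": {"enum": ["and", "or"]},
    "truth": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
    "undefined": {"type": "boolean"},
    "text": {"type": "string"}
  }
}
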