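{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/famrisk/pedigree.schema.json",
  "title": "famrisk pedigree document, version 1",
  "type": "object",
  "required": ["format", "version", "relatives"],
  "properties": {
    "format": {"const": "famrisk-pedigree"},
    "version": {"const": 1},
    "proband_note": {"type": "string"},
    "relatives": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["role", "affected"],
        "properties": {
          "role": {
            "enum": [
              "mother", "father",
              "maternal_grandmother", "maternal_grandfather",
              "paternal_grandmother", "paternal_grandfather",
              "maternal_aunt_uncle", "maternal_aunt_uncle_child",
              "paternal_aunt_uncle", "paternal_aunt_uncle_child",
              "sibling", "child"
            ]
          },
          "member_index": {"type": "integer", "minimum": 0},
          "affected": {"type": "boolean"},
          "age_at_diagnosis": {"type": "integer", "minimum": 1, "maximum": 120},
          "multiple_polyps": {"type": "boolean"},
          "other_related_cancers": {"type": "boolean"},
          "multiple_primary_crc": {"type": "boolean"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
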