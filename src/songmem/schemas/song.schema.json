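{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Song",
  "type": "object",
  "required": ["title", "phrases"],
  "properties": {
    "title": {"type": "string"},
    "beat_period_s": {"type": "number", "exclusiveMinimum": 0},
    "phrases": {
      "type": "array",
      "items": {
        "type": "array",
        "items": {
          "type": "object",
          "properties": {
            "word": {"type": ["string", "null"]},
            "items": {"type": "array", "items": {"type": "string"}},
            "pitch": {"type": ["string", "null"]},
            "duration_beats": {"type": "number", "exclusiveMinimum": 0},
            "is_rest": {"type": "boolean"}
          },
          "additionalProperties": false
        }
      }
    }
  }
}
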