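{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "dastrack JSON interchange payload",
  "description": "Versioned envelope carrying either individual features or summary bins for one segment window at one zoom tier. Coordinates are 1-based inclusive.",
  "type": "object",
  "required": ["format", "version", "segment", "tier", "kind", "payload"],
  "properties": {
    "format": {"const": "dastrack.payload"},
    "version": {"const": "1"},
    "segment": {
      "type": "object",
      "required": ["id", "start", "stop"],
      "properties": {
        "id": {"type": "string"},
        "start": {"type": "integer", "minimum": 1},
        "stop": {"type": "integer", "minimum": 1}
      }
    },
    "tier": {
      "type": "object",
      "required": ["kind", "bases_per_pixel"],
      "properties": {
        "kind": {"enum": ["sequence", "individual", "summary"]},
        "bases_per_pixel": {"type": "number", "exclusiveMinimum": 0},
        "bin_width": {"type": "integer", "minimum": 1}
      }
    },
    "kind": {"enum": ["features", "bins"]},
    "payload": {
      "type": "array",
      "items": {
        "oneOf": [
          {
            "type": "object",
            "description": "one annotated feature (kind = features)",
            "required": ["id", "start", "stop", "type"],
            "properties": {
              "id": {"type": "string"},
              "start": {"type": "integer", "minimum": 1},
              "stop": {"type": "integer", "minimum": 1},
              "type": {"type": "string"},
              "label": {"type": "string"},
              "category": {"type": "string"},
              "method": {"type": "string"},
              "score": {"type": "number"},
              "orientation": {"enum": ["forward", "reverse"]},
              "phase": {"enum": [0, 1, 2]},
              "group": {"type": "string"},
              "link": {"type": "string"},
              "notes": {"type": "array", "items": {"type": "string"}}
            }
          },
          {
            "type": "object",
            "description": "one summary bin (kind = bins)",
            "required": ["start", "stop", "count", "coverage"],
            "properties": {
              "start": {"type": "integer", "minimum": 1},
              "stop": {"type": "integer", "minimum": 1},
              "count": {"type": "integer", "minimum": 0},
              "coverage": {"type": "number", "minimum": 0, "maximum": 1},
              "max_score": {"type": "number"}
            }
          }
        ]
      }
    }
  }
}
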