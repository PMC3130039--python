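{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "dastrack session file",
  "description": "Flat-text snapshot of the application state: every viewer's viewport, tracks and styles, viewer link groups, and the registered DAS sources. Sessions store source URLs, never data.",
  "type": "object",
  "required": ["format", "format_version", "viewers", "registered_sources"],
  "properties": {
    "format": {"const": "dastrack.session"},
    "format_version": {"const": "1"},
    "viewers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["viewport", "tracks", "link_group", "link_role"],
        "properties": {
          "viewport": {
            "type": "object",
            "required": ["segment_id", "start", "stop", "pixel_width"],
            "properties": {
              "segment_id": {"type": "string"},
              "start": {"type": "integer", "minimum": 1},
              "stop": {"type": "integer", "minimum": 1},
              "pixel_width": {"type": "integer", "minimum": 1}
            }
          },
          "tracks": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["source_url", "label", "style"],
              "properties": {
                "source_url": {"type": "string"},
                "label": {"type": "string"},
                "style": {
                  "type": "object",
                  "required": ["glyph", "fg_color", "bg_color", "track_height",
                               "row_height", "min_gap_px", "show_labels"],
                  "properties": {
                    "glyph": {"enum": ["box", "line", "arrow", "tick", "histogram"]},
                    "fg_color": {"type": "string"},
                    "bg_color": {"type": "string"},
                    "track_height": {"type": "integer", "minimum": 1},
                    "row_height": {"type": "integer", "minimum": 1},
                    "min_gap_px": {"type": "integer", "minimum": 0},
                    "show_labels": {"type": "boolean"}
                  }
                }
              }
            }
          },
          "link_group": {"type": ["string", "null"]},
          "link_role": {
            "enum": ["independent", "same_region_other_zoom",
                     "adjacent_next", "adjacent_previous"]
          }
        }
      }
    },
    "registered_sources": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["base_url"],
        "properties": {
          "base_url": {"type": "string"},
          "title": {"type": "string"},
          "capabilities": {"type": "array", "items": {"type": "string"}},
          "coordinate_system": {"type": "string"}
        }
      }
    }
  }
}
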