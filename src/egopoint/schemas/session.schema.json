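{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Pointing session (dialect v1)",
 "description": "One participant-day of egocentric pointing trials. Unknown keys at any level are permitted and preserved by readers (forward tolerance).",
 "type": "object",
 "required": ["format_version", "participant", "trials"],
 "properties": {
  "format_version": {"const": 1},
  "day": {"type": ["integer", "null"], "enum": [1, 2, null]},
  "participant": {
   "type": "object",
   "required": ["id"],
   "properties": {
    "id": {"type": "string"},
    "sex": {"type": "string"},
    "birthdate": {"type": "string"},
    "handedness": {"enum": ["left", "right"]},
    "pointing_hand": {"enum": ["left", "right"]},
    "rotation_side": {"enum": ["left", "right"]}
   }
  },
  "layout": {
   "type": "object",
   "properties": {
    "width_m": {"type": "number", "exclusiveMinimum": 0},
    "depth_m": {"type": "number", "exclusiveMinimum": 0},
    "height_m": {"type": "number", "exclusiveMinimum": 0},
    "observer_xy": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
    "eye_height_m": {"type": "number", "exclusiveMinimum": 0},
    "facing_heading_deg": {"type": "number"}
   }
  },
  "roster": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name"],
    "properties": {
     "name": {"type": "string"},
     "position_xyz_m": {"type": "array", "items": {"type": "number"}, "minItems": 3, "maxItems": 3},
     "true_direction": {
      "type": "object",
      "properties": {
       "azimuth_deg": {"type": "number", "exclusiveMinimum": -180, "maximum": 180},
       "elevation_deg": {"type": "number", "minimum": -90, "maximum": 90},
       "azimuth_defined": {"type": "boolean"}
      }
     },
     "side": {"enum": ["left", "right", "center"]},
     "analyse_azimuth": {"type": "boolean"}
    }
   }
  },
  "trials": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["condition", "target", "vector"],
    "properties": {
     "index": {"type": "integer", "minimum": 0},
     "day": {"type": "integer", "enum": [1, 2]},
     "condition": {"enum": ["EO", "EC", "RR", "MR"]},
     "target": {"type": "string"},
     "repetition": {"type": "integer", "minimum": 1},
     "vector": {
      "description": "East/North/Up unit-vector components, each in [-1, 1]",
      "type": "array",
      "items": {"type": "number", "minimum": -1, "maximum": 1},
      "minItems": 3,
      "maxItems": 3
     }
    }
   }
  }
 }
}
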