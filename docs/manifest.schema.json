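{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "redoxscan study manifest",
  "description": "YAML manifest tying the per-section TIFF files of a redox-scanning study together with calibration constants. Paths are relative to the manifest's directory.",
  "type": "object",
  "required": ["standard_concentrations_um", "sections"],
  "properties": {
    "standard_concentrations_um": {
      "type": "object",
      "required": ["fp", "nadh"],
      "properties": {
        "fp": {"type": "number", "exclusiveMinimum": 0},
        "nadh": {"type": "number", "exclusiveMinimum": 0}
      },
      "description": "Known concentrations (uM) of the FAD/Fp and NADH reference standards embedded beside the specimen."
    },
    "step_size_um": {
      "type": "number",
      "exclusiveMinimum": 0,
      "default": 100.0,
      "description": "Physical scan step between adjacent pixels, micrometres."
    },
    "sections": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["animal_id", "group", "depth_um", "fp_path", "nadh_path", "mask_path"],
        "properties": {
          "animal_id": {"type": "string"},
          "group": {"type": "string", "enum": ["control", "pten_null"]},
          "depth_um": {
            "type": "number",
            "minimum": 0,
            "description": "Milling depth below the first milled surface; the top section carries its own recorded depth, not 0."
          },
          "fp_path": {"type": "string"},
          "nadh_path": {"type": "string"},
          "mask_path": {
            "type": "string",
            "description": "8-bit labelled TIFF: 0 background, 1 tissue, 2 Fp standard, 3 NADH standard."
          }
        }
      },
      "description": "One record per milled section; (animal_id, depth_um) pairs must be unique."
    }
  }
}
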