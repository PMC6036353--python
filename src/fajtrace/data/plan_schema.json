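{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fajtrace treatment plan dialect",
  "type": "object",
  "required": ["beams"],
  "properties": {
    "beams": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["modality", "total_mu", "control_points"],
        "properties": {
          "name": {"type": "string"},
          "modality": {"enum": ["static", "imrt_dynamic", "vmat_arc"]},
          "total_mu": {"type": "number", "exclusiveMinimum": 0},
          "jaw_tracking": {"type": "boolean"},
          "control_points": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["mu_cum_raw", "jaws"],
              "properties": {
                "mu_cum_raw": {
                  "type": "number", "minimum": 0,
                  "description": "raw cumulative meterset; normalized to [0,1] on load"
                },
                "jaws": {
                  "type": "object",
                  "required": ["X1", "X2", "Y1", "Y2"],
                  "description": "jaw edges in cm projected to the isocenter plane; X1<X2, Y1<Y2",
                  "properties": {
                    "X1": {"type": "number"}, "X2": {"type": "number"},
                    "Y1": {"type": "number"}, "Y2": {"type": "number"}
                  }
                },
                "mlc": {
                  "type": ["object", "null"],
                  "required": ["boundaries", "bankA", "bankB"],
                  "description": "leaf positions in cm at isocenter; boundaries has one more entry than each bank; bankA[i] <= bankB[i]",
                  "properties": {
                    "boundaries": {"type": "array", "items": {"type": "number"}},
                    "bankA": {"type": "array", "items": {"type": "number"}},
                    "bankB": {"type": "array", "items": {"type": "number"}}
                  }
                },
                "gantry_deg": {"type": "number"}
              }
            }
          }
        }
      }
    }
  }
}
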