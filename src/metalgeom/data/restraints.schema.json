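{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "metalgeom restraint JSON, schema version 1",
  "description": "Per-metal-site stereochemical information: every matched coordination class ranked by Procrustes distance, with full bond-length mode lists and per-angle summaries. A dictionary update uses exactly the most probable mode of the top class.",
  "type": "object",
  "required": ["schema_version", "sites"],
  "properties": {
    "schema_version": {"const": "1"},
    "sites": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["metal", "element", "accepted", "classes"],
        "properties": {
          "metal": {"type": "string", "minLength": 1},
          "element": {"type": "string", "minLength": 1},
          "accepted": {"type": "boolean"},
          "classes": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["name", "coordination_number", "procrustes_distance", "bonds", "angles"],
              "properties": {
                "name": {"type": "string", "minLength": 1},
                "coordination_number": {"type": "integer", "minimum": 1},
                "procrustes_distance": {"type": "number", "minimum": 0},
                "alpha": {"type": "number"},
                "bonds": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["ligand_element", "modes", "most_probable"],
                    "properties": {
                      "ligand_element": {"type": "string"},
                      "most_probable": {"type": "integer", "minimum": 0},
                      "modes": {
                        "type": "array",
                        "minItems": 1,
                        "items": {
                          "type": "object",
                          "required": ["mean", "sd", "count"],
                          "properties": {
                            "mean": {"type": "number", "exclusiveMinimum": 0},
                            "sd": {"type": "number", "exclusiveMinimum": 0},
                            "count": {"type": "integer", "minimum": 1}
                          }
                        }
                      }
                    }
                  }
                },
                "angles": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["vertex1", "vertex2", "mean", "sd", "count"],
                    "properties": {
                      "vertex1": {"type": "integer", "minimum": 0},
                      "vertex2": {"type": "integer", "minimum": 0},
                      "mean": {"type": "number", "minimum": 0, "maximum": 180},
                      "sd": {"type": "number", "exclusiveMinimum": 0},
                      "count": {"type": "integer", "minimum": 1}
                    }
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
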