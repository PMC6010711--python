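{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "popcompare describe report",
 "type": "object",
 "required": ["popcompare_version", "n_reps", "n_distinct_histories", "populations"],
 "properties": {
  "popcompare_version": {"type": "string"},
  "seed": {"type": ["integer", "null"]},
  "n_reps": {"type": "integer", "minimum": 1},
  "n_distinct_histories": {"type": "integer", "minimum": 1},
  "populations": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": [
     "population_id", "n", "n_per_stage", "stages", "census", "sampling",
     "reproduction_type", "matrix", "parameters", "sensitivity",
     "elasticity", "history_composition", "intervals", "sss_distance"
    ],
    "properties": {
     "population_id": {"type": "string"},
     "n": {"type": "integer", "minimum": 1},
     "n_per_stage": {"type": "array", "items": {"type": "integer", "minimum": 0}},
     "stages": {"type": "array", "items": {"type": "string"}},
     "census": {"enum": ["prebreeding", "postbreeding"]},
     "sampling": {"enum": ["random", "fixed_per_stage"]},
     "reproduction_type": {"enum": ["identified", "anon1", "anon2", "anon3"]},
     "matrix": {
      "type": "object",
      "required": ["F", "U", "A"],
      "properties": {
       "F": {"type": "array"},
       "U": {"type": "array"},
       "A": {"type": "array"}
      }
     },
     "parameters": {
      "type": "object",
      "required": ["lambda", "R0", "T", "sss", "rv"],
      "properties": {
       "lambda": {"type": "number"},
       "R0": {"type": ["number", "null"]},
       "T": {"type": ["number", "null"]},
       "T_undefined_reason": {"type": ["string", "null"]},
       "sss": {"type": "array", "items": {"type": "number"}},
       "rv": {"type": "array", "items": {"type": "number"}}
      }
     },
     "sensitivity": {"type": "array"},
     "elasticity": {"type": "array"},
     "history_composition": {"type": "array", "items": {"type": "number"}},
     "intervals": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["parameter", "element", "observed", "median", "ci", "n_reps", "n_undefined", "unreliable"],
       "properties": {
        "parameter": {"type": "string"},
        "element": {"type": ["string", "null"]},
        "observed": {"type": "number"},
        "median": {"type": "number"},
        "ci": {
         "type": "object",
         "patternProperties": {
          "^[0-9]+%$": {"type": "array", "minItems": 2, "maxItems": 2, "items": {"type": "number"}}
         }
        },
        "n_reps": {"type": "integer"},
        "n_undefined": {"type": "integer"},
        "unreliable": {"type": "boolean"}
       }
      }
     },
     "sss_distance": {
      "type": ["object", "null"],
      "properties": {
       "observed_structure": {"type": "array", "items": {"type": "number"}},
       "keyfitz_delta": {"type": "number"},
       "p_value": {"type": "number", "minimum": 0, "maximum": 1},
       "n_reps": {"type": "integer"}
      }
     }
    }
   }
  }
 }
}
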