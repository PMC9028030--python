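{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ShuntingParams",
  "type": "object",
  "required": ["A", "B", "C"],
  "properties": {
    "A": {"type": "number", "exclusiveMinimum": 0, "description": "passive decay rate (1/time)"},
    "B": {"type": "number", "exclusiveMinimum": 0, "description": "excitatory ceiling (activity)"},
    "C": {"type": "number", "minimum": 0, "description": "inhibitory floor (activity)"},
    "on_center": {"type": ["array", "null"], "description": "nonnegative on-center weight matrix"},
    "off_surround": {"type": ["array", "null"], "description": "nonnegative off-surround weight matrix"},
    "f": {"$ref": "#/$defs/signal"},
    "g": {"$ref": "#/$defs/signal"},
    "epsilon": {"type": "number", "exclusiveMinimum": 0, "description": "slow-interneuron rate (1/time)"},
    "slow_inhibition": {"type": "boolean"},
    "dt": {"type": ["number", "null"], "exclusiveMinimum": 0}
  },
  "$defs": {
    "signal": {
      "type": "object",
      "properties": {
        "family": {"enum": ["linear", "faster_than_linear", "sigmoid"]},
        "threshold": {"type": "number", "minimum": 0},
        "gain": {"type": "number", "exclusiveMinimum": 0},
        "power": {"type": "number", "minimum": 1},
        "half_point": {"type": "number", "exclusiveMinimum": 0}
      }
    }
  }
}
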