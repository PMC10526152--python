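{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "kinfuse two-subsystem kinetic system",
  "description": "Serialized discrete kinetic system: state-space labels, probability distributions, intra/cross transition tensors (index order [r][s][j]: candidate s falls to r after meeting field j), encounter rates and step size. Dimensions must be mutually consistent; the package validates them on load.",
  "type": "object",
  "required": ["labels", "distributions", "intra_tensors", "cross_tensors", "tau", "eta"],
  "properties": {
    "labels": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "items": {"type": "string"}, "minItems": 1}
    },
    "distributions": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "items": {"type": "number", "minimum": 0, "maximum": 1}}
    },
    "time_index": {"type": "integer", "minimum": 0},
    "intra_tensors": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "items": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}}}
    },
    "cross_tensors": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "items": {"type": "array", "items": {"type": "array", "items": {"type": "number"}}}}
    },
    "tau": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "items": {"type": "array", "items": {"type": "number", "minimum": 0}}}
    },
    "eta": {
      "type": "array", "minItems": 2, "maxItems": 2,
      "items": {"type": "array", "items": {"type": "array", "items": {"type": "number", "minimum": 0}}}
    },
    "dt": {"type": "number", "minimum": 0}
  }
}
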