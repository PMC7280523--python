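{
  "schema_version": "1.0",
  "required": {
    "schema_version": "string",
    "seed": "number",
    "marker_stats": "array",
    "combos": "array",
    "best": "object"
  }
}
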