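{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "epimast pipeline report",
  "type": "object",
  "required": ["seed", "thresholds", "methylation", "chip", "expression",
               "integration"],
  "properties": {
    "seed": {"type": "integer"},
    "thresholds": {"type": "object"},
    "simulate": {"type": "object"},
    "methylation": {"type": "object"},
    "chip": {"type": "object"},
    "expression": {"type": "object"},
    "integration": {"type": "object"}
  }
}
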