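{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Flowchart graph",
  "type": "object",
  "required": ["periods", "nodes", "edges"],
  "properties": {
    "periods": {"type": "array"},
    "nodes": {"type": "array"},
    "edges": {"type": "array"}
  },
  "definitions": {
    "node": {
      "type": "object",
      "required": ["code", "period", "height", "base", "category", "color"],
      "properties": {
        "code": {"type": "string"},
        "period": {"type": "string"},
        "height": {"type": "number"},
        "base": {"type": "number"},
        "category": {"type": "string"},
        "color": {"type": "string"}
      }
    },
    "edge": {
      "type": "object",
      "required": ["pre_code", "post_code", "period", "width", "color"],
      "properties": {
        "pre_code": {"type": "string"},
        "post_code": {"type": "string"},
        "period": {"type": "string"},
        "width": {"type": "number"},
        "color": {"type": "string"}
      }
    }
  }
}
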