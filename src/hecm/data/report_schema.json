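{
  "title": "HECMReport",
  "type": "object",
  "required": [
    "similarity",
    "vip",
    "miv",
    "cluster",
    "selected_markers",
    "equivalence",
    "provenance"
  ],
  "properties": {
    "similarity": {
      "type": "object",
      "required": ["summary", "per_sample"],
      "properties": {
        "summary": {"type": "object"},
        "per_sample": {"type": "object"}
      }
    },
    "vip": {
      "type": "object",
      "required": ["values", "threshold", "selected", "r_squared"],
      "properties": {
        "values": {"type": "object"},
        "threshold": {"type": "number"},
        "selected": {"type": "array"},
        "r_squared": {"type": "number"},
        "adjusted_r_squared": {"type": ["number", "null"]},
        "n_components": {"type": "integer"}
      }
    },
    "miv": {
      "type": "object",
      "required": ["values", "ranking_signed", "ranking_abs"],
      "properties": {
        "values": {"type": "object"},
        "iv": {"type": "object"},
        "ranking_signed": {"type": "array"},
        "ranking_abs": {"type": "array"},
        "final_mse": {"type": "number"}
      }
    },
    "cluster": {
      "type": "object",
      "required": ["col_order", "row_order"],
      "properties": {
        "col_order": {"type": "array"},
        "row_order": {"type": "array"},
        "markers_near_endpoints": {"type": "array"}
      }
    },
    "selected_markers": {"type": "array"},
    "equivalence": {"type": ["object", "null"]},
    "provenance": {
      "type": "object",
      "required": ["config_hash", "seed", "version"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "version": {"type": "string"}
      }
    }
  }
}
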