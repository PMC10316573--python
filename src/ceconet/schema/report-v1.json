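{
  "type": "object",
  "required": ["schema_version", "package_version", "config", "seeds", "input", "groups", "global"],
  "properties": {
    "schema_version": {"type": "string"},
    "package_version": {"type": "string"},
    "config": {"type": "object"},
    "seeds": {"type": "object"},
    "input": {
      "type": "object",
      "required": ["n_samples", "n_taxa"],
      "properties": {
        "n_samples": {"type": "integer"},
        "n_taxa": {"type": "integer"}
      }
    },
    "groups": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["n_nodes", "n_edges"],
        "properties": {
          "n_nodes": {"type": "integer"},
          "n_edges": {"type": "integer"},
          "acc": {"type": "number"},
          "apl": {"type": "number", "nullable": true},
          "diameter": {"type": "integer", "nullable": true},
          "modularity": {"type": "number"},
          "n_modules": {"type": "integer"},
          "positive_edge_fraction": {"type": "number", "nullable": true},
          "null_stats": {"type": "object", "nullable": true},
          "role_counts": {"type": "object", "nullable": true}
        }
      }
    },
    "global": {"type": "object"}
  }
}
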