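{
  "type": "object",
  "required": ["seed", "thresholds", "stages"],
  "properties": {
    "seed": {"type": ["integer", "null"]},
    "versions": {"type": "object"},
    "thresholds": {"type": "object"},
    "stages": {
      "type": "object",
      "properties": {
        "seedling": {
          "type": "object",
          "properties": {
            "n_isolates": {"type": "integer"},
            "class_counts": {"type": "object"},
            "n_pathogenic": {"type": "integer"}
          }
        },
        "mature": {
          "type": "object",
          "properties": {
            "n_isolates": {"type": "integer"},
            "class_counts": {"type": "object"},
            "n_lesion_inducers": {"type": "integer"}
          }
        },
        "lineage_comparison": {"type": "object"},
        "literature": {"type": "object"},
        "trophic": {"type": "object"}
      }
    }
  }
}
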