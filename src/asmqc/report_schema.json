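{
  "type": "object",
  "required": ["sections", "omitted_sections", "tool_version", "config", "manifest"],
  "properties": {
    "sections": {
      "type": "object",
      "required": ["effects", "statistics", "correlations"],
      "properties": {
        "effects": {
          "type": "object",
          "required": [
            "mismatches_in_cds", "mismatches_outside_cds",
            "indels_in_cds", "indels_outside_cds",
            "non_synonymous_mutations", "synonymous_mutations",
            "inframe_indels", "affected_mrnas", "altered_proteins",
            "size_classes"
          ]
        },
        "statistics": {
          "type": "object",
          "required": ["L_cds", "L_nc"]
        },
        "misassemblies": {
          "type": "object",
          "required": ["translocation", "relocation", "inversion", "local", "consistent"]
        },
        "correlations": {
          "type": "object",
          "required": ["file", "pairs", "window", "step", "block"]
        }
      }
    },
    "omitted_sections": {"type": "array"},
    "tool_version": {"type": "string"},
    "config": {"type": "object"},
    "manifest": {"type": "object"}
  }
}
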