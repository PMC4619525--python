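{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "samplesim-summary-v1",
  "title": "samplesim compare summary",
  "type": "object",
  "required": ["schema", "summary", "head_to_head"],
  "properties": {
    "schema": {"const": "samplesim-summary-v1"},
    "summary": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "object",
          "required": ["failed_replicates"],
          "properties": {
            "failed_replicates": {"type": "integer", "minimum": 0}
          },
          "additionalProperties": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["median", "mean", "centile_2.5", "centile_97.5"],
              "properties": {
                "median": {"type": "number", "minimum": 0},
                "mean": {"type": "number", "minimum": 0},
                "centile_2.5": {"type": "number", "minimum": 0},
                "centile_97.5": {"type": "number", "minimum": 0},
                "batch_sd_median": {"type": "number", "minimum": 0}
              }
            }
          }
        }
      }
    },
    "head_to_head": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "additionalProperties": {
                "type": "number",
                "minimum": 0,
                "maximum": 100
              }
            }
          }
        }
      }
    }
  }
}
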