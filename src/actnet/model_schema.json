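{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "actnet model file",
  "description": "Activity-network model: nodes with bounded integer activity levels and signed interactions with a kinetic scenario and strength k. This schema documents the format; the loader performs equivalent validation plus referential-integrity checks.",
  "type": "object",
  "required": ["nodes", "edges"],
  "properties": {
    "format": { "const": "actnet-model" },
    "version": { "type": "integer" },
    "metadata": { "type": "object" },
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": { "type": "string", "minLength": 1 },
          "levels": { "type": "integer", "minimum": 1, "default": 100 },
          "initial": { "type": "integer", "minimum": 0, "default": 0 },
          "clamp": { "type": ["integer", "null"], "minimum": 0, "default": null },
          "reaction_class": { "enum": ["slow", "fast"], "default": "fast" }
        },
        "additionalProperties": false
      }
    },
    "edges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["regulators", "target", "k"],
        "properties": {
          "regulators": {
            "type": "array",
            "items": { "type": "string" },
            "minItems": 1,
            "maxItems": 2,
            "description": "One regulator for scenarios 1-2, exactly two for scenario 3."
          },
          "target": { "type": "string" },
          "sign": { "enum": ["activation", "inhibition"], "default": "activation" },
          "scenario": { "enum": [1, 2, 3], "default": 1 },
          "k": { "type": "number", "exclusiveMinimum": 0 },
          "reaction_class": { "enum": ["slow", "fast"], "default": "fast" }
        },
        "additionalProperties": false
      }
    }
  }
}
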