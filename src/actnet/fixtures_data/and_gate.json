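{
  "format": "actnet-model",
  "version": 1,
  "metadata": {
    "name": "and_gate"
  },
  "nodes": [
    {
      "name": "A",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "B",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "C",
      "levels": 100,
      "initial": 0
    }
  ],
  "edges": [
    {
      "regulators": [
        "A",
        "B"
      ],
      "target": "C",
      "sign": "activation",
      "scenario": 3,
      "k": 1.0
    },
    {
      "regulators": [
        "C"
      ],
      "target": "C",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    }
  ]
}
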