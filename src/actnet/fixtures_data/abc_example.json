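{
  "format": "actnet-model",
  "version": 1,
  "metadata": {
    "name": "abc_example"
  },
  "nodes": [
    {
      "name": "A",
      "levels": 100,
      "initial": 100
    },
    {
      "name": "B",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "C",
      "levels": 100,
      "initial": 100
    }
  ],
  "edges": [
    {
      "regulators": [
        "A"
      ],
      "target": "B",
      "sign": "activation",
      "scenario": 1,
      "k": 0.5
    },
    {
      "regulators": [
        "C"
      ],
      "target": "B",
      "sign": "inhibition",
      "scenario": 1,
      "k": 0.4
    }
  ]
}
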