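{
  "format": "actnet-model",
  "version": 1,
  "metadata": {
    "name": "ras_motif"
  },
  "nodes": [
    {
      "name": "Wnt",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "BMP",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "FGFR1",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "FGFR3",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "Ras",
      "levels": 100,
      "initial": 0
    }
  ],
  "edges": [
    {
      "regulators": [
        "Wnt"
      ],
      "target": "Ras",
      "sign": "activation",
      "scenario": 1,
      "k": 0.444
    },
    {
      "regulators": [
        "BMP"
      ],
      "target": "Ras",
      "sign": "activation",
      "scenario": 1,
      "k": 0.444
    },
    {
      "regulators": [
        "FGFR1"
      ],
      "target": "Ras",
      "sign": "activation",
      "scenario": 1,
      "k": 0.444
    },
    {
      "regulators": [
        "FGFR3"
      ],
      "target": "Ras",
      "sign": "activation",
      "scenario": 1,
      "k": 0.444
    },
    {
      "regulators": [
        "Ras"
      ],
      "target": "Ras",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    }
  ]
}
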