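{
  "format": "actnet-model",
  "version": 1,
  "metadata": {
    "name": "destruction_complex"
  },
  "nodes": [
    {
      "name": "Dsh",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "ERK",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "DC_on",
      "levels": 100,
      "initial": 100,
      "clamp": 100
    },
    {
      "name": "DC_free",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "DC_cap",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "DC",
      "levels": 100,
      "initial": 0
    }
  ],
  "edges": [
    {
      "regulators": [
        "DC_on"
      ],
      "target": "DC_free",
      "sign": "activation",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "Dsh"
      ],
      "target": "DC_free",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "DC_free"
      ],
      "target": "DC_free",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "DC_on"
      ],
      "target": "DC_cap",
      "sign": "activation",
      "scenario": 1,
      "k": 1.5
    },
    {
      "regulators": [
        "ERK"
      ],
      "target": "DC_cap",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "DC_cap"
      ],
      "target": "DC_cap",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "DC_free",
        "DC_cap"
      ],
      "target": "DC",
      "sign": "activation",
      "scenario": 3,
      "k": 1.0
    },
    {
      "regulators": [
        "DC"
      ],
      "target": "DC",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    }
  ]
}
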