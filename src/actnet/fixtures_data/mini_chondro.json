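{
  "format": "actnet-model",
  "version": 1,
  "metadata": {
    "name": "mini_chondro"
  },
  "nodes": [
    {
      "name": "X",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "Y",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "XA",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "YA",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "XI",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "YI",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "XU",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "YU",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "M1",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "M2",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "XW",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "YW",
      "levels": 100,
      "initial": 0
    }
  ],
  "edges": [
    {
      "regulators": [
        "XA",
        "X"
      ],
      "target": "X",
      "sign": "activation",
      "scenario": 3,
      "k": 1.8
    },
    {
      "regulators": [
        "XA"
      ],
      "target": "X",
      "sign": "activation",
      "scenario": 1,
      "k": 0.3
    },
    {
      "regulators": [
        "Y"
      ],
      "target": "X",
      "sign": "inhibition",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "X"
      ],
      "target": "X",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "YA",
        "Y"
      ],
      "target": "Y",
      "sign": "activation",
      "scenario": 3,
      "k": 1.8
    },
    {
      "regulators": [
        "YA"
      ],
      "target": "Y",
      "sign": "activation",
      "scenario": 1,
      "k": 0.3
    },
    {
      "regulators": [
        "X"
      ],
      "target": "Y",
      "sign": "inhibition",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "Y"
      ],
      "target": "Y",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "X"
      ],
      "target": "XA",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "XI"
      ],
      "target": "XA",
      "sign": "activation",
      "scenario": 1,
      "k": 0.5
    },
    {
      "regulators": [
        "M2"
      ],
      "target": "XA",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "XA"
      ],
      "target": "XA",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "Y"
      ],
      "target": "YA",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "YI"
      ],
      "target": "YA",
      "sign": "activation",
      "scenario": 1,
      "k": 0.5
    },
    {
      "regulators": [
        "M1"
      ],
      "target": "YA",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "YA"
      ],
      "target": "YA",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "XU"
      ],
      "target": "XI",
      "sign": "activation",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "XI"
      ],
      "target": "XI",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "YU"
      ],
      "target": "YI",
      "sign": "activation",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "YI"
      ],
      "target": "YI",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "XU"
      ],
      "target": "XU",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "YU"
      ],
      "target": "YU",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "X"
      ],
      "target": "M1",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "M1"
      ],
      "target": "M1",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "Y"
      ],
      "target": "M2",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "M2"
      ],
      "target": "M2",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "X"
      ],
      "target": "XW",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "XW"
      ],
      "target": "XW",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "Y"
      ],
      "target": "YW",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "YW"
      ],
      "target": "YW",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    }
  ]
}
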