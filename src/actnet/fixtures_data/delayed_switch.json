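{
  "format": "actnet-model",
  "version": 1,
  "metadata": {
    "name": "delayed_switch",
    "target_predicate": "T >= 60"
  },
  "nodes": [
    {
      "name": "SRC",
      "levels": 100,
      "initial": 100,
      "clamp": 100
    },
    {
      "name": "W",
      "levels": 100,
      "initial": 0,
      "reaction_class": "slow"
    },
    {
      "name": "TRIG",
      "levels": 100,
      "initial": 0
    },
    {
      "name": "T",
      "levels": 100,
      "initial": 0
    }
  ],
  "edges": [
    {
      "regulators": [
        "SRC"
      ],
      "target": "W",
      "sign": "activation",
      "scenario": 1,
      "k": 0.1,
      "reaction_class": "slow"
    },
    {
      "regulators": [
        "TRIG"
      ],
      "target": "W",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "W"
      ],
      "target": "W",
      "sign": "inhibition",
      "scenario": 1,
      "k": 0.1,
      "reaction_class": "slow"
    },
    {
      "regulators": [
        "TRIG"
      ],
      "target": "TRIG",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    },
    {
      "regulators": [
        "TRIG",
        "W"
      ],
      "target": "T",
      "sign": "activation",
      "scenario": 3,
      "k": 2.0
    },
    {
      "regulators": [
        "T"
      ],
      "target": "T",
      "sign": "activation",
      "scenario": 1,
      "k": 2.0
    },
    {
      "regulators": [
        "T"
      ],
      "target": "T",
      "sign": "inhibition",
      "scenario": 1,
      "k": 1.0
    }
  ]
}
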