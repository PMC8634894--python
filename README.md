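# actnet

Executable activity-network models of signaling networks: a deterministic
discrete-level simulator with three abstract kinetic scenarios, a
Boolean-rule-to-network translator, Monte Carlo cell-fate screens,
single/pairwise perturbation screens, and a bounded reachability checker
for fate-switch properties.

Nodes carry an integer activity level on a 0–100 scale; edges are signed
interactions with a single strength parameter `k` and one of three rate
laws (upstream-only, upstream × target availability, or two-regulator
AND). Simulation advances one node by ±1 at a time, at timeouts inversely
proportional to the node's net rate, so the discrete run tracks the
underlying rate equations while remaining exactly reproducible: the same
model and initial state always give bit-identical trajectories.

## Library tour

- `actnet.model` — `NodeSpec`, `EdgeSpec`, `NetworkModel`; JSON model
  file I/O (`load_model` / `save_model`, schema in `model_schema.json`),
  SIF/GraphML export, and editing operations: `apply_clamps` (constant
  dummies, knockouts, constitutive activation), `scale_downstream`
  (multiply all outgoing `k` by a factor), `contract_nodes` (remove
  pass-through nodes).
- `actnet.simulate` — `simulate` (event trajectory), `find_attractor`
  (fixed point / limit cycle / Null / unresolved, with per-node reported
  levels), `classify_fate` with a `FateClassifier`.
- `actnet.boolean` — `parse_boolean_rules` for plain-text rule files
  (`C = A | B`, annotations `@slow`, `@dual`, `@w(src)=0.444`) and
  `translate`: OR branches become independent edges, binary ANDs become
  scenario-3 edges, every non-constant node gets exactly one
  self-inhibition (k = 0.1 slow / 1.0 fast), and `@dual` nodes expand
  into the expression/PTM three-node pattern.
- `actnet.screens` — `monte_carlo_fates` (seeded fate distributions with
  99% Wald confidence half-widths), `single_perturbation_screen`
  (knockout/overactivation of every node), `pairwise_switch_screen`
  (all pair clamp combinations from a verified attractor state).
- `actnet.reachability` — `check_persist` (A[]) and `check_reach`
  (E<>/A<>) with optional delayed interventions enumerated over event
  indices; three-valued verdicts with witness/counterexample traces.
- `actnet.fixtures` — bundled motifs (`ras_motif`, `abc_example`,
  `and_gate`, `destruction_complex`, `delayed_switch`, `mini_chondro`),
  a seeded random-network generator, and `ode_oracle`, an independent
  continuous-rate-equation integrator used to cross-check the simulator.

## CLI

```sh
actnet attractor --fixture ras_motif --clamp Wnt=100
actnet fates --fixture mini_chondro --n 10000 --seed 7 --classifier X:Y --out fates.csv
actnet screen-single --fixture mini_chondro --n 1000 --seed 1 --classifier X:Y
actnet screen-pairs --fixture mini_chondro --init X=100 --init XA=100 \
    --init M1=100 --init XW=100 --classifier X:Y
actnet check --fixture delayed_switch --property "E<> T >= 60" \
    --intervene "TRIG=100@choice" --horizon 200
actnet translate rules.txt --out model.json
actnet generate --nodes 8 --density 0.3 --seed 5 --out random.json
actnet scale --model model.json --node p38 --factor 0.64 --out scaled.json
```

Options can also come from a YAML config file (`actnet --config cfg.yaml
fates`); explicit flags win. Seeds and configuration are logged to
stderr so every stochastic run is reproducible.

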