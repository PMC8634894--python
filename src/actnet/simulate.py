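"""Deterministic simulation of activity networks to their attractors.

The update semantics is the discrete approximation of the rate
equations: each node's activity moves by one level at a time, at a
timeout inversely proportional to the magnitude of its current net
rate.  With fixed inputs the whole run is a pure function of the model
and the initial state — two runs with identical inputs are bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import engine
from .model import EdgeSpec, FateClassifier, NetworkModel

__all__ = [
    "SimState",
    "Trajectory",
    "Attractor",
    "edge_rate",
    "net_rate",
    "step",
    "simulate",
    "find_attractor",
    "classify_fate",
]


@dataclass
class SimState:
    """Activities of all nodes at one instant of a simulation."""

    activities: np.ndarray  # int64 per node
    node_names: tuple[str, ...]
    levels: np.ndarray  # int64 per node
    clamped: np.ndarray  # bool per node
    time: float = 0.0
    event_count: int = 0

    @classmethod
    def from_model(
        cls, model: NetworkModel, overrides: Mapping[str, int] | None = None
    ) -> "SimState":
        cm = engine.CompiledModel(model)
        return cls(
            activities=cm.make_init(overrides),
            node_names=cm.node_names,
            levels=cm.levels.copy(),
            clamped=cm.clamped.copy(),
        )

    def __getitem__(self, name: str) -> int:
        return int(self.activities[self.node_names.index(name)])

    def as_dict(self) -> dict[str, int]:
        return {n: int(a) for n, a in zip(self.node_names, self.activities)}

    def copy(self) -> "SimState":
        return SimState(
            self.activities.copy(),
            self.node_names,
            self.levels,
            self.clamped,
            self.time,
            self.event_count,
        )


def _normalized(state: SimState, name: str) -> float:
    i = state.node_names.index(name)
    return float(state.activities[i]) / float(state.levels[i])


def edge_rate(edge: EdgeSpec, state: SimState) -> float:
    """Instantaneous occurrence rate of one interaction (always >= 0).

    Scenario 1: ``k * [E]``; scenario 3: ``k * [E1] * [E2]``; scenario 2
    multiplies ``k * [E]`` by the target's availability — the inactive
    fraction for activations, the active fraction for inhibitions —
    so an activation has no effect on an already-saturated target.
    Activities are normalized to [0, 1].
    """
    e_hat = _normalized(state, edge.regulators[0])
    if edge.scenario == 1:
        return edge.k * e_hat
    if edge.scenario == 3:
        return edge.k * e_hat * _normalized(state, edge.regulators[1])
    s_hat = _normalized(state, edge.target)
    avail = (1.0 - s_hat) if edge.sign == "activation" else s_hat
    return edge.k * e_hat * avail


def net_rate(model: NetworkModel, node: str, state: SimState) -> float:
    """Signed sum of incoming activation minus inhibition rates."""
    total = 0.0
    for e in model.in_edges(node):
        r = edge_rate(e, state)
        total += r if e.sign == "activation" else -r
    return total


def step(model: NetworkModel, state: SimState) -> SimState:
    """Advance the earliest-timeout movable node by one level.

    This is a memoryless single-event advance (all per-node clocks taken
    at ``state.time``); :func:`simulate` is the authoritative multi-event
    engine, which keeps per-node clocks across events.  Raises
    ``RuntimeError`` on a quiescent state.
    """
    best = None
    for i, name in enumerate(state.node_names):
        if state.clamped[i]:
            continue
        rho = net_rate(model, name, state)
        a = int(state.activities[i])
        movable = (rho > engine._RATE_EPS and a < state.levels[i]) or (
            rho < -engine._RATE_EPS and a > 0
        )
        if not movable:
            continue
        timeout = state.time + (1.0 / state.levels[i]) / abs(rho)
        if best is None or timeout < best[0]:
            best = (timeout, i, 1 if rho > 0 else -1)
    if best is None:
        raise RuntimeError("step() called on a quiescent state")
    timeout, i, direction = best
    out = state.copy()
    out.activities[i] += direction
    out.time = timeout
    out.event_count += 1
    return out


@dataclass
class Trajectory:
    """Event log of one deterministic run."""

    initial: SimState
    events: list[tuple[float, str, int]] = field(default_factory=list)
    truncated: bool = False
    final: SimState | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns time, node, level."""
        rows = [
            {"time": 0.0, "node": n, "level": int(a)}
            for n, a in zip(self.initial.node_names, self.initial.activities)
        ]
        rows.extend(
            {"time": t, "node": n, "level": lv} for t, n, lv in self.events
        )
        return pd.DataFrame(rows, columns=["time", "node", "level"])

    def iter_states(self):
        """Yield (time, activities array) for the initial state and after
        every event; the arrays are reused views — copy if kept."""
        a = self.initial.activities.copy()
        names = self.initial.node_names
        yield 0.0, a
        idx = {n: i for i, n in enumerate(names)}
        for t, node, level in self.events:
            a[idx[node]] = level
            yield t, a


@dataclass
class Attractor:
    """Terminal behavior of a run.

    ``reported_levels`` holds one integer per node: the fixed-point
    value, or for limit cycles the time-weighted mean over one period
    rounded to the nearest integer (ties rounded down).
    """

    kind: str  # fixed_point | limit_cycle | null | unresolved
    reported_levels: dict[str, int]
    period: int
    events_to_reach: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "period": self.period,
                "events_to_reach": self.events_to_reach,
                "reported_levels": self.reported_levels,
            },
            indent=2,
        )


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def simulate(
    model: NetworkModel,
    init: SimState | Mapping[str, int] | None = None,
    max_events: int | None = None,
) -> Trajectory:
    """Run the model until quiescence, recurrence, or ``max_events``.

    ``init`` may be a :class:`SimState`, a partial name->level mapping
    overriding the model's initial values, or None for the model's own
    initial state.
    """
    cm = engine.CompiledModel(model)
    a0, initial = _resolve_init(cm, init)
    res = cm.run(a0, max_events=max_events, record=True)
    events = [
        (float(t), cm.node_names[int(i)], int(lv))
        for t, i, lv in zip(res.ev_time, res.ev_node, res.ev_level)
    ]
    final = SimState(
        res.final_state.copy(),
        cm.node_names,
        cm.levels,
        cm.clamped,
        time=res.final_time,
        event_count=res.n_events,
    )
    return Trajectory(
        initial=initial,
        events=events,
        truncated=(res.status == engine.STATUS_TRUNCATED),
        final=final,
    )


def _resolve_init(cm: engine.CompiledModel, init):
    if init is None:
        a0 = cm.make_init()
    elif isinstance(init, SimState):
        a0 = np.array(init.activities, dtype=np.int64, copy=True)
    else:
        a0 = cm.make_init(init)
    initial = SimState(a0.copy(), cm.node_names, cm.levels, cm.clamped)
    return a0, initial


def attractor_from_run(cm: engine.CompiledModel, res: engine.RunResult) -> Attractor:
    if res.status == engine.STATUS_FIXED_POINT:
        levels = {n: int(v) for n, v in zip(cm.node_names, res.final_state)}
        kind = "null" if all(v == 0 for v in levels.values()) else "fixed_point"
        return Attractor(kind, levels, 1, res.n_events)
    if res.status == engine.STATUS_CYCLE:
        levels = {
            n: _round_half_down(float(v))
            for n, v in zip(cm.node_names, res.mean_levels)
        }
        return Attractor("limit_cycle", levels, res.period, res.cycle_start)
    levels = {n: int(v) for n, v in zip(cm.node_names, res.final_state)}
    return Attractor("unresolved", levels, 0, res.n_events)


def find_attractor(
    model: NetworkModel,
    init: SimState | Mapping[str, int] | None = None,
    max_events: int | None = None,
) -> Attractor:
    """Simulate to the attractor and report per-node integer levels."""
    cm = engine.CompiledModel(model)
    a0, _ = _resolve_init(cm, init)
    res = cm.run(a0, max_events=max_events, record=False)
    return attractor_from_run(cm, res)


def classify_fate(attractor: Attractor, classifier: FateClassifier) -> str:
    """Label an attractor; unresolved runs get the label "unresolved"."""
    if attractor.kind == "unresolved":
        return "unresolved"
    return classifier.classify(attractor.reported_levels)
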