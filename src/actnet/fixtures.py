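"""Bundled motif models, a random-network generator, and an
independent rate-equation oracle.

The motifs make every other module testable without external data:

* ``abc_example`` — one activator and one inhibitor competing on B.
* ``ras_motif`` — four independent activators (k=0.444) against a unit
  self-inhibition; one activator at full drives the target to level 44.
* ``and_gate`` — a single scenario-3 (AND) interaction.
* ``destruction_complex`` — dummy-node subnetwork whose output settles
  at ``(1 - Dsh) * min(1.5 - ERK, 1)`` (inputs normalized to [0, 1]).
* ``delayed_switch`` — the target can only be switched on by a clamp
  applied after some delay, never by an immediate one.
* ``mini_chondro`` — a 12-node mutual-inhibition network with three
  attractors (X+, Y+, Null), X+ and Y+ mutually exclusive.

``ode_oracle`` integrates the continuous rate equations the discrete
simulator approximates; it shares no code with the event-driven path
and serves as its independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from . import engine
from .engine import njit
from .model import EdgeSpec, FateClassifier, NetworkModel, NodeSpec

__all__ = [
    "MOTIF_NAMES",
    "motif",
    "motif_classifier",
    "fixture_path",
    "GeneratorParams",
    "random_network",
    "OracleResult",
    "ode_oracle",
]

MOTIF_NAMES = (
    "abc_example",
    "ras_motif",
    "and_gate",
    "destruction_complex",
    "delayed_switch",
    "mini_chondro",
)

_DATA_DIR = Path(__file__).parent / "fixtures_data"


def _act(src, tgt, k, scenario=1, cls="fast"):
    regs = (src,) if isinstance(src, str) else tuple(src)
    return EdgeSpec(regs, tgt, "activation", scenario, k, cls)


def _inh(src, tgt, k, scenario=1, cls="fast"):
    return EdgeSpec((src,), tgt, "inhibition", scenario, k, cls)


def _build_abc_example() -> NetworkModel:
    return NetworkModel(
        nodes=[
            NodeSpec("A", initial=100),
            NodeSpec("B", initial=0),
            NodeSpec("C", initial=100),
        ],
        edges=[_act("A", "B", 0.5), _inh("C", "B", 0.4)],
        metadata={"name": "abc_example"},
    )


def _build_ras_motif() -> NetworkModel:
    sources = ("Wnt", "BMP", "FGFR1", "FGFR3")
    return NetworkModel(
        nodes=[NodeSpec(s) for s in sources] + [NodeSpec("Ras")],
        edges=[_act(s, "Ras", 0.444) for s in sources]
        + [_inh("Ras", "Ras", 1.0)],
        metadata={"name": "ras_motif"},
    )


def _build_and_gate() -> NetworkModel:
    return NetworkModel(
        nodes=[NodeSpec("A"), NodeSpec("B"), NodeSpec("C")],
        edges=[_act(("A", "B"), "C", 1.0, scenario=3), _inh("C", "C", 1.0)],
        metadata={"name": "and_gate"},
    )


def _build_destruction_complex() -> NetworkModel:
    # DC_free tracks (1 - Dsh); DC_cap saturates at min(1.5 - ERK, 1);
    # the AND edge multiplies them into the output.  DC_on is the
    # constant dummy encoding the complex's constitutive activity.
    return NetworkModel(
        nodes=[
            NodeSpec("Dsh"),
            NodeSpec("ERK"),
            NodeSpec("DC_on", clamp=100, initial=100),
            NodeSpec("DC_free"),
            NodeSpec("DC_cap"),
            NodeSpec("DC"),
        ],
        edges=[
            _act("DC_on", "DC_free", 1.0),
            _inh("Dsh", "DC_free", 1.0),
            _inh("DC_free", "DC_free", 1.0),
            _act("DC_on", "DC_cap", 1.5),
            _inh("ERK", "DC_cap", 1.0),
            _inh("DC_cap", "DC_cap", 1.0),
            _act(("DC_free", "DC_cap"), "DC", 1.0, scenario=3),
            _inh("DC", "DC", 1.0),
        ],
        metadata={"name": "destruction_complex"},
    )


def _build_delayed_switch() -> NetworkModel:
    # W rises slowly from the constant source; clamping TRIG at full
    # *before* W has left zero pins W (and hence T) at zero forever,
    # while any later clamp fires the AND gate and T self-sustains.
    return NetworkModel(
        nodes=[
            NodeSpec("SRC", clamp=100, initial=100),
            NodeSpec("W", reaction_class="slow"),
            NodeSpec("TRIG"),
            NodeSpec("T"),
        ],
        edges=[
            _act("SRC", "W", 0.1, cls="slow"),
            _inh("TRIG", "W", 1.0),
            _inh("W", "W", 0.1, cls="slow"),
            _inh("TRIG", "TRIG", 1.0),
            _act(("TRIG", "W"), "T", 2.0, scenario=3),
            _act("T", "T", 2.0),
            _inh("T", "T", 1.0),
        ],
        metadata={"name": "delayed_switch", "target_predicate": "T >= 60"},
    )


def _build_mini_chondro() -> NetworkModel:
    # Two master regulators X and Y in mutual inhibition.  Each locks
    # itself in through its activator (XA/YA) via an AND loop plus a
    # weak direct ignition edge, is fed by a decaying trigger branch
    # (XU -> XI -> XA), represses the rival branch through M1/M2, and
    # drives a readout node (XW/YW).  Attractors: X+, Y+, all-zero Null;
    # X+ and Y+ are mutually exclusive, and clamping XA at 0 makes X+
    # unreachable.
    nodes = [
        NodeSpec(n)
        for n in (
            "X", "Y", "XA", "YA", "XI", "YI",
            "XU", "YU", "M1", "M2", "XW", "YW",
        )
    ]
    edges = [
        _act(("XA", "X"), "X", 1.8, scenario=3), _act("XA", "X", 0.3),
        _inh("Y", "X", 2.0), _inh("X", "X", 1.0),
        _act(("YA", "Y"), "Y", 1.8, scenario=3), _act("YA", "Y", 0.3),
        _inh("X", "Y", 2.0), _inh("Y", "Y", 1.0),
        _act("X", "XA", 2.0), _act("XI", "XA", 0.5),
        _inh("M2", "XA", 1.0), _inh("XA", "XA", 1.0),
        _act("Y", "YA", 2.0), _act("YI", "YA", 0.5),
        _inh("M1", "YA", 1.0), _inh("YA", "YA", 1.0),
        _act("XU", "XI", 1.0), _inh("XI", "XI", 1.0),
        _act("YU", "YI", 1.0), _inh("YI", "YI", 1.0),
        _inh("XU", "XU", 1.0),
        _inh("YU", "YU", 1.0),
        _act("X", "M1", 2.0), _inh("M1", "M1", 1.0),
        _act("Y", "M2", 2.0), _inh("M2", "M2", 1.0),
        _act("X", "XW", 2.0), _inh("XW", "XW", 1.0),
        _act("Y", "YW", 2.0), _inh("YW", "YW", 1.0),
    ]
    return NetworkModel(
        nodes=nodes, edges=edges, metadata={"name": "mini_chondro"}
    )


_BUILDERS = {
    "abc_example": _build_abc_example,
    "ras_motif": _build_ras_motif,
    "and_gate": _build_and_gate,
    "destruction_complex": _build_destruction_complex,
    "delayed_switch": _build_delayed_switch,
    "mini_chondro": _build_mini_chondro,
}


def motif(name: str) -> NetworkModel:
    """Return a bundled motif model by name (see :data:`MOTIF_NAMES`)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown motif {name!r}; available: {', '.join(MOTIF_NAMES)}"
        ) from None
    m = builder()
    m.validate()
    return m


def motif_classifier(name: str) -> FateClassifier:
    """Fate classifier matching a motif's master regulators."""
    if name == "mini_chondro":
        return FateClassifier.two_fate("X", "Y")
    return FateClassifier.two_fate()


def fixture_path(name: str) -> Path:
    """Path to the bundled JSON model file for a motif."""
    if name not in _BUILDERS:
        raise KeyError(f"unknown motif {name!r}")
    return _DATA_DIR / f"{name}.json"


# ---------------------------------------------------------------------------
# Random network generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Parameters for :func:`random_network`."""

    n_nodes: int
    edge_density: float = 0.2
    frac_slow: float = 0.0
    frac_and: float = 0.0
    seed: int = 0
    levels: int = 100
    p_activation: float = 0.5

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        for name in ("frac_slow", "frac_and", "p_activation"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


def random_network(params: GeneratorParams) -> NetworkModel:
    """Seeded random activity network; every node gets a self-inhibition.

    Cross-edges are drawn per ordered node pair with probability
    ``edge_density``; a ``frac_and`` fraction become scenario-3 edges
    with a second random regulator.  Edge and node classes are slow with
    probability ``frac_slow`` (k 0.1), else fast (k 1.0).  No constant
    nodes are generated, so the all-zero state is always quiescent.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_nodes
    names = [f"N{i:02d}" for i in range(n)]
    classes = [
        "slow" if rng.random() < params.frac_slow else "fast" for _ in range(n)
    ]
    nodes = [
        NodeSpec(nm, levels=params.levels, reaction_class=cls)
        for nm, cls in zip(names, classes)
    ]
    edges = []
    for i in range(n):
        for j in range(n):
            if i == j or rng.random() >= params.edge_density:
                continue
            cls = "slow" if rng.random() < params.frac_slow else "fast"
            k = 0.1 if cls == "slow" else 1.0
            sign = (
                "activation"
                if rng.random() < params.p_activation
                else "inhibition"
            )
            if n >= 3 and rng.random() < params.frac_and:
                others = [q for q in range(n) if q != i and q != j]
                r2 = others[int(rng.integers(len(others)))]
                edges.append(
                    EdgeSpec((names[i], names[r2]), names[j], sign, 3, k, cls)
                )
            else:
                edges.append(EdgeSpec((names[i],), names[j], sign, 1, k, cls))
    for i in range(n):
        k = 0.1 if classes[i] == "slow" else 1.0
        edges.append(
            EdgeSpec((names[i],), names[i], "inhibition", 1, k, classes[i])
        )
    model = NetworkModel(
        nodes=nodes,
        edges=edges,
        metadata={"name": f"random_{params.seed}", "generator": vars(params)},
    )
    model.validate(translated=True)
    return model


# ---------------------------------------------------------------------------
# Continuous rate-equation oracle
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ode_kernel(
    x, clamped, e_scn, e_sign, e_k, e_r1, e_r2, e_tgt, dt, tol, max_steps
):
    n = x.shape[0]
    E = e_k.shape[0]
    rho = np.zeros(n)
    for step in range(max_steps):
        for i in range(n):
            rho[i] = 0.0
        for j in range(E):
            act = x[e_r1[j]]
            scn = e_scn[j]
            if scn == 1:
                rate = e_k[j] * act
            elif scn == 2:
                s = x[e_tgt[j]]
                if e_sign[j] > 0:
                    rate = e_k[j] * act * (1.0 - s)
                else:
                    rate = e_k[j] * act * s
            else:
                rate = e_k[j] * act * x[e_r2[j]]
            if e_sign[j] > 0:
                rho[e_tgt[j]] += rate
            else:
                rho[e_tgt[j]] -= rate
        resid = 0.0
        for i in range(n):
            if clamped[i]:
                continue
            r = rho[i]
            if (x[i] <= 0.0 and r < 0.0) or (x[i] >= 1.0 and r > 0.0):
                r = 0.0  # pushing against a bound does not count
            if abs(r) > resid:
                resid = abs(r)
        if resid < tol:
            return True
        for i in range(n):
            if clamped[i]:
                continue
            v = x[i] + dt * rho[i]
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            x[i] = v
    return False


@dataclass
class OracleResult:
    """Continuous fixed point (normalized to [0, 1]) and convergence flag."""

    fixed_point: dict[str, float]
    converged: bool

    def scaled(self, levels: Mapping[str, int] | int = 100) -> dict[str, float]:
        if isinstance(levels, int):
            return {k: v * levels for k, v in self.fixed_point.items()}
        return {k: v * levels[k] for k, v in self.fixed_point.items()}


def ode_oracle(
    model: NetworkModel,
    init: Mapping[str, int] | None = None,
    dt: float = 1e-3,
    tol: float = 1e-9,
    max_steps: int = 2_000_000,
) -> OracleResult:
    """Integrate the continuous rate equations to a fixed point.

    Fixed-step Euler integration of ``dx/dt = net_rate(x)`` on the
    normalized cube [0, 1]^n, sharing no code with the event-driven
    simulator.  Non-convergence is reported, not raised.
    """
    cm = engine.CompiledModel(model)
    a0 = cm.make_init(init)
    x = a0.astype(np.float64) / cm.levels.astype(np.float64)
    if cm.n == 0:
        return OracleResult({}, True)
    converged = _ode_kernel(
        x,
        cm.clamped,
        cm.e_scn,
        cm.e_sign,
        cm.e_k,
        cm.e_r1,
        cm.e_r2,
        cm.e_tgt,
        dt,
        tol,
        max_steps,
    )
    fp = {name: float(v) for name, v in zip(cm.node_names, x)}
    return OracleResult(fp, bool(converged))
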