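"""Domain types and I/O for activity-network models.

An activity network is a directed graph whose nodes carry an integer
activity level on a bounded scale (0..levels, 100 by default) and whose
edges are signed interactions with one of three abstract rate laws
("kinetic scenarios") and a single strength parameter ``k``:

* scenario 1 — rate depends on the upstream regulator only,
* scenario 2 — rate depends on the regulator and on the availability of
  the target,
* scenario 3 — rate depends on two regulators jointly (AND kinetics).

Models are stored as a single JSON document with top-level ``nodes`` and
``edges`` arrays (see ``model_schema.json`` for the documented shape) and
can be exported to SIF and GraphML for use in graph tools.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .predicates import AllZeroPredicate, Predicate, parse_predicate

__all__ = [
    "NodeSpec",
    "EdgeSpec",
    "NetworkModel",
    "FateClassifier",
    "ModelError",
    "ModelParseError",
    "ModelValidationError",
    "load_model",
    "save_model",
    "loads_model",
    "dumps_model",
    "export_sif",
    "export_graphml",
    "apply_clamps",
    "scale_downstream",
    "contract_nodes",
    "SLOW_K",
    "FAST_K",
]

SLOW_K = 0.1
FAST_K = 1.0
CLASS_K = {"slow": SLOW_K, "fast": FAST_K}


class ModelError(Exception):
    """Base class for model-related failures."""


class ModelParseError(ModelError):
    """A model file could not be parsed; carries field context."""


class ModelValidationError(ModelError):
    """A model violates structural invariants; lists every violation."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class NodeSpec:
    """One molecular species with a bounded integer activity level."""

    name: str
    levels: int = 100
    initial: int = 0
    clamp: int | None = None
    reaction_class: str = "fast"

    def validate(self) -> list[str]:
        errs = []
        if not self.name:
            errs.append("node with empty name")
        if self.levels < 1:
            errs.append(f"node {self.name!r}: levels must be >= 1")
        if not (0 <= self.initial <= self.levels):
            errs.append(
                f"node {self.name!r}: initial {self.initial} outside "
                f"[0, {self.levels}]"
            )
        if self.clamp is not None and not (0 <= self.clamp <= self.levels):
            errs.append(
                f"node {self.name!r}: clamp {self.clamp} outside [0, {self.levels}]"
            )
        if self.reaction_class not in ("slow", "fast"):
            errs.append(
                f"node {self.name!r}: reaction_class must be 'slow' or 'fast'"
            )
        return errs

    @property
    def is_constant(self) -> bool:
        return self.clamp is not None


@dataclass(frozen=True)
class EdgeSpec:
    """One signed interaction with a kinetic scenario and strength ``k``.

    ``regulators`` holds one name for scenarios 1-2 and exactly two for
    scenario 3.  ``reaction_class`` records whether the underlying
    reaction is slow (expression-like) or fast (modification-like); it is
    informative for dual-regulation expansion and does not affect rates.
    """

    regulators: tuple[str, ...]
    target: str
    sign: str = "activation"
    scenario: int = 1
    k: float = FAST_K
    reaction_class: str = "fast"

    def __post_init__(self):
        object.__setattr__(self, "regulators", tuple(self.regulators))

    def validate(self, node_names: set[str] | None = None) -> list[str]:
        errs = []
        if self.sign not in ("activation", "inhibition"):
            errs.append(f"edge to {self.target!r}: bad sign {self.sign!r}")
        if self.scenario not in (1, 2, 3):
            errs.append(f"edge to {self.target!r}: bad scenario {self.scenario}")
        n_reg = len(self.regulators)
        if self.scenario == 3 and n_reg != 2:
            errs.append(
                f"edge to {self.target!r}: scenario 3 requires exactly two "
                f"regulators, got {n_reg}"
            )
        if self.scenario in (1, 2) and n_reg != 1:
            errs.append(
                f"edge to {self.target!r}: scenario {self.scenario} requires "
                f"exactly one regulator, got {n_reg}"
            )
        if not (self.k > 0):
            errs.append(f"edge to {self.target!r}: k must be > 0, got {self.k}")
        if self.reaction_class not in ("slow", "fast"):
            errs.append(f"edge to {self.target!r}: bad reaction_class")
        if node_names is not None:
            for name in (*self.regulators, self.target):
                if name not in node_names:
                    errs.append(
                        f"edge {self.regulators}->{self.target!r}: unknown "
                        f"node {name!r}"
                    )
        return errs

    @property
    def is_self_inhibition(self) -> bool:
        return (
            self.sign == "inhibition"
            and len(self.regulators) == 1
            and self.regulators[0] == self.target
        )


@dataclass
class NetworkModel:
    """An executable activity network: nodes, edges and metadata."""

    nodes: list[NodeSpec] = field(default_factory=list)
    edges: list[EdgeSpec] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- lookup helpers -------------------------------------------------
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def node(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"unknown node {name!r}")

    def node_index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(f"unknown node {name!r}")

    def in_edges(self, name: str) -> list[EdgeSpec]:
        return [e for e in self.edges if e.target == name]

    def out_edges(self, name: str) -> list[EdgeSpec]:
        """Edges whose regulator set includes *name* (self-loops included)."""
        return [e for e in self.edges if name in e.regulators]

    # -- validation -----------------------------------------------------
    def validate(self, translated: bool = False) -> None:
        """Check all structural invariants; raise listing every violation.

        With ``translated=True`` additionally require exactly one
        self-inhibition edge on every non-constant node (the shape
        produced by Boolean-model translation).
        """
        errs: list[str] = []
        names = [n.name for n in self.nodes]
        seen = set()
        for name in names:
            if name in seen:
                errs.append(f"duplicate node name {name!r}")
            seen.add(name)
        for n in self.nodes:
            errs.extend(n.validate())
        for e in self.edges:
            errs.extend(e.validate(seen))
        if translated:
            for n in self.nodes:
                if n.is_constant:
                    continue
                loops = [
                    e for e in self.in_edges(n.name) if e.is_self_inhibition
                ]
                if len(loops) != 1:
                    errs.append(
                        f"translated model: node {n.name!r} has "
                        f"{len(loops)} self-inhibition edges (need exactly 1)"
                    )
        if errs:
            raise ModelValidationError(errs)

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            nodes=list(self.nodes),
            edges=list(self.edges),
            metadata=copy.deepcopy(self.metadata),
        )

    def structurally_equal(self, other: "NetworkModel") -> bool:
        """Node/edge multiset equality, ignoring metadata and order."""
        return sorted(self.nodes, key=lambda n: n.name) == sorted(
            other.nodes, key=lambda n: n.name
        ) and sorted(self.edges, key=_edge_key) == sorted(other.edges, key=_edge_key)


def _edge_key(e: EdgeSpec):
    return (e.target, e.regulators, e.sign, e.scenario, e.k)


# ---------------------------------------------------------------------------
# JSON model format
# ---------------------------------------------------------------------------

def _node_to_dict(n: NodeSpec) -> dict:
    d = {"name": n.name, "levels": n.levels, "initial": n.initial}
    if n.clamp is not None:
        d["clamp"] = n.clamp
    if n.reaction_class != "fast":
        d["reaction_class"] = n.reaction_class
    return d


def _edge_to_dict(e: EdgeSpec) -> dict:
    d = {
        "regulators": list(e.regulators),
        "target": e.target,
        "sign": e.sign,
        "scenario": e.scenario,
        "k": e.k,
    }
    if e.reaction_class != "fast":
        d["reaction_class"] = e.reaction_class
    return d


def dumps_model(model: NetworkModel) -> str:
    doc = {
        "format": "actnet-model",
        "version": 1,
        "metadata": model.metadata,
        "nodes": [_node_to_dict(n) for n in model.nodes],
        "edges": [_edge_to_dict(e) for e in model.edges],
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


def _require(d: Mapping, key: str, ctx: str):
    if key not in d:
        raise ModelParseError(f"{ctx}: missing required field {key!r}")
    return d[key]


def loads_model(text: str, source: str = "<string>") -> NetworkModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelParseError(
            f"{source}: not valid JSON (line {exc.lineno}, col {exc.colno}): "
            f"{exc.msg}"
        ) from exc
    if not isinstance(doc, dict):
        raise ModelParseError(f"{source}: top level must be a JSON object")
    nodes = []
    for i, nd in enumerate(doc.get("nodes", [])):
        ctx = f"{source}: nodes[{i}]"
        if not isinstance(nd, dict):
            raise ModelParseError(f"{ctx}: must be an object")
        try:
            nodes.append(
                NodeSpec(
                    name=str(_require(nd, "name", ctx)),
                    levels=int(nd.get("levels", 100)),
                    initial=int(nd.get("initial", 0)),
                    clamp=None if nd.get("clamp") is None else int(nd["clamp"]),
                    reaction_class=str(nd.get("reaction_class", "fast")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ModelParseError(f"{ctx}: {exc}") from exc
    edges = []
    for i, ed in enumerate(doc.get("edges", [])):
        ctx = f"{source}: edges[{i}]"
        if not isinstance(ed, dict):
            raise ModelParseError(f"{ctx}: must be an object")
        regs = ed.get("regulators")
        if regs is None and "source" in ed:
            regs = [ed["source"]]
        if not isinstance(regs, list):
            raise ModelParseError(f"{ctx}: 'regulators' must be a list")
        try:
            edges.append(
                EdgeSpec(
                    regulators=tuple(str(r) for r in regs),
                    target=str(_require(ed, "target", ctx)),
                    sign=str(ed.get("sign", "activation")),
                    scenario=int(ed.get("scenario", 1)),
                    k=float(_require(ed, "k", ctx)),
                    reaction_class=str(ed.get("reaction_class", "fast")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ModelParseError(f"{ctx}: {exc}") from exc
    metadata = doc.get("metadata", {})
    if not isinstance(metadata, dict):
        raise ModelParseError(f"{source}: 'metadata' must be an object")
    model = NetworkModel(nodes=nodes, edges=edges, metadata=metadata)
    model.validate()
    return model


def load_model(path) -> NetworkModel:
    """Load and validate a model from a JSON model file."""
    path = Path(path)
    return loads_model(path.read_text(), source=str(path))


def save_model(model: NetworkModel, path) -> None:
    """Write the model as a JSON model file (round-trips exactly)."""
    model.validate()
    Path(path).write_text(dumps_model(model))


# ---------------------------------------------------------------------------
# Exchange exports
# ---------------------------------------------------------------------------

_SIF_RELATION = {"activation": "activates", "inhibition": "inhibits"}


def export_sif(model: NetworkModel) -> str:
    """SIF rows ``source<TAB>relation<TAB>target``.

    A scenario-3 edge is written as a single record whose source token
    joins both regulators with ``&``.
    """
    rows = []
    for e in model.edges:
        src = "&".join(e.regulators)
        rows.append(f"{src}\t{_SIF_RELATION[e.sign]}\t{e.target}")
    return "\n".join(rows) + ("\n" if rows else "")


def export_graphml(model: NetworkModel, path=None) -> str:
    """GraphML with Cytoscape-style ``interaction`` plus ``scenario``/``k``.

    Scenario-3 edges become one graph edge per regulator, sharing the
    attribute ``coregulator`` naming the partner.
    """
    g = nx.MultiDiGraph(name=model.metadata.get("name", "actnet-model"))
    for n in model.nodes:
        g.add_node(
            n.name,
            levels=n.levels,
            initial=n.initial,
            clamp=-1 if n.clamp is None else n.clamp,
            reaction_class=n.reaction_class,
        )
    for i, e in enumerate(model.edges):
        for reg in e.regulators:
            attrs = {
                "interaction": _SIF_RELATION[e.sign],
                "scenario": e.scenario,
                "k": e.k,
                "edge_id": i,
            }
            if e.scenario == 3:
                partner = [r for r in e.regulators if r != reg]
                attrs["coregulator"] = partner[0] if partner else reg
            g.add_edge(reg, e.target, **attrs)
    text = "\n".join(nx.generate_graphml(g))
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Editing operations
# ---------------------------------------------------------------------------

def apply_clamps(model: NetworkModel, clamps: Mapping[str, int]) -> NetworkModel:
    """Return a copy with the given nodes clamped to constant levels.

    Clamped nodes never change during simulation but still drive the
    rates of their downstream edges.  Used for constant "dummy" nodes
    and for knockout (clamp 0) / constitutive activation (clamp full).
    """
    out = model.copy()
    for name, level in clamps.items():
        idx = out.node_index(name)  # KeyError for unknown nodes
        n = out.nodes[idx]
        if not (0 <= level <= n.levels):
            raise ModelValidationError(
                [f"clamp {level} for {name!r} outside [0, {n.levels}]"]
            )
        out.nodes[idx] = replace(n, clamp=level, initial=level)
    return out


def scale_downstream(
    model: NetworkModel, node: str, factor: float
) -> NetworkModel:
    """Multiply ``k`` of every edge regulated by *node* by *factor*.

    The node's own self-inhibition is left untouched: scaling models a
    change in the strength of a node's downstream influence (e.g. a
    tissue-specific expression ratio), not of its decay.
    """
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    model.node(node)  # KeyError for unknown node
    out = model.copy()
    out.edges = [
        replace(e, k=e.k * factor)
        if node in e.regulators and not e.is_self_inhibition
        else e
        for e in out.edges
    ]
    return out


def contract_nodes(model: NetworkModel, nodes: Iterable[str]) -> NetworkModel:
    """Remove pass-through nodes, re-targeting their in-edges.

    Each contracted node must have exactly one outgoing non-self edge;
    its incoming edges are redirected to that unique successor
    (preserving sign, scenario and k) and its self-inhibition dropped.
    """
    out = model.copy()
    for name in nodes:
        out.node(name)  # KeyError for unknown node
        succ_edges = [
            e for e in out.edges
            if name in e.regulators and not e.is_self_inhibition
        ]
        if len(succ_edges) != 1:
            raise ModelValidationError(
                [
                    f"cannot contract {name!r}: needs exactly one outgoing "
                    f"non-self edge, found {len(succ_edges)}"
                ]
            )
        successor = succ_edges[0].target
        new_edges = []
        for e in out.edges:
            if e.target == name and e.is_self_inhibition:
                continue  # drop the contracted node's self-loop
            if e is succ_edges[0]:
                continue  # drop the pass-through edge itself
            if e.target == name:
                e = replace(e, target=successor)
            new_edges.append(e)
        out.edges = new_edges
        out.nodes = [n for n in out.nodes if n.name != name]
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Fate classification
# ---------------------------------------------------------------------------

@dataclass
class FateClassifier:
    """Ordered (label, predicate) rules mapping reported levels to a fate.

    The first rule whose predicate holds wins; states matching no rule
    get ``fallback_label``.
    """

    rules: list[tuple[str, object]] = field(default_factory=list)
    fallback_label: str = "other"

    def __post_init__(self):
        labels = [lab for lab, _ in self.rules]
        if len(labels) != len(set(labels)):
            raise ValueError("fate labels must be unique")

    def classify(self, levels: Mapping[str, int]) -> str:
        for label, pred in self.rules:
            if pred.holds(levels):
                return label
        return self.fallback_label

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.rules] + [self.fallback_label]

    @classmethod
    def two_fate(
        cls,
        x: str = "SOX9",
        y: str = "RUNX2",
        high: int = 60,
        low: int = 20,
    ) -> "FateClassifier":
        """Mutually exclusive two-master-regulator classifier.

        ``<x>+`` means *x* high and *y* low, ``<y>+`` the converse,
        ``Null`` the all-zero state, everything else ``other``.
        """
        return cls(
            rules=[
                (f"{x}+", parse_predicate(f"{x} >= {high} && {y} < {low}")),
                (f"{y}+", parse_predicate(f"{y} >= {high} && {x} < {low}")),
                ("Null", AllZeroPredicate()),
            ],
            fallback_label="other",
        )
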