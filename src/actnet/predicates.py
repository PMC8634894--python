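"""Threshold predicates over node activity levels.

A predicate is a conjunction of atomic comparisons such as
``RUNX2 >= 60 && SOX9 < 20``.  Predicates are used both by the fate
classifier (labelling attractor states) and by the reachability checker
(persistence / reachability queries).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Atom",
    "Predicate",
    "AllZeroPredicate",
    "parse_predicate",
    "PredicateError",
]

_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "=": lambda a, b: a == b,
    "==": lambda a, b: a == b,
}

_ATOM_RE = re.compile(
    r"^\s*([A-Za-z_][A-Za-z0-9_.+-]*)\s*(<=|>=|==|<|>|=)\s*(-?\d+)\s*$"
)


class PredicateError(ValueError):
    """Raised on malformed predicate text or invalid atoms."""


@dataclass(frozen=True)
class Atom:
    """One comparison ``node op threshold`` on an integer activity level."""

    node: str
    op: str
    threshold: int

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise PredicateError(f"unknown operator {self.op!r}")

    def holds(self, levels: Mapping[str, int]) -> bool:
        try:
            value = levels[self.node]
        except KeyError:
            raise PredicateError(f"unknown node {self.node!r} in predicate")
        return _OPS[self.op](value, self.threshold)

    def __str__(self) -> str:
        op = "==" if self.op == "=" else self.op
        return f"{self.node} {op} {self.threshold}"


@dataclass(frozen=True)
class Predicate:
    """Conjunction of :class:`Atom` comparisons."""

    atoms: tuple[Atom, ...] = field(default_factory=tuple)

    def holds(self, levels: Mapping[str, int]) -> bool:
        return all(atom.holds(levels) for atom in self.atoms)

    def negation_hint(self) -> str:
        return " || ".join(f"!({a})" for a in self.atoms)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(a.node for a in self.atoms)

    def __str__(self) -> str:
        return " && ".join(str(a) for a in self.atoms)


@dataclass(frozen=True)
class AllZeroPredicate:
    """True iff every reported level is exactly zero (the Null state)."""

    def holds(self, levels: Mapping[str, int]) -> bool:
        return all(v == 0 for v in levels.values())

    def __str__(self) -> str:
        return "<all zero>"


def parse_predicate(text: str, model=None) -> Predicate:
    """Parse ``"A >= 60 && B < 20"`` into a :class:`Predicate`.

    When *model* (a :class:`actnet.model.NetworkModel`) is given, node
    names are checked for existence and thresholds for range.
    """
    parts = text.split("&&")
    if not text.strip():
        raise PredicateError("empty predicate")
    atoms = []
    for part in parts:
        m = _ATOM_RE.match(part)
        if m is None:
            raise PredicateError(f"cannot parse predicate atom {part.strip()!r}")
        node, op, thr = m.group(1), m.group(2), int(m.group(3))
        if op == "==":
            op = "="
        atoms.append(Atom(node, op, thr))
    pred = Predicate(tuple(atoms))
    if model is not None:
        for atom in pred.atoms:
            if atom.node not in model.node_names():
                raise PredicateError(f"unknown node {atom.node!r} in predicate")
            levels = model.node(atom.node).levels
            if not (0 <= atom.threshold <= levels):
                raise PredicateError(
                    f"threshold {atom.threshold} for {atom.node!r} outside "
                    f"[0, {levels}]"
                )
    return pred
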