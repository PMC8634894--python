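"""Translation of Boolean/additive rule models into activity networks.

Rule files are plain text, one rule per line::

    # comment
    C = A | B
    D = A & B            @slow
    Ras = Wnt | BMP | FGFR1 | FGFR3  @w(Wnt)=0.444 @w(BMP)=0.444 @w(FGFR1)=0.444 @w(FGFR3)=0.444
    SOX9 = TF | PTM      @dual @slow(TF) @fast(PTM)
    input Wnt
    const ON = 100

Translation rules:

* each OR branch becomes an independent edge (additive, non-exclusive);
* a binary AND of two positive literals becomes one scenario-3 edge;
* a negated literal becomes an inhibition edge;
* every non-constant node gets exactly one self-inhibition loop with k
  set by its reaction class (0.1 slow / 1.0 fast);
* nodes tagged ``@dual`` are expanded into the three-node
  expression/PTM pattern (``X_prot`` AND ``X_PTM`` activate ``X``).

Branch strength is ``weight * k_class`` when a ``@w(source)=value``
annotation is present, else ``k_class`` alone; weights are input data,
not derived.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .model import (
    CLASS_K,
    EdgeSpec,
    ModelParseError,
    NetworkModel,
    NodeSpec,
)

__all__ = [
    "BooleanModel",
    "RuleError",
    "parse_boolean_rules",
    "translate",
    "expand_dual_regulation",
]


class RuleError(ModelParseError):
    """Syntax or integrity error in a Boolean rule file."""


@dataclass(frozen=True)
class Literal:
    name: str
    negated: bool = False


@dataclass(frozen=True)
class AndBranch:
    left: Literal
    right: Literal


Branch = Literal | AndBranch


@dataclass
class BooleanModel:
    """Parsed rule set: one OR-of-branches expression per target node."""

    rules: dict[str, list[Branch]] = field(default_factory=dict)
    class_tags: dict[str, str] = field(default_factory=dict)
    dual_regulation: set[str] = field(default_factory=set)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    branch_class: dict[tuple[str, str], str] = field(default_factory=dict)
    inputs: set[str] = field(default_factory=set)
    constants: dict[str, int] = field(default_factory=dict)

    def declared(self) -> set[str]:
        return set(self.rules) | self.inputs | set(self.constants)

    def node_class(self, name: str) -> str:
        return self.class_tags.get(name, "fast")

    def validate(self) -> None:
        names = self.declared()
        errs = []
        for target, branches in self.rules.items():
            for br in branches:
                lits = (br,) if isinstance(br, Literal) else (br.left, br.right)
                for lit in lits:
                    if lit.name not in names:
                        errs.append(
                            f"rule for {target!r} references undeclared "
                            f"node {lit.name!r}"
                        )
        for (target, src), w in self.weights.items():
            if w <= 0:
                errs.append(f"weight for {src!r} -> {target!r} must be > 0")
        for name in self.dual_regulation:
            if name not in self.rules:
                errs.append(f"@dual node {name!r} has no rule")
        if errs:
            raise RuleError("; ".join(errs))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_ANN_RE = re.compile(
    rf"@(?:(dual)|(slow|fast)\(({_NAME})\)|(slow|fast)|w\(({_NAME})\)\s*=\s*([0-9.eE+-]+))"
)
_TOKEN_RE = re.compile(rf"\s*(?:({_NAME})|([|&!()])|(\S))")


def _tokenize(expr: str, lineno: int) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            break
        if m.group(3):
            raise RuleError(
                f"line {lineno}: unexpected character {m.group(3)!r}"
            )
        tokens.append(m.group(1) or m.group(2))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for OR / AND / NOT / parentheses."""

    def __init__(self, tokens: list[str], lineno: int):
        self.tokens = tokens
        self.pos = 0
        self.lineno = lineno

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def fail(self, msg):
        raise RuleError(f"line {self.lineno}: {msg}")

    def parse(self) -> list[Branch]:
        branches = self.or_expr()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return branches

    def or_expr(self) -> list[Branch]:
        branches = [self.and_expr()]
        while self.peek() == "|":
            self.take()
            branches.append(self.and_expr())
        return branches

    def and_expr(self) -> Branch:
        left = self.unary()
        if self.peek() != "&":
            return left
        self.take()
        right = self.unary()
        if self.peek() == "&":
            self.fail(
                "AND gates are strictly binary; nest n-ary ANDs through "
                "intermediate nodes"
            )
        if isinstance(left, AndBranch) or isinstance(right, AndBranch):
            self.fail("nested AND gates are not supported; use helper nodes")
        return AndBranch(left, right)

    def unary(self) -> Literal | AndBranch:
        tok = self.peek()
        if tok == "!":
            self.take()
            inner = self.unary()
            if not isinstance(inner, Literal) or inner.negated:
                self.fail("'!' applies to a single node name")
            return Literal(inner.name, negated=True)
        if tok == "(":
            self.take()
            inner = self.or_expr()
            if self.take() != ")":
                self.fail("unbalanced parenthesis")
            if len(inner) != 1:
                self.fail("OR must be at the top level of a rule")
            return inner[0]
        if tok is None or tok in "|&()!":
            self.fail(f"expected a node name, got {tok!r}")
        return Literal(self.take())


def parse_boolean_rules(text: str) -> BooleanModel:
    """Parse a rule file into a :class:`BooleanModel` (integrity-checked)."""
    bm = BooleanModel()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.match(rf"^const\s+({_NAME})\s*=\s*(\d+)$", line)
        if m:
            bm.constants[m.group(1)] = int(m.group(2))
            continue
        m = re.match(rf"^input\s+({_NAME})$", line)
        if m:
            bm.inputs.add(m.group(1))
            continue
        if "=" not in line:
            raise RuleError(f"line {lineno}: expected 'target = expression'")
        target, rhs = line.split("=", 1)
        target = target.strip()
        if not re.fullmatch(_NAME, target):
            raise RuleError(f"line {lineno}: bad target name {target!r}")
        if target in bm.rules:
            raise RuleError(f"line {lineno}: duplicate rule for {target!r}")
        # pull out @annotations before parsing the expression
        expr = rhs
        for ann in _ANN_RE.finditer(rhs):
            if ann.group(1):
                bm.dual_regulation.add(target)
            elif ann.group(2):
                bm.branch_class[(target, ann.group(3))] = ann.group(2)
            elif ann.group(4):
                bm.class_tags[target] = ann.group(4)
            else:
                try:
                    bm.weights[(target, ann.group(5))] = float(ann.group(6))
                except ValueError:
                    raise RuleError(
                        f"line {lineno}: bad weight value {ann.group(6)!r}"
                    ) from None
        expr = _ANN_RE.sub("", expr).strip()
        if not expr:
            raise RuleError(f"line {lineno}: empty expression")
        bm.rules[target] = _Parser(_tokenize(expr, lineno), lineno).parse()
    bm.validate()
    return bm


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def _branch_k(bm: BooleanModel, target: str, source: str, cls: str) -> float:
    k = CLASS_K[cls]
    w = bm.weights.get((target, source))
    return w * k if w is not None else k


def _branch_cls(bm: BooleanModel, target: str, source: str) -> str:
    return bm.branch_class.get((target, source), bm.node_class(target))


def translate(bm: BooleanModel) -> NetworkModel:
    """Compile a Boolean rule model into a validated activity network."""
    bm.validate()
    nodes = []
    for name in sorted(bm.declared()):
        if name in bm.constants:
            nodes.append(NodeSpec(name, clamp=bm.constants[name],
                                  initial=bm.constants[name]))
        else:
            nodes.append(NodeSpec(name, reaction_class=bm.node_class(name)))
    edges: list[EdgeSpec] = []
    for target, branches in bm.rules.items():
        seen_classes = set()
        for br in branches:
            if isinstance(br, Literal):
                cls = _branch_cls(bm, target, br.name)
                edges.append(
                    EdgeSpec(
                        regulators=(br.name,),
                        target=target,
                        sign="inhibition" if br.negated else "activation",
                        scenario=1,
                        k=_branch_k(bm, target, br.name, cls),
                        reaction_class=cls,
                    )
                )
            else:
                if br.left.negated or br.right.negated:
                    raise RuleError(
                        f"rule for {target!r}: negated literals inside AND "
                        "are not representable with AND kinetics; move the "
                        "negation to its own inhibition branch"
                    )
                cls = _branch_cls(bm, target, br.left.name)
                edges.append(
                    EdgeSpec(
                        regulators=(br.left.name, br.right.name),
                        target=target,
                        sign="activation",
                        scenario=3,
                        k=CLASS_K[cls],
                        reaction_class=cls,
                    )
                )
            seen_classes.add(edges[-1].reaction_class)
        if len(seen_classes) > 1 and target not in bm.dual_regulation:
            warnings.warn(
                f"node {target!r} has mixed slow/fast influences but is not "
                "tagged @dual; consider the expression/PTM pattern",
                stacklevel=2,
            )
    # one self-inhibition per non-constant node
    for name in sorted(bm.declared()):
        if name in bm.constants:
            continue
        k = CLASS_K[bm.node_class(name)]
        edges.append(
            EdgeSpec(
                regulators=(name,),
                target=name,
                sign="inhibition",
                scenario=1,
                k=k,
                reaction_class=bm.node_class(name),
            )
        )
    model = NetworkModel(nodes=nodes, edges=edges,
                         metadata={"source": "boolean-rules"})
    for name in sorted(bm.dual_regulation):
        model = expand_dual_regulation(model, name)
    model.validate(translated=True)
    return model


def expand_dual_regulation(model: NetworkModel, node: str) -> NetworkModel:
    """Split *node* into the three-node expression/PTM pattern.

    A ``<node>_prot`` node receives all slow influences, a
    ``<node>_PTM`` node all fast influences, and the main node keeps a
    single scenario-3 activation with regulators (prot, PTM) — the node
    must be both expressed and post-translationally activated to act.
    """
    spec = model.node(node)
    prot, ptm = f"{node}_prot", f"{node}_PTM"
    if prot in model.node_names() or ptm in model.node_names():
        raise ModelParseError(f"node {node!r} is already expanded")
    out = model.copy()
    out.nodes = [n for n in out.nodes if n.name != node] + [
        spec,
        NodeSpec(prot, levels=spec.levels, reaction_class="slow"),
        NodeSpec(ptm, levels=spec.levels, reaction_class="fast"),
    ]
    new_edges = []
    n_slow = 0
    for e in out.edges:
        if e.target != node or e.is_self_inhibition:
            new_edges.append(e)
            continue
        if e.reaction_class == "slow":
            new_edges.append(
                EdgeSpec(e.regulators, prot, e.sign, e.scenario, e.k, "slow")
            )
            n_slow += 1
        else:
            new_edges.append(
                EdgeSpec(e.regulators, ptm, e.sign, e.scenario, e.k, "fast")
            )
    if n_slow == 0:
        warnings.warn(
            f"dual node {node!r} has no slow influences: {prot!r} can never "
            "rise, so the main node can never activate",
            stacklevel=2,
        )
    new_edges.extend(
        [
            EdgeSpec((prot, ptm), node, "activation", 3,
                     CLASS_K[spec.reaction_class], spec.reaction_class),
            EdgeSpec((prot,), prot, "inhibition", 1, CLASS_K["slow"], "slow"),
            EdgeSpec((ptm,), ptm, "inhibition", 1, CLASS_K["fast"], "fast"),
        ]
    )
    out.edges = new_edges
    out.validate()
    return out
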