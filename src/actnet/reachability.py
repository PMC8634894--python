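"""Bounded persistence / reachability checking with timed interventions.

Because the simulator is deterministic, the only branching the checker
must explore is the timing of an optional intervention (clamping one
node at a chosen level at an unspecified moment).  Timing is enumerated
over a finite set of event indices plus "never", which reproduces the
qualitative model-checking patterns (persist / guaranteed reach /
possible reach) without a model-checker dependency.

Verdicts are three-valued ("true" / "false" / "unknown"): a run that
exhausts its event budget without resolving cannot support a universal
claim, so it degrades the verdict to "unknown" rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .model import NetworkModel, apply_clamps
from .predicates import Predicate, PredicateError, parse_predicate
from .simulate import SimState, Trajectory, simulate

__all__ = [
    "Predicate",
    "parse_predicate",
    "Intervention",
    "Property",
    "CheckResult",
    "check_persist",
    "check_reach",
    "DEFAULT_CHOICE_HORIZON",
]

DEFAULT_CHOICE_HORIZON = 200

NEVER = None  # sentinel time choice: the intervention is never applied


@dataclass(frozen=True)
class Intervention:
    """Clamp *node* at *level*, applied after one of several event counts.

    ``choices`` are event indices (0 = immediately, before any event);
    ``None`` means never.  An empty choice set degenerates to {never}.
    """

    node: str
    level: int
    choices: tuple[int | None, ...] = ()

    def normalized_choices(self) -> tuple[int | None, ...]:
        if not self.choices:
            return (NEVER,)
        return self.choices

    @classmethod
    def with_horizon(
        cls, node: str, level: int, horizon: int = DEFAULT_CHOICE_HORIZON
    ) -> "Intervention":
        """Enumerate every event index 0..horizon plus never."""
        return cls(node, level, tuple(range(horizon + 1)) + (NEVER,))


_QUANTIFIERS = {"persist", "guaranteed_reach", "possible_reach"}


@dataclass(frozen=True)
class Property:
    """A quantified predicate with an optional timed intervention."""

    quantifier: str  # persist (A[]) | guaranteed_reach (A<>) | possible_reach (E<>)
    predicate: Predicate
    intervention: Intervention | None = None

    def __post_init__(self):
        if self.quantifier not in _QUANTIFIERS:
            raise ValueError(f"unknown quantifier {self.quantifier!r}")
        if self.intervention is not None:
            choices = self.intervention.normalized_choices()
            if NEVER not in choices or 0 not in choices:
                raise ValueError(
                    "intervention time choices must include 'never' and "
                    "'immediately' (0)"
                )


@dataclass
class CheckResult:
    """Three-valued verdict with an optional witness/counterexample."""

    verdict: str  # "true" | "false" | "unknown"
    witness: Trajectory | None = None
    checked_choices: int = 0
    detail: str = ""


def _trajectory_prefix(tr: Trajectory, n_events: int) -> Trajectory:
    return Trajectory(
        initial=tr.initial,
        events=tr.events[:n_events],
        truncated=False,
        final=None,
    )


def _scan(tr: Trajectory, predicate: Predicate):
    """Indices of states (0 = initial) where the predicate holds/fails."""
    names = tr.initial.node_names
    first_hold = None
    first_fail = None
    for idx, (_, a) in enumerate(tr.iter_states()):
        levels = dict(zip(names, (int(v) for v in a)))
        ok = predicate.holds(levels)
        if ok and first_hold is None:
            first_hold = idx
        if not ok and first_fail is None:
            first_fail = idx
        if first_hold is not None and first_fail is not None:
            break
    return first_hold, first_fail


def check_persist(
    model: NetworkModel,
    init: SimState | Mapping[str, int] | None,
    predicate: Predicate | str,
    max_events: int | None = None,
) -> CheckResult:
    """Does the predicate hold at the initial state and forever after?

    The unperturbed model is deterministic, so the single trajectory —
    initial state, every event, and the attractor (one full cycle
    period) — decides the claim.  A trajectory that hits the event
    budget without resolving gives "unknown".
    """
    if isinstance(predicate, str):
        predicate = parse_predicate(predicate, model)
    tr = simulate(model, init=init, max_events=max_events)
    _, first_fail = _scan(tr, predicate)
    if first_fail is not None:
        return CheckResult(
            verdict="false",
            witness=_trajectory_prefix(tr, first_fail),
            checked_choices=1,
            detail=f"violated after {first_fail} event(s)",
        )
    if tr.truncated:
        return CheckResult(
            verdict="unknown",
            checked_choices=1,
            detail="event budget exhausted before reaching an attractor",
        )
    return CheckResult(verdict="true", checked_choices=1)


def _run_with_choice(
    model: NetworkModel,
    init,
    intervention: Intervention | None,
    choice: int | None,
    max_events: int | None,
) -> Trajectory:
    if intervention is None or choice is NEVER:
        return simulate(model, init=init, max_events=max_events)
    prefix = simulate(model, init=init, max_events=choice)
    clamped = apply_clamps(model, {intervention.node: intervention.level})
    suffix = simulate(
        clamped, init=prefix.final.as_dict(), max_events=max_events
    )
    offset = prefix.final.time
    events = prefix.events + [
        (offset + t, node, lv) for t, node, lv in suffix.events
    ]
    return Trajectory(
        initial=prefix.initial,
        events=events,
        truncated=suffix.truncated,
        final=suffix.final,
    )


def check_reach(
    model: NetworkModel,
    init: SimState | Mapping[str, int] | None,
    predicate: Predicate | str,
    mode: str = "possible",
    intervention: Intervention | None = None,
    max_events: int | None = None,
) -> CheckResult:
    """Can (or must) a predicate-satisfying state be visited?

    One deterministic simulation per intervention time choice.
    ``mode="possible"`` (E<>) asks for at least one satisfying choice
    and returns its witness; ``mode="guaranteed"`` (A<>) requires every
    choice to satisfy.  Without an intervention the two coincide.
    """
    if mode not in ("possible", "guaranteed"):
        raise ValueError(f"mode must be 'possible' or 'guaranteed', got {mode!r}")
    if isinstance(predicate, str):
        predicate = parse_predicate(predicate, model)
    choices = (
        intervention.normalized_choices() if intervention is not None else (NEVER,)
    )
    witness = None
    counterexample = None
    any_unknown = False
    any_false = False
    for choice in choices:
        tr = _run_with_choice(model, init, intervention, choice, max_events)
        first_hold, _ = _scan(tr, predicate)
        if first_hold is not None:
            if witness is None:
                witness = _trajectory_prefix(tr, first_hold)
            if mode == "possible":
                return CheckResult(
                    verdict="true",
                    witness=witness,
                    checked_choices=choices.index(choice) + 1,
                    detail=f"satisfied with intervention at choice {choice!r}",
                )
        elif tr.truncated:
            any_unknown = True
        else:
            any_false = True
            if counterexample is None:
                counterexample = tr
                bad_choice = choice
    n = len(choices)
    if mode == "possible":
        if any_unknown:
            return CheckResult(verdict="unknown", checked_choices=n,
                               detail="some branches unresolved, none satisfied")
        return CheckResult(verdict="false", checked_choices=n)
    # guaranteed
    if any_false:
        return CheckResult(
            verdict="false",
            witness=counterexample,
            checked_choices=n,
            detail=f"not satisfied with intervention at choice {bad_choice!r}",
        )
    if any_unknown:
        return CheckResult(verdict="unknown", checked_choices=n,
                           detail="some branches unresolved")
    return CheckResult(verdict="true", witness=witness, checked_choices=n)
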