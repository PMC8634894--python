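"""Monte Carlo fate-distribution analysis and perturbation screens.

A fate distribution is estimated by running many simulations from
uniformly random initial states to their attractors and classifying
each attractor with a :class:`~actnet.model.FateClassifier`; 99%
confidence half-widths use the Wald normal approximation.  Perturbation
screens clamp single nodes (knockout = 0, constitutive activation =
full scale) or node pairs and record how the fate distribution — or,
for pairwise screens started from a named attractor, the single
deterministic outcome — shifts.

All randomness flows from one master seed; per-run generators are
derived with a counter-based splitter, so results are exactly
reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import engine
from .model import FateClassifier, NetworkModel, apply_clamps
from .simulate import SimState, attractor_from_run, classify_fate, find_attractor

__all__ = [
    "FateDistribution",
    "PerturbationRecord",
    "random_init",
    "monte_carlo_fates",
    "proportion_ci",
    "ratio_with_ci",
    "single_perturbation_screen",
    "pairwise_switch_screen",
]


def proportion_ci(p_hat: float, n: int, conf: float = 0.99,
                  percent: bool = False) -> float:
    """Wald (normal-approximation) half-width for a binomial proportion.

    ``z * sqrt(p(1-p)/n)``; with ``percent=True`` the result is in
    percentage points.  Degenerate proportions (0 or 1) give 0.
    """
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < conf < 1.0):
        raise ValueError("conf must be in (0, 1)")
    z = norm.ppf((1.0 + conf) / 2.0)
    hw = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return float(hw * 100.0) if percent else float(hw)


def ratio_with_ci(
    p1: float, p2: float, n: int, conf: float = 0.99
) -> tuple[float, float]:
    """Ratio ``p1/p2`` of two multinomial proportions with a first-order
    delta-method half-width (approximate; includes the -p1*p2/n
    covariance of multinomial counts).  Returns (nan, nan) if p2 == 0.
    """
    if p2 == 0.0:
        return float("nan"), float("nan")
    r = p1 / p2
    v1 = p1 * (1.0 - p1) / n
    v2 = p2 * (1.0 - p2) / n
    cov = -p1 * p2 / n
    var = v1 / p2**2 + (p1**2 / p2**4) * v2 - 2.0 * (p1 / p2**3) * cov
    z = norm.ppf((1.0 + conf) / 2.0)
    return float(r), float(z * np.sqrt(max(var, 0.0)))


@dataclass
class FateDistribution:
    """Counts and proportions of fate labels over Monte Carlo runs."""

    n: int
    counts: dict[str, int]
    proportions: dict[str, float] = field(init=False)
    ci_halfwidth: dict[str, float] = field(init=False)
    conf: float = 0.99
    ratio: tuple[str, str, float, float] | None = None  # (num, den, value, hw)

    def __post_init__(self):
        total = sum(self.counts.values())
        if total != self.n:
            raise ValueError(f"counts sum to {total}, expected n={self.n}")
        self.proportions = {k: v / self.n for k, v in self.counts.items()}
        self.ci_halfwidth = {
            k: proportion_ci(p, self.n, self.conf)
            for k, p in self.proportions.items()
        }

    def with_ratio(self, numerator: str, denominator: str) -> "FateDistribution":
        p1 = self.proportions.get(numerator, 0.0)
        p2 = self.proportions.get(denominator, 0.0)
        r, hw = ratio_with_ci(p1, p2, self.n, self.conf)
        self.ratio = (numerator, denominator, r, hw)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns fate / proportion / ci / ratio."""
        rows = []
        for label in sorted(self.counts):
            ratio = float("nan")
            if self.ratio is not None and label == self.ratio[0]:
                ratio = self.ratio[2]
            rows.append(
                {
                    "fate": label,
                    "proportion": self.proportions[label],
                    "ci": self.ci_halfwidth[label],
                    "ratio": ratio,
                }
            )
        return pd.DataFrame(rows, columns=["fate", "proportion", "ci", "ratio"])


def _run_rng(seed, run_index: int) -> np.random.Generator:
    # counter-based splitting: independent stream per (seed, index)
    if isinstance(seed, (int, np.integer)):
        key = [int(seed), run_index]
    else:
        key = [*map(int, seed), run_index]
    return np.random.default_rng(key)


def random_init(model: NetworkModel, seed) -> SimState:
    """Uniform random initial state: each non-clamped node drawn on the
    integers 0..levels inclusive; clamped nodes at their clamp value."""
    cm = engine.CompiledModel(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a0 = _random_init_array(cm, rng)
    return SimState(a0, cm.node_names, cm.levels.copy(), cm.clamped.copy())


def _random_init_array(cm: engine.CompiledModel, rng) -> np.ndarray:
    a0 = rng.integers(0, cm.levels + 1, dtype=np.int64)
    a0[cm.clamped] = cm.clamp_values[cm.clamped]
    return a0


def monte_carlo_fates(
    model: NetworkModel,
    n: int,
    seed,
    classifier: FateClassifier,
    max_events: int | None = None,
    ratio_labels: tuple[str, str] | None = None,
    conf: float = 0.99,
) -> FateDistribution:
    """Fate distribution over *n* random initializations.

    Each run draws a uniform random initial state, simulates to the
    attractor, and classifies it; unresolved runs are counted under the
    label "unresolved", never dropped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cm = engine.CompiledModel(model)
    counts: dict[str, int] = {}
    for i in range(n):
        rng = _run_rng(seed, i)
        a0 = _random_init_array(cm, rng)
        res = cm.run(a0, max_events=max_events)
        label = classify_fate(attractor_from_run(cm, res), classifier)
        counts[label] = counts.get(label, 0) + 1
    dist = FateDistribution(n=n, counts=counts, conf=conf)
    if ratio_labels is not None:
        dist.with_ratio(*ratio_labels)
    return dist


@dataclass
class PerturbationRecord:
    """Outcome of clamping one node at 0 or full scale."""

    node: str
    clamp: int
    distribution: FateDistribution
    deviation: dict[str, float]  # perturbed - baseline proportion per fate


def single_perturbation_screen(
    model: NetworkModel,
    n: int,
    seed,
    classifier: FateClassifier,
    max_events: int | None = None,
) -> tuple[FateDistribution, list[PerturbationRecord]]:
    """Knockout / constitutive-activation screen over every node.

    For each node and each clamp level in {0, full}, runs a Monte Carlo
    fate distribution (independent random stream per condition) and
    reports the deviation from the unperturbed baseline.  Returns
    (baseline, records) with exactly ``2 * n_nodes`` records.
    """
    baseline = monte_carlo_fates(
        model, n, [seed, 0], classifier, max_events=max_events
    )
    records = []
    for idx, node in enumerate(model.node_names()):
        levels = model.node(node).levels
        for flag, clamp in enumerate((0, levels)):
            perturbed = apply_clamps(model, {node: clamp})
            dist = monte_carlo_fates(
                perturbed,
                n,
                [seed, 1 + 2 * idx + flag],
                classifier,
                max_events=max_events,
            )
            labels = set(baseline.proportions) | set(dist.proportions)
            deviation = {
                lab: dist.proportions.get(lab, 0.0)
                - baseline.proportions.get(lab, 0.0)
                for lab in sorted(labels)
            }
            records.append(PerturbationRecord(node, clamp, dist, deviation))
    return baseline, records


def screen_to_frame(records: Sequence[PerturbationRecord]) -> pd.DataFrame:
    """Deviation table: one row per (node, clamp, fate)."""
    rows = []
    for rec in records:
        for fate, dev in rec.deviation.items():
            rows.append(
                {
                    "node": rec.node,
                    "clamp": rec.clamp,
                    "fate": fate,
                    "proportion": rec.distribution.proportions.get(fate, 0.0),
                    "deviation": dev,
                }
            )
    return pd.DataFrame(
        rows, columns=["node", "clamp", "fate", "proportion", "deviation"]
    )


def _verify_attractor(model: NetworkModel, start_levels: Mapping[str, int]):
    att = find_attractor(model, init=dict(start_levels))
    if att.kind == "unresolved":
        raise ValueError("start_levels did not resolve to an attractor")
    tol = 0 if att.kind in ("fixed_point", "null") else 1
    for name, level in start_levels.items():
        if abs(att.reported_levels[name] - level) > tol:
            raise ValueError(
                f"start_levels is not an attractor: {name} reported "
                f"{att.reported_levels[name]}, given {level}"
            )


def pairwise_switch_screen(
    model: NetworkModel,
    start_levels: Mapping[str, int],
    classifier: FateClassifier,
    max_events: int | None = None,
) -> pd.DataFrame:
    """Deterministic switch screen from a verified attractor state.

    Every unordered node pair is clamped in the four knockout /
    full-activation combinations, plus every single node alone, all
    other nodes starting at ``start_levels``; each condition is one
    deterministic simulation whose resulting fate is recorded.  Output
    is long-format with columns node1, clamp1, node2, clamp2, fate
    (node2/clamp2 empty for single-node rows): ``4*C(n,2) + 2n`` rows.
    """
    _verify_attractor(model, start_levels)
    names = model.node_names()
    rows = []

    def outcome(clamps: dict[str, int]) -> str:
        perturbed = apply_clamps(model, clamps)
        att = find_attractor(perturbed, init=dict(start_levels),
                             max_events=max_events)
        return classify_fate(att, classifier)

    for node in names:
        full = model.node(node).levels
        for clamp in (0, full):
            rows.append(
                {
                    "node1": node, "clamp1": clamp,
                    "node2": "", "clamp2": pd.NA,
                    "fate": outcome({node: clamp}),
                }
            )
    for i, n1 in enumerate(names):
        full1 = model.node(n1).levels
        for n2 in names[i + 1:]:
            full2 = model.node(n2).levels
            for c1 in (0, full1):
                for c2 in (0, full2):
                    rows.append(
                        {
                            "node1": n1, "clamp1": c1,
                            "node2": n2, "clamp2": c2,
                            "fate": outcome({n1: c1, n2: c2}),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["node1", "clamp1", "node2", "clamp2", "fate"]
    )
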