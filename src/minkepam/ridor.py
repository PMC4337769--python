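"""Ripple-down-rule (RIDOR-style) classifier for pulse-train feature vectors.

A ripple-down rule set is a default label refined by an ordered list of
exception rules; each rule is a conjunction of single-feature threshold
conditions and may itself carry nested exceptions.  Classification descends
the tree: the deepest matching exception wins, otherwise the default
applies.  Induction is greedy — the default is the majority class, then
exception rules are grown one literal at a time by information gain until
they stop reducing training error, recursing on the examples each rule
captures.  Ties are broken deterministically (lowest feature index, then
lowest threshold), so refitting with the same data reproduces the same
rule set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["Condition", "Rule", "RuleSet", "ridor_fit", "classify", "RidorError"]


class RidorError(ValueError):
    """Invalid input to rule induction or classification."""


@dataclass(frozen=True)
class Condition:
    """Single-feature threshold test, ``feature <= threshold`` or ``> threshold``."""

    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def matches(self, fv: Mapping[str, float]) -> bool:
        v = fv[self.feature]
        return v <= self.threshold if self.op == "<=" else v > self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions predicting ``label``, with nested exceptions."""

    conditions: tuple[Condition, ...]
    label: str
    purity: float
    exceptions: tuple["Rule", ...] = ()

    def matches(self, fv: Mapping[str, float]) -> bool:
        return all(c.matches(fv) for c in self.conditions)


@dataclass(frozen=True)
class RuleSet:
    default_label: str
    default_purity: float
    rules: tuple[Rule, ...]
    feature_names: tuple[str, ...]

    def describe(self) -> str:
        lines = [f"default -> {self.default_label} (purity {self.default_purity:.2f})"]

        def walk(rules: tuple[Rule, ...], indent: int) -> None:
            for r in rules:
                cond = " and ".join(str(c) for c in r.conditions) or "(always)"
                lines.append(
                    "  " * indent + f"except if {cond} -> {r.label} (purity {r.purity:.2f})"
                )
                walk(r.exceptions, indent + 1)

        walk(self.rules, 1)
        return "\n".join(lines)


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(y: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    return np.array([(y == lab).sum() for lab in labels])


def _best_literal(
    X: np.ndarray,
    y_is_target: np.ndarray,
    covered: np.ndarray,
    feature_names: Sequence[str],
) -> tuple[Condition, np.ndarray] | None:
    """Best single-feature threshold condition by information gain.

    Evaluates both orientations at midpoints between consecutive distinct
    feature values among currently covered examples; deterministic
    tie-break on (feature index, threshold, orientation).
    """
    idx = np.nonzero(covered)[0]
    if idx.size == 0:
        return None
    base_counts = np.array([(~y_is_target[idx]).sum(), y_is_target[idx].sum()])
    base_h = _entropy(base_counts)
    n_cov = idx.size
    best: tuple[float, int, float, str] | None = None  # (-gain, j, thr, op)
    for j in range(X.shape[1]):
        vals = np.unique(X[idx, j])
        if vals.size < 2:
            continue
        thresholds = (vals[:-1] + vals[1:]) / 2.0
        for thr in thresholds:
            left = X[idx, j] <= thr
            n_in = left.sum()
            if n_in == 0 or n_in == n_cov:
                continue
            yi = y_is_target[idx]
            in_counts = np.array([(~yi[left]).sum(), yi[left].sum()])
            out_counts = base_counts - in_counts
            h = (n_in * _entropy(in_counts) + (n_cov - n_in) * _entropy(out_counts)) / n_cov
            gain = base_h - h
            if gain <= 1e-12:
                continue
            # orientation: keep the side richer in the target class
            purity_left = in_counts[1] / n_in
            purity_right = out_counts[1] / (n_cov - n_in)
            op = "<=" if purity_left >= purity_right else ">"
            key = (-gain, j, float(thr), op)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    _, j, thr, op = best
    cond = Condition(feature_names[j], op, thr)
    if op == "<=":
        new_cov = covered & (X[:, j] <= thr)
    else:
        new_cov = covered & (X[:, j] > thr)
    return cond, new_cov


def _majority(y: np.ndarray) -> str:
    labels, counts = np.unique(y, return_counts=True)
    return str(labels[np.argmax(counts)])  # np.unique sorts: ties -> smallest label


def _grow_rule(
    X: np.ndarray,
    y: np.ndarray,
    default_label: str,
    feature_names: Sequence[str],
    max_literals: int,
) -> tuple[Rule, np.ndarray] | None:
    """Grow one exception rule against the current default."""
    errors = y != default_label
    if not errors.any():
        return None
    target = _majority(y[errors])
    y_is_target = y == target
    covered = np.ones(y.size, dtype=bool)
    conditions: list[Condition] = []
    while len(conditions) < max_literals:
        purity = y_is_target[covered].mean()
        if purity >= 1.0:
            break
        lit = _best_literal(X, y_is_target, covered, feature_names)
        if lit is None:
            break
        cond, new_cov = lit
        if y_is_target[new_cov].mean() <= purity + 1e-12:
            break
        conditions.append(cond)
        covered = new_cov
    if not conditions:
        return None
    purity = float(y_is_target[covered].mean())
    return Rule(tuple(conditions), target, purity), covered


def _grow_exceptions(
    X: np.ndarray,
    y: np.ndarray,
    default_label: str,
    feature_names: Sequence[str],
    depth: int,
    max_depth: int,
    max_literals: int,
) -> tuple[Rule, ...]:
    if depth >= max_depth or y.size == 0:
        return ()
    rules: list[Rule] = []
    pool = np.ones(y.size, dtype=bool)
    while True:
        err_before = (y[pool] != default_label).sum()
        if err_before == 0:
            break
        grown = _grow_rule(X[pool], y[pool], default_label, feature_names, max_literals)
        if grown is None:
            break
        rule, cov_local = grown
        pool_idx = np.nonzero(pool)[0]
        cov_global = np.zeros(y.size, dtype=bool)
        cov_global[pool_idx[cov_local]] = True
        # training error if rule is adopted (covered examples relabelled)
        err_after = (
            (y[pool & ~cov_global] != default_label).sum()
            + (y[cov_global] != rule.label).sum()
        )
        if err_after >= err_before:
            break
        exceptions = _grow_exceptions(
            X[cov_global],
            y[cov_global],
            rule.label,
            feature_names,
            depth + 1,
            max_depth,
            max_literals,
        )
        rules.append(Rule(rule.conditions, rule.label, rule.purity, exceptions))
        pool &= ~cov_global
    return tuple(rules)


def ridor_fit(
    features: Sequence[Mapping[str, float]],
    labels: Sequence[str],
    feature_names: Sequence[str] | None = None,
    seed: int = 0,
    max_depth: int = 5,
    max_literals: int = 3,
) -> RuleSet:
    """Induce a ripple-down rule set from labelled feature vectors.

    The induction itself is deterministic (greedy with fixed tie-breaks);
    ``seed`` is accepted for interface stability and reserved for future
    stochastic variants.  A single-class training set yields a default-only
    rule set.
    """
    if len(features) == 0:
        raise RidorError("empty training set")
    if len(features) != len(labels):
        raise RidorError("features and labels length mismatch")
    if feature_names is None:
        feature_names = tuple(features[0].keys())
    X = np.array([[float(fv[name]) for name in feature_names] for fv in features])
    if not np.all(np.isfinite(X)):
        raise RidorError("non-finite feature values")
    y = np.asarray([str(lab) for lab in labels])
    default = _majority(y)
    default_purity = float((y == default).mean())
    rules = _grow_exceptions(X, y, default, tuple(feature_names), 0, max_depth, max_literals)
    return RuleSet(default, default_purity, rules, tuple(feature_names))


def classify(features: Mapping[str, float], ruleset: RuleSet) -> tuple[str, float]:
    """Label a feature vector: the deepest matching exception rule wins.

    Depth ties are resolved in favour of the earliest sibling path; with no
    matching exception, the default label applies.  The score is the
    training purity of the deciding rule.
    """

    def deepest(rules: tuple[Rule, ...], depth: int) -> tuple[int, tuple[int, ...], str, float] | None:
        best = None
        for i, r in enumerate(rules):
            if not r.matches(features):
                continue
            sub = deepest(r.exceptions, depth + 1)
            cand = sub if sub is not None else (depth, (i,), r.label, r.purity)
            if sub is not None:
                cand = (sub[0], (i,) + sub[1], sub[2], sub[3])
            if best is None or (cand[0], tuple(-k for k in cand[1])) > (
                best[0],
                tuple(-k for k in best[1]),
            ):
                best = cand
        return best

    hit = deepest(ruleset.rules, 1)
    if hit is None:
        return ruleset.default_label, ruleset.default_purity
    return hit[2], hit[3]
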