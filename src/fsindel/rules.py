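"""Rule-based classification of frameshifting indels.

Contains the four published decision rules with their exact thresholds and
training counts, confidence-score arithmetic, coverage summaries, and
extraction of rule paths from a trained decision tree.

The four published rules do not partition feature space (they are the four
high-coverage paths of a larger twelve-rule tree whose remaining paths are
not public), so :func:`classify` takes a fallback policy for feature
vectors matched by no rule; the default is the conservative
``"gene-damaging"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .features import FEATURE_NAMES, FeatureVector
from .genome_model import LABEL_DAMAGING, LABEL_NEUTRAL

FALLBACK_POLICIES = (LABEL_DAMAGING, LABEL_NEUTRAL)
UNCOVERED = "uncovered"

_COMPARATORS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed confidences."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RuleCondition:
    feature: str
    comparator: str  # one of < <= > >=
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def matches(self, value: float) -> bool:
        return bool(_COMPARATORS[self.comparator](value, self.threshold))

    def __str__(self) -> str:
        return f"{self.feature} {self.comparator} {self.threshold:g}"


@dataclass
class RulePath:
    """A conjunction of threshold conditions with a label and training counts."""

    rule_id: str
    conditions: tuple[RuleCondition, ...]
    label: str
    n_covered: Optional[int] = None
    n_correct: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if self.label not in (LABEL_DAMAGING, LABEL_NEUTRAL):
            raise ValueError(f"unknown label {self.label!r}")
        if self.n_covered is not None and self.n_correct is not None:
            if not (0 <= self.n_correct <= self.n_covered):
                raise ValueError("need 0 <= n_correct <= n_covered")
        if not _satisfiable(self.conditions):
            raise ValueError(f"rule {self.rule_id}: conditions are unsatisfiable")

    @property
    def confidence(self) -> Optional[float]:
        if not self.n_covered:
            return None
        return rule_confidence(self.n_correct, self.n_covered)

    def matches(self, fv: FeatureVector) -> bool:
        for cond in self.conditions:
            if not fv.is_computable(cond.feature):
                raise ValueError(
                    f"rule {self.rule_id} needs feature {cond.feature!r} "
                    f"which is uncomputable for this indel"
                )
            if not cond.matches(fv.value(cond.feature)):
                return False
        return True


def _satisfiable(conditions: Sequence[RuleCondition]) -> bool:
    # interval intersection per feature; [lo, lo_strict, hi, hi_strict]
    bounds: dict[str, list] = {}
    for c in conditions:
        b = bounds.setdefault(c.feature, [-np.inf, False, np.inf, False])
        if c.comparator in ("<", "<="):
            if c.threshold < b[2] or (c.threshold == b[2] and c.comparator == "<"):
                b[2], b[3] = c.threshold, c.comparator == "<"
        else:
            if c.threshold > b[0] or (c.threshold == b[0] and c.comparator == ">"):
                b[0], b[1] = c.threshold, c.comparator == ">"
    for lo, lo_strict, hi, hi_strict in bounds.values():
        if lo > hi or (lo == hi and (lo_strict or hi_strict)):
            return False
    return True


@dataclass(frozen=True)
class Prediction:
    label: str
    rule_id: str
    confidence: Optional[float]


# ---------------------------------------------------------------------------
# the published ruleset
# ---------------------------------------------------------------------------

def published_ruleset() -> list[RulePath]:
    """The four printed rules with thresholds, counts and labels.

    R2's printed confidence (0.92) disagrees with its printed counts
    (118/129 = 0.91 after rounding); the printed value is kept as metadata
    while :attr:`RulePath.confidence` is always computed from the counts.
    """
    return [
        RulePath(
            rule_id="R1",
            conditions=(RuleCondition("f14", "<", 1.2),),
            label=LABEL_NEUTRAL,
            n_covered=687,
            n_correct=660,
        ),
        RulePath(
            rule_id="R2",
            conditions=(
                RuleCondition("f5", "<=", 85.5),
                RuleCondition("f14", "<=", 4.3),
            ),
            label=LABEL_NEUTRAL,
            n_covered=129,
            n_correct=118,
            metadata={"printed_confidence": 0.92},
        ),
        RulePath(
            rule_id="R3",
            conditions=(
                RuleCondition("f14", "<=", 4.3),
                RuleCondition("f18", "<=", 0.9),
                RuleCondition("f5", ">", 85.5),
            ),
            label=LABEL_NEUTRAL,
            n_covered=102,
            n_correct=83,
        ),
        RulePath(
            rule_id="R4",
            conditions=(
                RuleCondition("f14", ">", 6.2),
                RuleCondition("f18", ">", 0.9),
                RuleCondition("f5", ">", 8.7),
                RuleCondition("f15", ">", 6),
            ),
            label=LABEL_DAMAGING,
            n_covered=1193,
            n_correct=1024,
        ),
    ]


def rule_confidence(n_correct: int, n_covered: int) -> float:
    """Fraction of covered training samples the rule classifies correctly,
    rounded half-up to two decimals."""
    if n_covered <= 0:
        raise ValueError("n_covered must be > 0")
    if not (0 <= n_correct <= n_covered):
        raise ValueError("need 0 <= n_correct <= n_covered")
    return round_half_up(n_correct / n_covered, 2)


def classify(
    fv: FeatureVector,
    ruleset: Optional[Sequence[RulePath]] = None,
    fallback: str = LABEL_DAMAGING,
) -> Prediction:
    """First matching rule (in ruleset order) wins; unmatched vectors get the
    fallback label with rule_id="uncovered" and no confidence."""
    if ruleset is None:
        ruleset = published_ruleset()
    if fallback not in FALLBACK_POLICIES:
        raise ValueError(f"unknown fallback policy {fallback!r}")
    for rule in ruleset:
        if rule.matches(fv):
            return Prediction(label=rule.label, rule_id=rule.rule_id,
                              confidence=rule.confidence)
    return Prediction(label=fallback, rule_id=UNCOVERED, confidence=None)


def coverage_summary(
    ruleset: Sequence[RulePath],
    labeled: Optional[Sequence[tuple[FeatureVector, str]]] = None,
    class_totals: Optional[Mapping[str, int]] = None,
) -> dict[str, Optional[float]]:
    """Per-class percentage of examples correctly captured by same-label rules.

    Two modes: route a labeled dataset through the ruleset, or recompute
    from the rules' stored ``n_correct`` counts against supplied per-class
    totals.  Percentages are rounded half-up to one decimal; a class with
    no total (or no rule of its label) maps to None.
    """
    if (labeled is None) == (class_totals is None):
        raise ValueError("pass exactly one of labeled / class_totals")
    correct: dict[str, int] = {LABEL_DAMAGING: 0, LABEL_NEUTRAL: 0}
    totals: dict[str, int] = {LABEL_DAMAGING: 0, LABEL_NEUTRAL: 0}
    rule_labels = {r.label for r in ruleset}
    if labeled is not None:
        for fv, label in labeled:
            totals[label] += 1
            pred = classify(fv, ruleset, fallback=LABEL_DAMAGING)
            if pred.rule_id != UNCOVERED and pred.label == label:
                correct[label] += 1
    else:
        for r in ruleset:
            if r.n_correct is None:
                raise ValueError(f"rule {r.rule_id} has no stored counts")
            correct[r.label] += r.n_correct
        totals.update(class_totals)
    out: dict[str, Optional[float]] = {}
    for label in (LABEL_NEUTRAL, LABEL_DAMAGING):
        if totals[label] == 0 or label not in rule_labels:
            out[label] = None
        else:
            out[label] = round_half_up(100.0 * correct[label] / totals[label], 1)
    return out


# ---------------------------------------------------------------------------
# rule extraction from trees
# ---------------------------------------------------------------------------

def extract_rules(tree, X: np.ndarray, y: np.ndarray,
                  feature_names: Optional[Sequence[str]] = None) -> list[RulePath]:
    """One RulePath per leaf of a trained tree, with coverage counts obtained
    by routing the training rows; ordered by n_covered descending.

    ``tree`` is a :class:`fsindel.training.DecisionTree` (or anything with a
    compatible ``root``/``feature_names``).  Every training row lands in
    exactly one leaf, so coverage counts sum to ``len(y)``.
    """
    names = list(feature_names or tree.feature_names)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    paths: list[tuple[tuple[RuleCondition, ...], str]] = []

    def walk(node, conds: tuple[RuleCondition, ...]) -> None:
        if node.is_leaf:
            paths.append((conds, node.label))
            return
        fname = node.feature
        walk(node.left, conds + (RuleCondition(fname, "<=", node.threshold),))
        walk(node.right, conds + (RuleCondition(fname, ">", node.threshold),))

    if tree.root is None:
        return []
    walk(tree.root, ())

    col = {name: i for i, name in enumerate(names)}
    rules = []
    for conds, label in paths:
        mask = np.ones(len(X), dtype=bool)
        for c in conds:
            mask &= _COMPARATORS[c.comparator](X[:, col[c.feature]], c.threshold)
        n_covered = int(mask.sum())
        n_correct = int((y[mask] == label).sum())
        rules.append((conds, label, n_covered, n_correct))
    rules.sort(key=lambda r: -r[2])
    return [
        RulePath(rule_id=f"P{i + 1}", conditions=conds, label=label,
                 n_covered=nc, n_correct=ncr)
        for i, (conds, label, nc, ncr) in enumerate(rules)
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def ruleset_to_json(ruleset: Sequence[RulePath], path) -> None:
    payload = [
        {
            "rule_id": r.rule_id,
            "conditions": [
                {"feature": c.feature, "cmp": c.comparator, "threshold": c.threshold}
                for c in r.conditions
            ],
            "label": r.label,
            "n_covered": r.n_covered,
            "n_correct": r.n_correct,
            "confidence": r.confidence,
            "metadata": r.metadata,
        }
        for r in ruleset
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def ruleset_from_json(path) -> list[RulePath]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        RulePath(
            rule_id=d["rule_id"],
            conditions=tuple(
                RuleCondition(c["feature"], c["cmp"], c["threshold"])
                for c in d["conditions"]
            ),
            label=d["label"],
            n_covered=d.get("n_covered"),
            n_correct=d.get("n_correct"),
            metadata=d.get("metadata", {}),
        )
        for d in payload
    ]


def write_predictions(rows: Iterable[tuple[str, Prediction]], path) -> None:
    """TSV: indel_id, label, rule_id, confidence."""
    with open(path, "w") as fh:
        fh.write("indel_id\tlabel\trule_id\tconfidence\n")
        for indel_id, pred in rows:
            conf = "" if pred.confidence is None else f"{pred.confidence:.2f}"
            fh.write(f"{indel_id}\t{pred.label}\t{pred.rule_id}\t{conf}\n")
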