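"""Rule coverage counting and quality measures.

The central measure is the rule quality

    Q(R, w) = compl(R)^w * consig(R)^(1-w)

where ``compl(R) = p/P`` is the rule's completeness (recall at the rule
level) and

    consig(R) = ((p/(p+n)) - (P/(P+N))) * (P+N)/N

is the consistency gain: the precision improvement over guessing the class
prior, normalized so that a perfectly consistent rule (n = 0) scores exactly
1.  ``w`` in [0, 1] trades completeness against consistency; the default
0.3 mildly favors consistent rules.

A rule whose precision is below the class prior gains nothing; its
consistency gain is clamped to 0 (a negative base under a fractional power
is undefined), which makes Q = 0 for worse-than-chance rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

from .data_model import BinaryView, Condition, Dataset, Example, Rule, SchemaError

DEFAULT_WEIGHT = 0.3


class UndefinedMeasureError(ValueError):
    """A measure was requested outside its domain (e.g. P = 0)."""


@dataclass(frozen=True)
class CoverageStats:
    """Coverage counts of one rule on one binarized dataset."""

    p: int
    n: int
    P: int
    N: int

    def __post_init__(self):
        if not (0 <= self.p <= self.P and 0 <= self.n <= self.N):
            raise ValueError(f"inconsistent coverage counts {self}")
        if self.P + self.N <= 0:
            raise ValueError("empty dataset")


def completeness(stats: CoverageStats) -> float:
    """p / P: the fraction of all positives the rule covers."""
    if stats.P == 0:
        raise UndefinedMeasureError("completeness undefined with no positive examples")
    return stats.p / stats.P


def consistency_gain(stats: CoverageStats) -> float:
    """Normalized precision gain over the class prior, clamped below at 0."""
    if stats.N == 0:
        raise UndefinedMeasureError("consistency gain undefined with no negative examples")
    if stats.p + stats.n == 0:
        raise UndefinedMeasureError("consistency gain undefined for an empty-coverage rule")
    total = stats.P + stats.N
    value = ((stats.p / (stats.p + stats.n)) - (stats.P / total)) * total / stats.N
    return max(value, 0.0)


def rule_quality(stats: CoverageStats, weight: float = DEFAULT_WEIGHT) -> float:
    """Q(R, w) = compl^w * consig^(1-w); w=1 is completeness, w=0 consistency gain."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    compl = completeness(stats)
    consig = consistency_gain(stats)
    if weight == 1.0:
        return compl
    if weight == 0.0:
        return consig
    if compl == 0.0 or consig == 0.0:
        return 0.0
    return compl ** weight * consig ** (1.0 - weight)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(stats: CoverageStats) -> tuple:
    if stats.P == 0:
        raise UndefinedMeasureError("recall undefined with no positive examples")
    precision = stats.p / (stats.p + stats.n) if stats.p + stats.n else 0.0
    recall = stats.p / stats.P
    return precision, recall, f1_score(precision, recall)


def prevalence_pct(p_cond: int, n_cond: int) -> int:
    """Integer positive-class prevalence, truncated: floor(100 * p / (p+n)).

    Truncation (not rounding) matches the annotation convention of the rule
    text dialect, e.g. 30/(30+34) = 46.9% prints as 46%.
    """
    if p_cond + n_cond <= 0:
        raise UndefinedMeasureError("prevalence undefined for empty coverage")
    return math.floor(100 * p_cond / (p_cond + n_cond))


# --------------------------------------------------------------------------
# Coverage semantics


def _condition_matches(condition: Condition, value, missing_token, hierarchy) -> bool:
    if value is None or value == missing_token:
        return False
    if condition.mode == "set":
        return value in condition.allowed
    if condition.mode == "interval":
        try:
            v = float(value)
        except (TypeError, ValueError):
            return False
        lo, hi = condition.allowed
        return lo <= v <= hi
    # closure semantics over an IS-A hierarchy
    if hierarchy is None:
        raise SchemaError(f"hierarchy required to evaluate condition on {condition.attribute!r}")
    return value in hierarchy.closure(condition.allowed)


def covers(rule_or_condition, example: Example, schema, hierarchies: Optional[Mapping] = None) -> bool:
    """Does a condition (or every condition of a rule) match the example?

    A missing value never matches.
    """
    by_name = {a.name: a for a in schema}
    conditions = (
        rule_or_condition.premise if isinstance(rule_or_condition, Rule) else [rule_or_condition]
    )
    for cond in conditions:
        attr = by_name.get(cond.attribute)
        if attr is None:
            raise SchemaError(f"condition on unknown attribute {cond.attribute!r}")
        hier = None
        if attr.kind == "hierarchical" and hierarchies is not None:
            hier = hierarchies.get(attr.domain)
        value = example.values.get(cond.attribute)
        if not _condition_matches(cond, value, attr.missing_token, hier):
            return False
    return True


class CoverageEngine:
    """Vectorized coverage counting over one dataset.

    Example sets are represented as Python integer bitmasks (bit i set iff
    example i matches), which makes conjunction an ``&`` and counting a
    ``bit_count()`` -- fast enough to drive beam search over hundreds of
    candidate rules.
    """

    def __init__(self, dataset: Dataset, hierarchies: Optional[Mapping] = None):
        self.dataset = dataset
        self.hierarchies = dict(hierarchies or {})
        self.size = len(dataset.examples)
        self.full_mask = (1 << self.size) - 1
        self._attrs = {a.name: a for a in dataset.schema}
        self._values = {
            a.name: [ex.values.get(a.name) for ex in dataset.examples]
            for a in dataset.input_attributes
        }
        self._cond_cache: dict = {}
        self._label_cache: dict = {}

    def hierarchy_for(self, attr_name: str):
        attr = self._attrs[attr_name]
        if attr.kind != "hierarchical":
            return None
        hier = self.hierarchies.get(attr.domain)
        if hier is None:
            raise SchemaError(f"hierarchy {attr.domain!r} not provided for attribute {attr_name!r}")
        return hier

    def label_mask(self, target_class: str) -> int:
        mask = self._label_cache.get(target_class)
        if mask is None:
            mask = 0
            for i, ex in enumerate(self.dataset.examples):
                if ex.label == target_class:
                    mask |= 1 << i
            self._label_cache[target_class] = mask
        return mask

    def condition_mask(self, condition: Condition) -> int:
        key = condition.signature()
        mask = self._cond_cache.get(key)
        if mask is not None:
            return mask
        attr = self._attrs.get(condition.attribute)
        if attr is None:
            raise SchemaError(f"condition on unknown attribute {condition.attribute!r}")
        values = self._values[condition.attribute]
        missing = attr.missing_token
        mask = 0
        if condition.mode == "set":
            allowed = condition.allowed
            for i, v in enumerate(values):
                if v is not None and v != missing and v in allowed:
                    mask |= 1 << i
        elif condition.mode == "interval":
            lo, hi = condition.allowed
            for i, v in enumerate(values):
                if v is None or v == missing:
                    continue
                try:
                    x = float(v)
                except (TypeError, ValueError):
                    continue
                if lo <= x <= hi:
                    mask |= 1 << i
        else:
            extent = self.hierarchy_for(condition.attribute).closure(condition.allowed)
            for i, v in enumerate(values):
                if v is not None and v != missing and v in extent:
                    mask |= 1 << i
        self._cond_cache[key] = mask
        return mask

    def rule_mask(self, rule_or_premise) -> int:
        premise = rule_or_premise.premise if isinstance(rule_or_premise, Rule) else rule_or_premise
        mask = self.full_mask
        for cond in premise:
            mask &= self.condition_mask(cond)
            if not mask:
                return 0
        return mask

    def stats_from_mask(self, mask: int, target_class: str) -> CoverageStats:
        pos = self.label_mask(target_class)
        P = pos.bit_count()
        return CoverageStats(
            p=(mask & pos).bit_count(),
            n=(mask & ~pos & self.full_mask).bit_count(),
            P=P,
            N=self.size - P,
        )

    def ids_from_mask(self, mask: int) -> list:
        return [ex.id for i, ex in enumerate(self.dataset.examples) if mask >> i & 1]


def count_coverage(
    rule: Rule,
    dataset,
    hierarchies: Optional[Mapping] = None,
    engine: Optional[CoverageEngine] = None,
    weight: Optional[float] = None,
) -> CoverageStats:
    """Count p/n for the rule and annotate each condition in place.

    Each condition's annotation is the coverage of that single condition
    alone: ``(p_cond, n_cond, prevalence_pct)``.  The rule's ``p``, ``n``
    and ``q`` fields are refreshed.
    """
    if isinstance(dataset, BinaryView):
        dataset = dataset.dataset
    if engine is None:
        engine = CoverageEngine(dataset, hierarchies)
    pos = engine.label_mask(rule.consequent)
    for cond in rule.premise:
        cmask = engine.condition_mask(cond)
        pc = (cmask & pos).bit_count()
        nc = (cmask & ~pos & engine.full_mask).bit_count()
        cond.annotation = (pc, nc, prevalence_pct(pc, nc) if pc + nc else None)
    stats = engine.stats_from_mask(engine.rule_mask(rule), rule.consequent)
    rule.p, rule.n = stats.p, stats.n
    if weight is not None:
        rule.w_used = weight
    try:
        rule.q = rule_quality(stats, rule.w_used)
    except UndefinedMeasureError:
        rule.q = 0.0
    return stats
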