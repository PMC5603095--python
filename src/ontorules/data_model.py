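"""Core typed vocabulary: attributes, examples, datasets, conditions, rules.

Attributes come in five kinds:

* ``nominal`` -- unordered categorical with an explicit, finite domain;
* ``numeric`` -- real-valued, optionally bounded;
* ``hierarchical`` -- values are node identifiers of an IS-A concept
  hierarchy (UMLS-style CUIs, ICD chapters, toy ontologies alike);
* ``id`` -- a stable example identifier, never used in conditions;
* ``output`` -- the class attribute (exactly one per schema).

A :class:`Condition` restricts one attribute.  Its ``mode`` determines the
match semantics:

* ``set``    -- exact membership of the example's value in ``allowed``;
* ``interval`` -- ``allowed`` is a closed interval ``(lo, hi)``;
* ``closure``  -- the value matches if it lies in the descendant-or-self
  closure of ``allowed`` within the attribute's hierarchy.

Conditions never match a missing value (conservative convention: an
unanswered survey item can neither support nor refute a condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

ATTRIBUTE_KINDS = ("nominal", "numeric", "hierarchical", "id", "output")

#: Default token standing for an unknown / unanswered value.
DEFAULT_MISSING = "?"


class SchemaError(ValueError):
    """Raised when a schema or value violates its declared contract."""


@dataclass(frozen=True)
class AttributeSpec:
    """Declaration of a single column.

    ``domain`` is interpreted per ``kind``: an ordered tuple of legal tokens
    for nominal/output attributes, a ``(low, high)`` pair (either may be
    infinite) for numeric ones, and the identifier of the hierarchy the
    values are drawn from for hierarchical ones.
    """

    name: str
    kind: str
    domain: object = None
    missing_token: str = DEFAULT_MISSING

    def __post_init__(self):
        if self.kind not in ATTRIBUTE_KINDS:
            raise SchemaError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.kind in ("nominal", "output"):
            values = tuple(self.domain or ())
            if len(set(values)) != len(values):
                raise SchemaError(f"duplicate domain values in {self.name!r}")
            object.__setattr__(self, "domain", values)
        elif self.kind == "numeric":
            lo, hi = self.domain if self.domain is not None else (-math.inf, math.inf)
            object.__setattr__(self, "domain", (float(lo), float(hi)))

    @property
    def is_input(self) -> bool:
        return self.kind in ("nominal", "numeric", "hierarchical")


@dataclass
class Example:
    """One labeled observation: a value per attribute plus the class token."""

    id: str
    values: dict
    label: str


def _check_schema(schema: Sequence[AttributeSpec]) -> None:
    names = [a.name for a in schema]
    if len(set(names)) != len(names):
        raise SchemaError("attribute names must be unique within a schema")
    outputs = [a for a in schema if a.kind == "output"]
    if len(outputs) != 1:
        raise SchemaError(f"schema needs exactly one output attribute, found {len(outputs)}")


@dataclass
class Dataset:
    """A schema plus labeled examples.

    ``class_totals`` is derived; for a chosen target class ``c``,
    ``P = class_totals[c]`` and ``N = len(examples) - P``.
    """

    schema: list
    examples: list

    def __post_init__(self):
        _check_schema(self.schema)

    @property
    def output_attribute(self) -> AttributeSpec:
        return next(a for a in self.schema if a.kind == "output")

    @property
    def input_attributes(self) -> list:
        return [a for a in self.schema if a.is_input]

    @property
    def id_attribute(self) -> Optional[AttributeSpec]:
        return next((a for a in self.schema if a.kind == "id"), None)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.schema:
            if a.name == name:
                return a
        raise SchemaError(f"no attribute named {name!r}")

    @property
    def class_totals(self) -> dict:
        totals = {c: 0 for c in self.output_attribute.domain}
        for ex in self.examples:
            totals[ex.label] = totals.get(ex.label, 0) + 1
        return totals

    def with_examples(self, examples: Iterable[Example]) -> "Dataset":
        return Dataset(schema=self.schema, examples=list(examples))


@dataclass
class BinaryView:
    """A dataset re-read one-vs-rest for a single target class."""

    dataset: Dataset
    target_class: str
    P: int
    N: int

    @property
    def examples(self):
        return self.dataset.examples

    def is_positive(self, example: Example) -> bool:
        return example.label == self.target_class


def binarize(dataset: Dataset, target_class: str) -> BinaryView:
    """One-vs-rest framing: P positives of ``target_class``, N all others."""
    legal = dataset.output_attribute.domain
    if target_class not in legal:
        raise SchemaError(
            f"unknown class {target_class!r}; legal classes: {', '.join(legal)}"
        )
    P = sum(1 for ex in dataset.examples if ex.label == target_class)
    return BinaryView(dataset=dataset, target_class=target_class, P=P, N=len(dataset.examples) - P)


@dataclass(frozen=True)
class Violation:
    example_id: str
    attribute: str
    reason: str


def validate_dataset(dataset: Dataset, hierarchies: Optional[Mapping] = None) -> list:
    """Report every example whose values fall outside the declared domains.

    Returns an empty list iff the dataset is clean; never raises.
    """
    out_attr = dataset.output_attribute
    violations = []
    for ex in dataset.examples:
        if ex.label not in out_attr.domain:
            violations.append(Violation(ex.id, out_attr.name, f"label {ex.label!r} not in output domain"))
        for attr in dataset.input_attributes:
            value = ex.values.get(attr.name, attr.missing_token)
            if value == attr.missing_token or value is None:
                continue
            if attr.kind == "nominal":
                if value not in attr.domain:
                    violations.append(Violation(ex.id, attr.name, f"value {value!r} not in nominal domain"))
            elif attr.kind == "numeric":
                try:
                    v = float(value)
                except (TypeError, ValueError):
                    violations.append(Violation(ex.id, attr.name, f"value {value!r} is not numeric"))
                    continue
                lo, hi = attr.domain
                if not (lo <= v <= hi):
                    violations.append(Violation(ex.id, attr.name, f"value {v} outside [{lo}, {hi}]"))
            elif attr.kind == "hierarchical" and hierarchies is not None:
                hier = hierarchies.get(attr.domain)
                if hier is None:
                    violations.append(Violation(ex.id, attr.name, f"hierarchy {attr.domain!r} not provided"))
                elif value not in hier.nodes:
                    violations.append(Violation(ex.id, attr.name, f"value {value!r} is not a node of hierarchy {attr.domain!r}"))
    return violations


# --------------------------------------------------------------------------
# Conditions and rules


@dataclass
class Condition:
    """A single attributional condition (one attribute, one value region)."""

    attribute: str
    allowed: object  # frozenset for set/closure, (lo, hi) for interval
    mode: str = "set"  # set | interval | closure
    #: (p_cond, n_cond, prevalence_pct) filled by coverage counting.
    annotation: Optional[tuple] = None

    def __post_init__(self):
        if self.mode not in ("set", "interval", "closure"):
            raise SchemaError(f"unknown condition mode {self.mode!r}")
        if self.mode == "interval":
            lo, hi = self.allowed
            if lo > hi:
                raise SchemaError("empty interval condition")
            self.allowed = (float(lo), float(hi))
        else:
            allowed = frozenset(self.allowed)
            if not allowed:
                raise SchemaError("condition with empty allowed set")
            self.allowed = allowed

    def signature(self):
        if self.mode == "interval":
            return (self.attribute, self.mode, self.allowed)
        return (self.attribute, self.mode, frozenset(self.allowed))


def antichain(nodes: Iterable[str], hierarchy) -> frozenset:
    """Drop every node that is a descendant of another listed node."""
    nodes = set(nodes)
    keep = set()
    for node in nodes:
        if not (hierarchy.ancestors(node) & nodes):
            keep.add(node)
    return frozenset(keep)


def make_condition(
    attr: AttributeSpec,
    allowed,
    hierarchy=None,
    mode: Optional[str] = None,
) -> Optional[Condition]:
    """Build a normalized condition, or ``None`` if it is vacuous.

    A condition whose allowed region equals the attribute's full domain
    constrains nothing and is dropped.  Hierarchical value sets are reduced
    to antichain normal form (no member an ancestor of another).
    """
    if attr.kind == "numeric":
        lo, hi = allowed
        dlo, dhi = attr.domain
        if lo <= dlo and hi >= dhi:
            return None
        return Condition(attr.name, (max(lo, dlo), min(hi, dhi)), mode="interval")
    if attr.kind == "hierarchical" and (mode is None or mode == "closure"):
        if hierarchy is None:
            raise SchemaError(f"hierarchy required for attribute {attr.name!r}")
        normal = antichain(allowed, hierarchy)
        if hierarchy.closure(normal) == hierarchy.nodes:
            return None
        return Condition(attr.name, normal, mode="closure")
    allowed = frozenset(allowed)
    if attr.kind in ("nominal", "output") and set(attr.domain) == allowed:
        return None
    return Condition(attr.name, allowed, mode="set")


@dataclass
class Rule:
    """An attributional rule with optional exceptions.

    ``CONSEQUENT <= PREMISE |_ EXCEPTION``: the premise is a conjunction of
    conditions; exceptions list the identifiers of covered negative
    examples.  ``p``/``n`` are raw coverage counts (exceptions annotate,
    they do not alter counting) and ``q`` is the quality Q(R, w) the rule
    was scored with.
    """

    consequent: str
    premise: list
    exception_ids: list = field(default_factory=list)
    p: int = 0
    n: int = 0
    q: float = 0.0
    w_used: float = 0.3

    def signature(self):
        return (self.consequent, frozenset(c.signature() for c in self.premise))

    def copy(self) -> "Rule":
        return Rule(
            consequent=self.consequent,
            premise=[replace(c) for c in self.premise],
            exception_ids=list(self.exception_ids),
            p=self.p,
            n=self.n,
            q=self.q,
            w_used=self.w_used,
        )


@dataclass
class Model:
    """Per-class rule lists plus everything needed to replay the run."""

    rules: dict  # class -> list[Rule], descending q
    schema: list
    config: object
    majority_class: str
    class_totals: dict
    provenance: dict = field(default_factory=dict)

    def all_rules(self):
        for cls in self.rules:
            yield from self.rules[cls]

    def sort_rules(self):
        for cls in self.rules:
            self.rules[cls].sort(key=lambda r: -r.q)
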