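"""Synthetic clinical cohorts with planted hierarchical rule structure.

The generator emulates the shape of a linked cancer-registry / health-survey
cohort: roughly 700 patients, a binary functional outcome at 4-20%
prevalence, a handful of demographic nominals, thirteen binary comorbidity
flags, and several tumor attributes (site, histology, morphology) coded as
leaves of multi-level, possibly multi-parent IS-A hierarchies.

Labels are produced by *planted rules* whose hierarchical conditions sit at
internal hierarchy nodes.  An ontology-blind learner therefore has to
enumerate leaf codes to describe the concept, while an ontology-guided one
can name the internal node directly -- which is exactly the signal the
generalization machinery is supposed to exploit.  Optional label noise
flips each outcome independently.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .data_model import (
    AttributeSpec,
    Condition,
    Dataset,
    Example,
    Model,
    Rule,
    validate_dataset,
)
from .hierarchy import EdgeList, Hierarchy, sanitize

POSITIVE_CLASS = "impaired"
NEGATIVE_CLASS = "independent"

#: Outcome prevalences cycled over tasks; modeled on post-diagnosis ADL
#: disability rates (bathing 12%, chairing 16%, dressing 8%, eating 4%,
#: walking 20%, toileting 7%).
TASK_PREVALENCES = (0.12, 0.16, 0.08, 0.04, 0.20, 0.07)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic cohort.

    ``prevalence`` targets the fraction of examples fired by a planted rule
    (before label noise); ``noise_rate`` then flips each label
    independently.  Hierarchies are generated with the given depth,
    branching, and fraction of two-parent nodes.
    """

    n_examples: int = 723
    prevalence: float = 0.12
    n_nominal: int = 3
    n_comorbidities: int = 13
    n_hierarchical: int = 3
    hierarchy_depth: int = 3
    hierarchy_branching: int = 3
    multi_parent_fraction: float = 0.1
    noise_rate: float = 0.0
    planted_level: int = 1
    planted_rules: Optional[list] = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise rate must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the rules, which rule fired per example, and
    which labels were flipped by noise."""

    planted_rules: list
    fired: dict = field(default_factory=dict)  # example id -> rule index or None
    noise_flags: dict = field(default_factory=dict)  # example id -> bool


class SyntheticCohort(NamedTuple):
    dataset: Dataset
    hierarchies: dict
    truth: SyntheticTruth


def make_random_hierarchy(depth: int, branching: int, multi_parent_fraction: float,
                          rng, prefix: str = "H") -> Hierarchy:
    """A rooted DAG: a complete ``branching``-ary tree of the given depth in
    which a fraction of nodes below level 1 receive a second parent drawn
    from the previous level."""
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    if not (0.0 <= multi_parent_fraction <= 1.0):
        raise ValueError("multi_parent_fraction must lie in [0, 1]")
    root = f"{prefix}:ROOT"
    levels = [[root]]
    pairs = []
    for level in range(1, depth + 1):
        prev = levels[-1]
        count = len(prev) * branching
        nodes = [f"{prefix}:L{level}N{i:04d}" for i in range(count)]
        for i, node in enumerate(nodes):
            primary = prev[i // branching]
            pairs.append((primary, node))
            if len(prev) > 1 and rng.random() < multi_parent_fraction:
                others = [p for p in prev if p != primary]
                second = others[int(rng.integers(len(others)))]
                pairs.append((second, node))
        levels.append(nodes)
    return sanitize(EdgeList(pairs=pairs))


# --------------------------------------------------------------------------
# Schema assembly

_NOMINALS = [
    ("race", ("White", "Black", "Chinese", "Other"), (0.70, 0.15, 0.05, 0.10)),
    ("hispanic", ("No", "Yes"), (0.90, 0.10)),
    ("marital", ("Married", "Widowed", "Single", "Divorced"), (0.55, 0.25, 0.10, 0.10)),
]

_HIER_NAMES = ("tumor_site", "histology", "morphology")


def _comorbidity_prob(index: int) -> float:
    # Declining prevalences, roughly 60% down to 12% across thirteen flags.
    return max(0.6 - 0.04 * index, 0.05)


def _build_schema(spec: SyntheticSpec) -> list:
    schema = [AttributeSpec(name="patient_id", kind="id")]
    for k in range(spec.n_nominal):
        if k < len(_NOMINALS):
            name, domain, _ = _NOMINALS[k]
        else:
            name, domain = f"nominal{k:02d}", ("a", "b", "c")
        schema.append(AttributeSpec(name=name, kind="nominal", domain=domain))
    for k in range(spec.n_comorbidities):
        schema.append(AttributeSpec(name=f"comorb{k:02d}", kind="nominal", domain=("No", "Yes")))
    for k in range(spec.n_hierarchical):
        name = _HIER_NAMES[k] if k < len(_HIER_NAMES) else f"hier{k:02d}"
        schema.append(AttributeSpec(name=name, kind="hierarchical", domain=f"{name}_hierarchy"))
    schema.append(AttributeSpec(name="adl", kind="output",
                                domain=(NEGATIVE_CLASS, POSITIVE_CLASS)))
    return schema


def _nominal_sampler(spec: SyntheticSpec):
    tables = {}
    for k in range(spec.n_nominal):
        if k < len(_NOMINALS):
            name, domain, probs = _NOMINALS[k]
        else:
            name, domain, probs = f"nominal{k:02d}", ("a", "b", "c"), (1 / 3, 1 / 3, 1 / 3)
        tables[name] = (list(domain), list(probs))
    return tables


def default_planted_rule(spec: SyntheticSpec, hierarchies: dict, schema, rng) -> Rule:
    """One conjunctive rule: an internal node of the first hierarchy plus a
    mid-prevalence comorbidity flag."""
    hier_attr = next(a for a in schema if a.kind == "hierarchical")
    hier = hierarchies[hier_attr.domain]
    level_nodes = sorted(n for n in hier.nodes if hier.depth[n] == spec.planted_level)
    node = level_nodes[int(rng.integers(len(level_nodes)))]
    flag_index = int(rng.integers(min(6, spec.n_comorbidities)))
    return Rule(
        consequent=POSITIVE_CLASS,
        premise=[
            Condition(hier_attr.name, frozenset({node}), mode="closure"),
            Condition(f"comorb{flag_index:02d}", frozenset({"Yes"}), mode="set"),
        ],
    )


def _rule_fires(rule: Rule, values: dict, hierarchies: dict, schema_by_name) -> bool:
    for cond in rule.premise:
        v = values.get(cond.attribute)
        if v is None:
            return False
        if cond.mode == "closure":
            hier = hierarchies[schema_by_name[cond.attribute].domain]
            if v not in hier.closure(cond.allowed):
                return False
        else:
            if v not in cond.allowed:
                return False
    return True


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Sample a cohort whose positives are exactly the planted-rule firings
    (then label-flipped at the noise rate).

    The number of fired examples is pinned to ``round(n * prevalence)`` by
    rejection sampling over whole rows, capped at 100 x n draws.
    """
    rng = np.random.default_rng(spec.seed)
    hierarchies = {}
    for k in range(spec.n_hierarchical):
        name = _HIER_NAMES[k] if k < len(_HIER_NAMES) else f"hier{k:02d}"
        hierarchies[f"{name}_hierarchy"] = make_random_hierarchy(
            spec.hierarchy_depth, spec.hierarchy_branching,
            spec.multi_parent_fraction, rng, prefix=name[:4].upper(),
        )
    schema = _build_schema(spec)
    schema_by_name = {a.name: a for a in schema}
    planted = spec.planted_rules or [default_planted_rule(spec, hierarchies, schema, rng)]

    nominal_tables = _nominal_sampler(spec)
    hier_leaves = {
        hid: sorted(h.leaves()) for hid, h in hierarchies.items()
    }
    comorb_probs = [_comorbidity_prob(k) for k in range(spec.n_comorbidities)]

    def draw_row() -> dict:
        values = {}
        for name, (domain, probs) in nominal_tables.items():
            values[name] = domain[int(rng.choice(len(domain), p=probs))]
        for k in range(spec.n_comorbidities):
            values[f"comorb{k:02d}"] = "Yes" if rng.random() < comorb_probs[k] else "No"
        for attr in schema:
            if attr.kind == "hierarchical":
                leaves = hier_leaves[attr.domain]
                values[attr.name] = leaves[int(rng.integers(len(leaves)))]
        return values

    n = spec.n_examples
    want_fired = int(round(n * spec.prevalence))
    if not (0 < want_fired < n):
        raise ValueError("prevalence target leaves no examples of one class")
    fired_rows, quiet_rows = [], []
    draws = 0
    while (len(fired_rows) < want_fired or len(quiet_rows) < n - want_fired):
        if draws >= 100 * n:
            raise ValueError(
                "could not reach the target prevalence within 100 x n draws; "
                "planted-rule closures are too small or too large for it"
            )
        draws += 1
        values = draw_row()
        which = None
        for ri, rule in enumerate(planted):
            if _rule_fires(rule, values, hierarchies, schema_by_name):
                which = ri
                break
        if which is not None and len(fired_rows) < want_fired:
            fired_rows.append((values, which))
        elif which is None and len(quiet_rows) < n - want_fired:
            quiet_rows.append((values, None))

    rows = fired_rows + quiet_rows
    order = rng.permutation(len(rows))
    truth = SyntheticTruth(planted_rules=planted)
    examples = []
    for new_index, old_index in enumerate(order):
        values, which = rows[old_index]
        ex_id = f"pt{new_index:04d}"
        label = POSITIVE_CLASS if which is not None else NEGATIVE_CLASS
        flipped = bool(rng.random() < spec.noise_rate)
        if flipped:
            label = NEGATIVE_CLASS if label == POSITIVE_CLASS else POSITIVE_CLASS
        truth.fired[ex_id] = which
        truth.noise_flags[ex_id] = flipped
        examples.append(Example(id=ex_id, values=dict(values), label=label))

    dataset = Dataset(schema=schema, examples=examples)
    assert validate_dataset(dataset, hierarchies) == []
    return SyntheticCohort(dataset=dataset, hierarchies=hierarchies, truth=truth)


# --------------------------------------------------------------------------
# Recovery scoring


def _condition_extent(cond: Optional[Condition], attr: AttributeSpec, hierarchies: dict):
    """The set of concrete attribute values a condition admits.

    Hierarchical extents are closures restricted to leaves (the values that
    occur in generated data), so a leaf enumeration and its internal-node
    generalization compare as equal when they admit the same codes.
    """
    if attr.kind == "hierarchical":
        hier = hierarchies[attr.domain]
        leaves = hier.leaves()
        if cond is None:
            return leaves
        return hier.closure(cond.allowed) & leaves
    if cond is None:
        return frozenset(attr.domain)
    return frozenset(cond.allowed)


def _premise_similarity(learned: Rule, planted: Rule, schema_by_name, hierarchies) -> float:
    attrs = {c.attribute for c in learned.premise} | {c.attribute for c in planted.premise}
    if not attrs:
        return 1.0
    scores = []
    for name in sorted(attrs):
        attr = schema_by_name[name]
        lc = next((c for c in learned.premise if c.attribute == name), None)
        pc = next((c for c in planted.premise if c.attribute == name), None)
        le = _condition_extent(lc, attr, hierarchies)
        pe = _condition_extent(pc, attr, hierarchies)
        union = le | pe
        scores.append(len(le & pe) / len(union) if union else 1.0)
    return float(np.mean(scores))


def recovery_score(model: Model, truth: SyntheticTruth, hierarchies: dict) -> float:
    """Mean, over planted rules, of the best per-attribute closure Jaccard
    against any learned rule of the same consequent.  1.0 iff every planted
    rule is recovered up to closure equality; 0.0 for an empty model."""
    schema_by_name = {a.name: a for a in model.schema}
    scores = []
    for planted in truth.planted_rules:
        learned_rules = model.rules.get(planted.consequent, [])
        if not learned_rules:
            scores.append(0.0)
            continue
        scores.append(
            max(
                _premise_similarity(lr, planted, schema_by_name, hierarchies)
                for lr in learned_rules
            )
        )
    return float(np.mean(scores)) if scores else 0.0


# --------------------------------------------------------------------------
# Multi-task suites


class Task(NamedTuple):
    label: str
    cohort: SyntheticCohort
    target_class: str


def generate_task_suite(
    n_tasks: int = 6,
    seed: int = 0,
    noise_rate: float = 0.05,
    n_examples: int = 723,
) -> list:
    """Independent cohorts emulating a battery of binary outcome tasks.

    Prevalences cycle through :data:`TASK_PREVALENCES`; planted rules
    alternate between level-1 and level-2 hierarchy nodes so tasks differ
    in how much generalization the concept demands.
    """
    master = np.random.default_rng(seed)
    child_seeds = [int(master.integers(2**31)) for _ in range(n_tasks)]
    tasks = []
    for t in range(n_tasks):
        spec = SyntheticSpec(
            n_examples=n_examples,
            prevalence=TASK_PREVALENCES[t % len(TASK_PREVALENCES)],
            noise_rate=noise_rate,
            planted_level=1 + t % 2,
            seed=child_seeds[t],
        )
        tasks.append(Task(label=f"task{t + 1}", cohort=generate_cohort(spec),
                          target_class=POSITIVE_CLASS))
    return tasks
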