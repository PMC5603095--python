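"""AQ-style sequential-covering rule induction.

The engine repeatedly picks an uncovered positive example (the *seed*),
grows a *star* -- a bounded beam of maximally general candidate rules that
cover the seed -- by extending the seed against covered negatives one at a
time, keeps the best rule of the star, and marks its positives covered.

The extension-against operator emits, per attribute on which seed and
negative differ, the most general condition that covers the seed and
excludes the negative:

* nominal   -- the full domain minus the negative's value;
* numeric   -- the half-interval on the seed's side of the midpoint;
* hierarchical -- the maximal hierarchy nodes (closest to a root) whose
  descendant-or-self closure contains the seed's value but not the
  negative's.

With ``generalization_mode='off'`` the learner is deliberately
ontology-blind: hierarchical attributes are treated as flat nominal codes
over the values observed in the data, which is how a standard attributional
learner sees, say, a column of ICD or CUI codes.  Any other mode switches
the extension operator to closure semantics, and a post-learning
generalization pass (see :mod:`ontorules.ontology_generalization`) climbs
the hierarchies further.

Candidate rules are ranked lexicographically: higher Q(R, w) first, then
fewer conditions, then earlier creation.  When a candidate is specialized
against a negative, the unspecialized parent stays in the pool (it may
still win on quality if tolerating that negative is the better trade) --
this realizes rules that "approximately" exclude the negatives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .data_model import (
    AttributeSpec,
    BinaryView,
    Condition,
    Dataset,
    Example,
    Model,
    Rule,
    binarize,
)
from .quality import (
    DEFAULT_WEIGHT,
    CoverageEngine,
    count_coverage,
    covers,
    rule_quality,
)


@dataclass
class LearnerConfig:
    """All knobs of a learning run.

    ``consistency_tolerance`` is the number of negatives a rule may cover
    before the star stops specializing it (0 = demand fully consistent
    rules; covered negatives always end up as exceptions either way).
    ``generalization_mode`` is one of ``off`` (ontology-blind),
    ``strict`` (climb hierarchies as long as no new negative is admitted)
    or ``quality`` (climb while Q does not decrease).
    """

    w: float = DEFAULT_WEIGHT
    beam_width: int = 5
    max_rules_per_class: int = 10
    consistency_tolerance: int = 0
    generalization_mode: str = "off"
    rng_seed: int = 0
    discretize_bins: Optional[dict] = None

    def __post_init__(self):
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.generalization_mode not in ("off", "strict", "quality"):
            raise ValueError(f"unknown generalization_mode {self.generalization_mode!r}")


# --------------------------------------------------------------------------
# Preprocessing


def remove_ambiguous(dataset: Dataset):
    """Drop every group of input-identical examples whose labels disagree."""
    input_names = [a.name for a in dataset.input_attributes]
    groups: dict = {}
    for ex in dataset.examples:
        key = tuple(ex.values.get(name) for name in input_names)
        groups.setdefault(key, []).append(ex)
    removed = []
    kept = []
    for ex in dataset.examples:
        key = tuple(ex.values.get(name) for name in input_names)
        labels = {e.label for e in groups[key]}
        if len(labels) > 1:
            removed.append(ex.id)
        else:
            kept.append(ex)
    return dataset.with_examples(kept), removed


def discretize_equal_frequency(dataset: Dataset, attribute: str, k: int):
    """Replace a numeric attribute by ordinal bins of near-equal occupancy.

    Ties can merge quantile boundaries, so the result may have fewer than
    ``k`` bins.  Returns the new dataset and the bin boundaries used.
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    attr = dataset.attribute(attribute)
    if attr.kind != "numeric":
        raise ValueError(f"attribute {attribute!r} is not numeric")
    raw = [ex.values.get(attribute) for ex in dataset.examples]
    numeric = pd.Series(
        [float(v) if v not in (None, attr.missing_token) else np.nan for v in raw]
    )
    clean = numeric.dropna()
    if clean.nunique() < 2:
        raise ValueError(f"attribute {attribute!r} is constant; nothing to discretize")
    binned, bins = pd.qcut(numeric, q=k, duplicates="drop", retbins=True)
    labels = [str(interval) for interval in binned.cat.categories]
    new_attr = AttributeSpec(
        name=attribute, kind="nominal", domain=labels, missing_token=attr.missing_token
    )
    schema = [new_attr if a.name == attribute else a for a in dataset.schema]
    examples = []
    for ex, cat in zip(dataset.examples, binned):
        values = dict(ex.values)
        values[attribute] = attr.missing_token if pd.isna(cat) else str(cat)
        examples.append(Example(id=ex.id, values=values, label=ex.label))
    return Dataset(schema=schema, examples=examples), list(bins)


# --------------------------------------------------------------------------
# Seed selection and the extension-against operator


def select_seed(dataset: Dataset, uncovered_positive_ids, rng) -> str:
    """Uniformly random uncovered positive; deterministic given the rng state."""
    wanted = set(uncovered_positive_ids)
    if not wanted:
        raise ValueError("no uncovered positive examples to seed from")
    ordered = [ex.id for ex in dataset.examples if ex.id in wanted]
    return ordered[int(rng.integers(len(ordered)))]


def _maximal_covering_nodes(hierarchy, seed_value, neg_value) -> frozenset:
    """Maximal nodes whose closure contains the seed value but not the negative's."""
    candidates = {seed_value} | hierarchy.ancestors(seed_value)
    qualifying = {
        node for node in candidates if neg_value not in hierarchy.closure([node])
    }
    return frozenset(
        node for node in qualifying if not (hierarchy.ancestors(node) & qualifying)
    )


def extend_against(
    seed: Example,
    negative: Example,
    schema,
    hierarchies: Optional[Mapping] = None,
    flat_hierarchical: bool = False,
    observed_values: Optional[Mapping] = None,
) -> list:
    """Most general conditions covering the seed and excluding the negative.

    One condition per attribute on which the two examples carry different
    known values; attributes with equal or missing values contribute
    nothing.  ``flat_hierarchical`` switches hierarchical attributes to the
    nominal treatment over ``observed_values`` (ontology-blind learning).
    """
    conditions = []
    for attr in schema:
        if not attr.is_input:
            continue
        sv = seed.values.get(attr.name)
        nv = negative.values.get(attr.name)
        if sv in (None, attr.missing_token) or nv in (None, attr.missing_token):
            continue
        if sv == nv:
            continue
        if attr.kind == "numeric":
            s, v = float(sv), float(nv)
            if s == v:
                continue
            mid = (s + v) / 2.0
            interval = (-math.inf, mid) if s < v else (mid, math.inf)
            conditions.append(Condition(attr.name, interval, mode="interval"))
        elif attr.kind == "nominal":
            allowed = frozenset(attr.domain) - {nv}
            if allowed:
                conditions.append(Condition(attr.name, allowed, mode="set"))
        else:  # hierarchical
            if flat_hierarchical:
                domain = frozenset((observed_values or {}).get(attr.name, {sv, nv}))
                allowed = domain - {nv}
                if allowed:
                    conditions.append(Condition(attr.name, allowed, mode="set"))
            else:
                hier = (hierarchies or {}).get(attr.domain)
                if hier is None:
                    raise ValueError(f"hierarchy {attr.domain!r} not provided")
                maximal = _maximal_covering_nodes(hier, sv, nv)
                if maximal:
                    conditions.append(Condition(attr.name, maximal, mode="closure"))
    return conditions


def _intersect_conditions(a: Condition, b: Condition, hierarchy=None) -> Optional[Condition]:
    """Logical conjunction of two conditions on the same attribute."""
    assert a.attribute == b.attribute and a.mode == b.mode
    if a.mode == "interval":
        lo = max(a.allowed[0], b.allowed[0])
        hi = min(a.allowed[1], b.allowed[1])
        if lo > hi:
            return None
        return Condition(a.attribute, (lo, hi), mode="interval")
    if a.mode == "set":
        merged = a.allowed & b.allowed
        if not merged:
            return None
        return Condition(a.attribute, merged, mode="set")
    extent = hierarchy.closure(a.allowed) & hierarchy.closure(b.allowed)
    if not extent:
        return None
    # A descendant-closed set is the closure of its maximal elements.
    maximal = frozenset(
        node for node in extent if not (set(hierarchy.parents[node]) & extent)
    )
    return Condition(a.attribute, maximal, mode="closure")


# --------------------------------------------------------------------------
# Star generation


@dataclass
class _Candidate:
    premise: tuple  # Conditions in creation order
    mask: int
    p: int
    n: int
    q: float
    order: int

    def key(self):
        return (-self.q, len(self.premise), self.order)


@dataclass
class Star:
    """The beam of candidate rules grown around one seed."""

    seed_id: str
    candidates: list  # of Rule, ranked best-first


def _candidate_from_premise(premise, engine, pos_mask, P, N, weight, order) -> _Candidate:
    mask = engine.rule_mask(list(premise))
    p = (mask & pos_mask).bit_count()
    n = (mask & ~pos_mask & engine.full_mask).bit_count()
    q = _safe_quality(p, n, P, N, weight)
    return _Candidate(premise=tuple(premise), mask=mask, p=p, n=n, q=q, order=order)


def _safe_quality(p, n, P, N, weight) -> float:
    """Q(R, w) with degenerate inputs mapped to sensible scores: 0 for an
    empty or positive-free rule; completeness alone when there are no
    negatives at all (consistency gain is undefined there)."""
    if p == 0:
        return 0.0
    if N == 0:
        return p / P if P else 0.0
    return rule_quality(CoverageStatsFast(p, n, P, N), weight)


class CoverageStatsFast:
    """Duck-typed stand-in for CoverageStats without validation overhead."""

    __slots__ = ("p", "n", "P", "N")

    def __init__(self, p, n, P, N):
        self.p, self.n, self.P, self.N = p, n, P, N


def generate_star(
    seed_id: str,
    bview: BinaryView,
    hierarchies: Optional[Mapping],
    config: LearnerConfig,
    engine: Optional[CoverageEngine] = None,
) -> Star:
    """Grow the bounded beam of candidate rules covering the seed.

    Negatives are visited in dataset order; a negative no candidate covers
    is skipped.  Specializing a candidate conjoins one extension condition
    (merging same-attribute conditions by intersection); the unspecialized
    parent remains in the pool.  After each negative the pool is deduplicated
    by premise, ranked (Q, premise length, age) and cut to the beam width.
    """
    dataset = bview.dataset
    if engine is None:
        engine = CoverageEngine(dataset, hierarchies)
    seed = next(ex for ex in dataset.examples if ex.id == seed_id)
    if seed.label != bview.target_class:
        raise ValueError(f"seed {seed_id!r} is not a positive example of {bview.target_class!r}")
    pos_mask = engine.label_mask(bview.target_class)
    P, N = bview.P, bview.N
    weight = config.w
    tol = config.consistency_tolerance
    flat = config.generalization_mode == "off"

    observed = None
    if flat:
        observed = {
            a.name: frozenset(
                v
                for v in (ex.values.get(a.name) for ex in dataset.examples)
                if v not in (None, a.missing_token)
            )
            for a in dataset.schema
            if a.kind == "hierarchical"
        }

    order_counter = 0
    pool = [
        _candidate_from_premise((), engine, pos_mask, P, N, weight, order_counter)
    ]

    for i, ex in enumerate(dataset.examples):
        if ex.label == bview.target_class:
            continue
        bit = 1 << i
        if not any(c.mask & bit for c in pool):
            continue
        extensions = extend_against(
            seed, ex, dataset.schema, hierarchies,
            flat_hierarchical=flat, observed_values=observed,
        )
        new_pool = []
        for cand in pool:
            if not (cand.mask & bit):
                new_pool.append(cand)
                continue
            new_pool.append(cand)  # parent retained: may still win on quality
            for cond in extensions:
                merged = _merge_into_premise(cand.premise, cond, engine)
                if merged is None:
                    continue
                order_counter += 1
                new_pool.append(
                    _candidate_from_premise(merged, engine, pos_mask, P, N, weight, order_counter)
                )
        pool = _dedupe_and_trim(new_pool, config.beam_width)
        if all(c.n <= tol for c in pool):
            break

    pool.sort(key=_Candidate.key)
    rules = [
        Rule(
            consequent=bview.target_class,
            premise=list(c.premise),
            p=c.p,
            n=c.n,
            q=c.q,
            w_used=weight,
        )
        for c in pool
    ]
    return Star(seed_id=seed_id, candidates=rules)


def _merge_into_premise(premise: tuple, cond: Condition, engine: CoverageEngine):
    """Conjoin a condition, intersecting with an existing one on the same attribute."""
    out = []
    merged = False
    for existing in premise:
        if existing.attribute == cond.attribute and existing.mode == cond.mode:
            hier = engine.hierarchy_for(cond.attribute) if cond.mode == "closure" else None
            combined = _intersect_conditions(existing, cond, hier)
            if combined is None:
                return None
            out.append(combined)
            merged = True
        else:
            out.append(existing)
    if not merged:
        out.append(cond)
    return tuple(out)


def _dedupe_and_trim(pool, beam_width):
    seen = {}
    for cand in pool:
        key = frozenset(c.signature() for c in cand.premise)
        best = seen.get(key)
        if best is None or cand.order < best.order:
            seen[key] = cand
    ranked = sorted(seen.values(), key=_Candidate.key)
    return ranked[:beam_width]


# --------------------------------------------------------------------------
# Rule post-processing


def attach_exceptions(
    rule: Rule, bview: BinaryView, hierarchies=None, engine: Optional[CoverageEngine] = None
) -> Rule:
    """List covered negatives as the rule's exceptions (p, n unchanged)."""
    if engine is None:
        engine = CoverageEngine(bview.dataset, hierarchies)
    mask = engine.rule_mask(rule)
    neg_mask = mask & ~engine.label_mask(bview.target_class) & engine.full_mask
    rule.exception_ids = engine.ids_from_mask(neg_mask)
    return rule


def trim_rule(
    rule: Rule,
    bview: BinaryView,
    hierarchies=None,
    config: Optional[LearnerConfig] = None,
    engine: Optional[CoverageEngine] = None,
) -> Rule:
    """Greedily drop conditions (last-added first) while Q does not decrease
    and the covered-negative count stays within the consistency tolerance."""
    config = config or LearnerConfig()
    if engine is None:
        engine = CoverageEngine(bview.dataset, hierarchies)
    pos_mask = engine.label_mask(bview.target_class)

    def score(premise):
        mask = engine.rule_mask(list(premise))
        p = (mask & pos_mask).bit_count()
        n = (mask & ~pos_mask & engine.full_mask).bit_count()
        return p, n, _safe_quality(p, n, bview.P, bview.N, config.w)

    premise = list(rule.premise)
    p, n, q = score(premise)
    changed = True
    while changed and len(premise) > 1:
        changed = False
        for idx in range(len(premise) - 1, -1, -1):
            candidate = premise[:idx] + premise[idx + 1 :]
            cp, cn, cq = score(candidate)
            if cq >= q and cn <= config.consistency_tolerance:
                premise = candidate
                p, n, q = cp, cn, cq
                changed = True
                break
    rule.premise = premise
    rule.p, rule.n, rule.q = p, n, q
    rule.w_used = config.w
    return rule


# --------------------------------------------------------------------------
# Sequential covering


def learn_class(
    dataset_or_view,
    target_class: str,
    hierarchies: Optional[Mapping] = None,
    config: Optional[LearnerConfig] = None,
    rng=None,
    engine: Optional[CoverageEngine] = None,
) -> list:
    """Sequential covering for one target class.

    Repeats seed -> star -> best rule -> trim -> exceptions until every
    positive is covered, a rule contributes no new positive, or the per-class
    rule cap is reached.
    """
    config = config or LearnerConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if isinstance(dataset_or_view, BinaryView):
        bview = dataset_or_view
    else:
        bview = binarize(dataset_or_view, target_class)
    dataset = bview.dataset
    if bview.P == 0:
        warnings.warn(f"no positive examples of class {target_class!r}; empty rule list")
        return []
    if engine is None:
        engine = CoverageEngine(dataset, hierarchies)
    pos_mask = engine.label_mask(target_class)
    uncovered = pos_mask
    index_of = {ex.id: i for i, ex in enumerate(dataset.examples)}

    rules = []
    while uncovered and len(rules) < config.max_rules_per_class:
        uncovered_ids = engine.ids_from_mask(uncovered)
        seed_id = select_seed(dataset, uncovered_ids, rng)
        star = generate_star(seed_id, bview, hierarchies, config, engine=engine)
        if not star.candidates:
            break
        best = star.candidates[0]
        trim_rule(best, bview, hierarchies, config, engine=engine)
        attach_exceptions(best, bview, hierarchies, engine=engine)
        mask = engine.rule_mask(best)
        newly = mask & uncovered
        if not newly:
            break
        count_coverage(best, dataset, hierarchies, engine=engine, weight=config.w)
        rules.append(best)
        uncovered &= ~mask
    return rules


def learn(dataset: Dataset, hierarchies: Optional[Mapping] = None,
          config: Optional[LearnerConfig] = None) -> Model:
    """Full pipeline: preprocessing, per-class covering, trimming, and
    (when a generalization mode is on) the ontology generalization pass."""
    config = config or LearnerConfig()
    if not dataset.examples:
        raise ValueError("cannot learn from an empty dataset")
    working, removed = remove_ambiguous(dataset)
    if config.discretize_bins:
        for attr_name, k in config.discretize_bins.items():
            working, _ = discretize_equal_frequency(working, attr_name, k)
    if not working.examples:
        warnings.warn("all examples removed as ambiguous; empty model")
    rng = np.random.default_rng(config.rng_seed)
    engine = CoverageEngine(working, hierarchies) if working.examples else None

    rules: dict = {}
    for target in dataset.output_attribute.domain:
        if not working.examples:
            rules[target] = []
            continue
        rules[target] = learn_class(
            binarize(working, target), target, hierarchies, config, rng=rng, engine=engine
        )

    totals = working.class_totals if working.examples else dataset.class_totals
    majority = max(totals, key=lambda c: (totals[c], c))
    model = Model(
        rules=rules,
        schema=working.schema if working.examples else dataset.schema,
        config=config,
        majority_class=majority,
        class_totals=totals,
        provenance={"rng_seed": config.rng_seed, "removed_ambiguous": removed},
    )
    model.sort_rules()
    if config.generalization_mode != "off":
        from .ontology_generalization import generalize_ruleset

        model, _ = generalize_ruleset(model, working, hierarchies, config)
    return model


def predict(model: Model, example: Example, hierarchies: Optional[Mapping] = None):
    """Classify one example; returns (class, ids of matching rules).

    The class of the highest-Q matching rule wins; ties go to the class with
    the greater summed Q of matching rules; with no match, the majority
    training class is returned.
    """
    matches = []  # (q, class, rule index)
    sums: dict = {}
    matched_ids = []
    for cls, rules in model.rules.items():
        for idx, rule in enumerate(rules):
            if covers(rule, example, model.schema, hierarchies):
                matches.append((rule.q, cls, idx))
                sums[cls] = sums.get(cls, 0.0) + rule.q
                matched_ids.append(f"{cls}#{idx}")
    if not matches:
        return model.majority_class, []
    best_q = max(m[0] for m in matches)
    tied = sorted({m[1] for m in matches if m[0] == best_q})
    if len(tied) > 1:
        tied.sort(key=lambda c: (-sums.get(c, 0.0), c))
    return tied[0], matched_ids
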