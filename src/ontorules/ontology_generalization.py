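"""Post-learning rule optimization by climbing IS-A hierarchies.

A learned hierarchical condition typically enumerates the concrete codes
seen in the data.  This pass replaces subsets of a condition's value set by
a common ancestor -- the highest concept that is either *consistent with
the data* (strict mode: the rule's covered-negative count must not change)
or *maximizes the rule quality* (quality mode: Q(R, w) must not decrease,
ties resolved toward the more general ancestor).  Generalization proceeds
condition by condition to a fixpoint; every accepted replacement is
recorded in an auditable trace.

Because a replacement only ever widens a condition's extent, coverage is
monotone: in strict mode p can only grow while n is pinned, hence Q never
decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .data_model import BinaryView, Condition, Dataset, Model, Rule, antichain, binarize
from .quality import (
    CoverageEngine,
    CoverageStats,
    UndefinedMeasureError,
    count_coverage,
    rule_quality,
)


@dataclass
class TraceEntry:
    rule: str  # "<class>#<index>"
    attribute: str
    before: frozenset
    after: frozenset
    delta_q: float
    delta_n: int
    mode: str


@dataclass
class GeneralizationTrace:
    entries: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rule,attribute,before,after,delta_q,delta_n,mode\n")
            for e in self.entries:
                before = "|".join(sorted(e.before))
                after = "|".join(sorted(e.after))
                fh.write(
                    f"{e.rule},{e.attribute},{before},{after},{e.delta_q:.6f},{e.delta_n},{e.mode}\n"
                )


def candidate_ancestors(hierarchy, value_set) -> list:
    """Ancestors that could replace part of a value set.

    For each ancestor ``A`` of any member, the replaced subset is
    ``S = value_set ∩ closure(A)``.  Candidates are ordered nearest
    ancestors first (depth descending), then by ``|S|`` descending, then by
    node id, so a climb explores one level at a time; multi-parent nodes
    contribute every parent line.
    """
    value_set = frozenset(value_set)
    for node in value_set:
        hierarchy._require(node)
    anc_union = set()
    for node in value_set:
        anc_union |= hierarchy.ancestors(node)
    candidates = []
    for anc in anc_union:
        replaced = value_set & hierarchy.closure([anc])
        if replaced:
            candidates.append((anc, replaced))
    candidates.sort(key=lambda item: (-hierarchy.depth[item[0]], -len(item[1]), item[0]))
    return candidates


def _substitute(value_set: frozenset, replaced: frozenset, ancestor: str, hierarchy) -> frozenset:
    return antichain((value_set - replaced) | {ancestor}, hierarchy)


class _RuleEvaluator:
    """Scores a rule while one of its conditions is being varied."""

    def __init__(self, rule: Rule, cond_index: int, bview: BinaryView, engine: CoverageEngine, w: float):
        self.rule = rule
        self.cond_index = cond_index
        self.engine = engine
        self.pos = engine.label_mask(bview.target_class)
        self.P, self.N = bview.P, bview.N
        self.w = w
        self.rest_mask = engine.full_mask
        for i, cond in enumerate(rule.premise):
            if i != cond_index:
                self.rest_mask &= engine.condition_mask(cond)

    def score(self, condition: Condition):
        mask = self.rest_mask & self.engine.condition_mask(condition)
        p = (mask & self.pos).bit_count()
        n = (mask & ~self.pos & self.engine.full_mask).bit_count()
        if p == 0:
            return p, n, 0.0
        try:
            q = rule_quality(CoverageStats(p, n, self.P, self.N), self.w)
        except UndefinedMeasureError:
            q = 0.0
        return p, n, q


def generalize_condition(
    condition: Condition,
    rule: Rule,
    bview: BinaryView,
    hierarchy,
    mode: str,
    w: float,
    engine: Optional[CoverageEngine] = None,
    rule_label: str = "rule",
):
    """Climb one hierarchical condition to its fixpoint.

    Strict mode applies, repeatedly, the shallowest replacement that leaves
    the rule's covered-negative count unchanged.  Quality mode applies the
    replacement maximizing Q, accepted while Q does not decrease, ties
    broken toward the shallower ancestor.  Returns the (possibly new)
    condition and the trace entries.
    """
    if mode == "off":
        return condition, []
    if mode not in ("strict", "quality"):
        raise ValueError(f"unknown generalization mode {mode!r}")
    if engine is None:
        engine = CoverageEngine(bview.dataset)

    cond_index = next(
        i for i, c in enumerate(rule.premise) if c is condition
    )
    evaluator = _RuleEvaluator(rule, cond_index, bview, engine, w)

    current = condition
    # Flat-learned hierarchical conditions carry exact-match semantics;
    # re-reading them under closure semantics is itself a generalization
    # step and must pass the same acceptance test.
    if current.mode == "set":
        converted = Condition(
            current.attribute, antichain(current.allowed, hierarchy), mode="closure"
        )
        p0, n0, q0 = evaluator.score(current)
        p1, n1, q1 = evaluator.score(converted)
        ok = (n1 == n0) if mode == "strict" else (q1 >= q0)
        if not ok:
            return current, []
        current = converted

    entries = []
    seen = {frozenset(current.allowed)}
    p0, n0, q0 = evaluator.score(current)
    for _ in range(2 * len(hierarchy.nodes) + 1):
        candidates = candidate_ancestors(hierarchy, current.allowed)
        scored = []
        for anc, replaced in candidates:
            new_allowed = _substitute(current.allowed, replaced, anc, hierarchy)
            if new_allowed == current.allowed or new_allowed in seen:
                continue
            cand_cond = Condition(current.attribute, new_allowed, mode="closure")
            p, n, q = evaluator.score(cand_cond)
            scored.append((anc, replaced, new_allowed, cand_cond, p, n, q))
        chosen = None
        if mode == "strict":
            qualifying = [s for s in scored if s[5] == n0]
            if qualifying:
                qualifying.sort(
                    key=lambda s: (hierarchy.depth[s[0]], -len(s[1]), s[0])
                )
                chosen = qualifying[0]
        else:
            acceptable = [s for s in scored if s[6] >= q0]
            if acceptable:
                acceptable.sort(key=lambda s: (-s[6], hierarchy.depth[s[0]], s[0]))
                chosen = acceptable[0]
        if chosen is None:
            break
        anc, replaced, new_allowed, cand_cond, p, n, q = chosen
        entries.append(
            TraceEntry(
                rule=rule_label,
                attribute=current.attribute,
                before=frozenset(current.allowed),
                after=new_allowed,
                delta_q=q - q0,
                delta_n=n - n0,
                mode=mode,
            )
        )
        current = cand_cond
        seen.add(new_allowed)
        p0, n0, q0 = p, n, q
    return current, entries


def generalize_ruleset(
    model: Model,
    dataset: Dataset,
    hierarchies: Mapping,
    config,
) -> tuple:
    """Apply hierarchy climbing to every hierarchical condition of a model.

    Rules are processed in descending-Q order, conditions in premise order;
    coverage counts and annotations are refreshed after each rule.  The
    model is updated in place and returned with the full trace.
    """
    mode = getattr(config, "generalization_mode", "strict")
    w = getattr(config, "w", model_default_w(model))
    by_name = {a.name: a for a in model.schema}
    trace = GeneralizationTrace()
    engine = CoverageEngine(dataset, hierarchies)
    for cls, rules in model.rules.items():
        bview = binarize(dataset, cls)
        for idx, rule in enumerate(rules):
            for ci, cond in enumerate(list(rule.premise)):
                attr = by_name.get(cond.attribute)
                if attr is None or attr.kind != "hierarchical":
                    continue
                hier = hierarchies.get(attr.domain) if hierarchies else None
                if hier is None:
                    raise KeyError(
                        f"no hierarchy {attr.domain!r} for attribute {attr.name!r}"
                    )
                new_cond, entries = generalize_condition(
                    rule.premise[ci],
                    rule,
                    bview,
                    hier,
                    mode,
                    w,
                    engine=engine,
                    rule_label=f"{cls}#{idx}",
                )
                rule.premise[ci] = new_cond
                trace.entries.extend(entries)
            count_coverage(rule, dataset, hierarchies, engine=engine, weight=w)
            from .learner import attach_exceptions

            attach_exceptions(rule, bview, hierarchies, engine=engine)
    model.sort_rules()
    return model, trace


def model_default_w(model: Model) -> float:
    for rule in model.all_rules():
        return rule.w_used
    return 0.3
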