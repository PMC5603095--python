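"""Sequential covering: preprocessing, extension-against, stars, covering."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ontorules.data_model import AttributeSpec, Condition, Example, Rule, binarize
from ontorules.learner import (
    LearnerConfig,
    attach_exceptions,
    discretize_equal_frequency,
    extend_against,
    generate_star,
    learn,
    learn_class,
    predict,
    remove_ambiguous,
    select_seed,
    trim_rule,
)
from ontorules.quality import count_coverage

from conftest import make_dataset


# -- preprocessing -----------------------------------------------------------


def test_remove_ambiguous_drops_label_conflicts():
    rows = [
        ("e0", {"a": "x"}, "pos"),
        ("e1", {"a": "x"}, "neg"),
        ("e2", {"a": "y"}, "pos"),
    ]
    dataset = make_dataset(rows)
    cleaned, removed = remove_ambiguous(dataset)
    assert sorted(removed) == ["e0", "e1"]
    assert [ex.id for ex in cleaned.examples] == ["e2"]


def test_remove_ambiguous_keeps_consistent_duplicates():
    rows = [("e0", {"a": "x"}, "pos"), ("e1", {"a": "x"}, "pos")]
    dataset = make_dataset(rows)
    cleaned, removed = remove_ambiguous(dataset)
    assert removed == []
    assert len(cleaned.examples) == 2


def test_remove_ambiguous_majority_does_not_survive():
    # Any label disagreement removes the whole duplicate group.
    rows = [
        ("e0", {"a": "x"}, "pos"),
        ("e1", {"a": "x"}, "pos"),
        ("e2", {"a": "x"}, "neg"),
    ]
    _, removed = remove_ambiguous(make_dataset(rows))
    assert sorted(removed) == ["e0", "e1", "e2"]


def test_discretize_equal_frequency_splits_in_half():
    attrs = {"age": AttributeSpec("age", "numeric", (0, 100))}
    rows = [(f"e{i}", {"age": str(i)}, "pos" if i < 4 else "neg") for i in range(1, 9)]
    dataset = make_dataset(rows, attrs=attrs)
    binned, bounds = discretize_equal_frequency(dataset, "age", 2)
    attr = binned.attribute("age")
    assert attr.kind == "nominal" and len(attr.domain) == 2
    low_bin = binned.examples[0].values["age"]
    assert [ex.values["age"] for ex in binned.examples[:4]] == [low_bin] * 4
    assert all(ex.values["age"] != low_bin for ex in binned.examples[4:])
    assert len(bounds) == 3


def test_discretize_ties_collapse_bins():
    attrs = {"x": AttributeSpec("x", "numeric", (0, 10))}
    rows = [(f"e{i}", {"x": "1" if i < 5 else "9"}, "pos") for i in range(10)]
    dataset = make_dataset(rows, attrs=attrs, classes=("pos", "neg"))
    binned, _ = discretize_equal_frequency(dataset, "x", 4)
    assert len(binned.attribute("x").domain) == 2


def test_discretize_invalid_inputs():
    attrs = {"x": AttributeSpec("x", "numeric", (0, 10))}
    rows = [(f"e{i}", {"x": "3"}, "pos") for i in range(4)]
    dataset = make_dataset(rows, attrs=attrs, classes=("pos", "neg"))
    with pytest.raises(ValueError):
        discretize_equal_frequency(dataset, "x", 1)
    with pytest.raises(ValueError, match="constant"):
        discretize_equal_frequency(dataset, "x", 2)


# -- seed selection ----------------------------------------------------------


def test_select_seed_single_and_deterministic(color_dataset):
    rng = np.random.default_rng(42)
    assert select_seed(color_dataset, ["e3"], rng) == "e3"
    picks = {
        select_seed(color_dataset, ["e0", "e1", "e3"], np.random.default_rng(42))
        for _ in range(5)
    }
    assert len(picks) == 1


def test_select_seed_uniformity(color_dataset):
    rng = np.random.default_rng(0)
    ids = ["e0", "e1", "e3"]
    counts = {i: 0 for i in ids}
    for _ in range(10_000):
        counts[select_seed(color_dataset, ids, rng)] += 1
    _, pvalue = sps.chisquare(list(counts.values()))
    assert pvalue > 1e-3


def test_select_seed_empty_errors(color_dataset):
    with pytest.raises(ValueError):
        select_seed(color_dataset, [], np.random.default_rng(0))


# -- extension-against -------------------------------------------------------


def test_extend_against_nominal_excludes_negative_value():
    attrs = {"color": AttributeSpec("color", "nominal", ["red", "blue", "green"])}
    dataset = make_dataset(
        [("s", {"color": "red"}, "pos"), ("n", {"color": "blue"}, "neg")], attrs=attrs
    )
    conds = extend_against(dataset.examples[0], dataset.examples[1], dataset.schema)
    assert len(conds) == 1
    assert conds[0].allowed == frozenset({"red", "green"})


def test_extend_against_equal_values_contribute_nothing():
    dataset = make_dataset(
        [("s", {"a": "x", "b": "1"}, "pos"), ("n", {"a": "x", "b": "2"}, "neg")]
    )
    conds = extend_against(dataset.examples[0], dataset.examples[1], dataset.schema)
    assert [c.attribute for c in conds] == ["b"]


def test_extend_against_hierarchical_maximal_node(chain_hierarchy):
    attrs = {"site": AttributeSpec("site", "hierarchical", "h")}
    dataset = make_dataset(
        [("s", {"site": "s"}, "pos"), ("n", {"site": "v"}, "neg")], attrs=attrs
    )
    conds = extend_against(
        dataset.examples[0], dataset.examples[1], dataset.schema, {"h": chain_hierarchy}
    )
    # A is the maximal node containing s but not v; R contains both.
    assert len(conds) == 1
    assert conds[0].mode == "closure" and conds[0].allowed == frozenset({"A"})


def test_extend_against_numeric_midpoint():
    attrs = {"age": AttributeSpec("age", "numeric", (0, 100))}
    dataset = make_dataset(
        [("s", {"age": "60"}, "pos"), ("n", {"age": "70"}, "neg")], attrs=attrs
    )
    conds = extend_against(dataset.examples[0], dataset.examples[1], dataset.schema)
    assert conds[0].allowed == (-math.inf, 65.0)


def test_extend_against_flat_hierarchical_uses_observed_values(chain_hierarchy):
    attrs = {"site": AttributeSpec("site", "hierarchical", "h")}
    dataset = make_dataset(
        [("s", {"site": "s"}, "pos"), ("n", {"site": "v"}, "neg")], attrs=attrs
    )
    conds = extend_against(
        dataset.examples[0], dataset.examples[1], dataset.schema,
        flat_hierarchical=True, observed_values={"site": frozenset({"s", "v"})},
    )
    assert conds[0].mode == "set" and conds[0].allowed == frozenset({"s"})


# -- star generation ---------------------------------------------------------


def test_star_without_negatives_is_the_empty_premise():
    dataset = make_dataset([("e0", {"a": "x"}, "pos"), ("e1", {"a": "y"}, "pos")],
                           classes=("neg", "pos"))
    star = generate_star("e0", binarize(dataset, "pos"), {}, LearnerConfig())
    assert len(star.candidates) == 1
    best = star.candidates[0]
    assert best.premise == [] and best.p == 2 and best.n == 0


def test_star_separates_toy_dataset():
    rows = [
        ("p0", {"a": "x", "b": "u"}, "pos"),
        ("p1", {"a": "x", "b": "w"}, "pos"),
        ("n0", {"a": "y", "b": "u"}, "neg"),
        ("n1", {"a": "y", "b": "w"}, "neg"),
    ]
    dataset = make_dataset(rows)
    star = generate_star("p0", binarize(dataset, "pos"), {}, LearnerConfig())
    best = star.candidates[0]
    assert best.p == 2 and best.n == 0
    assert [c.attribute for c in best.premise] == ["a"]


def test_star_beam_one_matches_greedy_trace():
    rows = [
        ("p0", {"a": "x", "b": "u"}, "pos"),
        ("n0", {"a": "y", "b": "u"}, "neg"),
        ("n1", {"a": "x", "b": "w"}, "neg"),
    ]
    dataset = make_dataset(rows)
    star = generate_star("p0", binarize(dataset, "pos"), {},
                         LearnerConfig(beam_width=1))
    best = star.candidates[0]
    # greedy hand-simulation: exclude n0 via a=x, then n1 via b=u
    assert {(c.attribute, tuple(sorted(c.allowed))) for c in best.premise} == {
        ("a", ("x",)),
        ("b", ("u",)),
    }
    assert best.n == 0


def _brute_force_best_q(dataset, seed, w=0.3):
    """Exhaustive search over all conjunctive rules covering the seed.

    Binary nominal attributes only: per attribute the condition is absent or
    pins one value, so the premise space is the full power set.
    """
    input_attrs = [a for a in dataset.schema if a.is_input]
    P = sum(1 for ex in dataset.examples if ex.label == "pos")
    N = len(dataset.examples) - P
    best = 0.0
    for r in range(len(input_attrs) + 1):
        for chosen in itertools.combinations(input_attrs, r):
            constraint = {a.name: seed.values[a.name] for a in chosen}
            p = n = 0
            for ex in dataset.examples:
                if all(ex.values[k] == v for k, v in constraint.items()):
                    if ex.label == "pos":
                        p += 1
                    else:
                        n += 1
            if p == 0:
                continue
            prior = P / (P + N)
            consig = max(((p / (p + n)) - prior) * (P + N) / N, 0.0)
            q = 0.0 if consig == 0.0 else (p / P) ** w * consig ** (1 - w)
            best = max(best, q)
    return best


def test_star_attains_brute_force_optimum_on_tiny_datasets():
    """For every positive seed, the star's best rule matches the exhaustive
    optimum over conjunctive rules covering that seed."""
    rng = np.random.default_rng(5)
    config = LearnerConfig(beam_width=32)
    for _ in range(30):
        n_attr = int(rng.integers(2, 4))
        attrs = {
            f"a{k}": AttributeSpec(f"a{k}", "nominal", ["0", "1"]) for k in range(n_attr)
        }
        rows = [
            (
                f"e{i}",
                {f"a{k}": str(rng.integers(2)) for k in range(n_attr)},
                "pos" if rng.random() < 0.5 else "neg",
            )
            for i in range(int(rng.integers(3, 7)))
        ]
        dataset = make_dataset(rows, attrs=attrs)
        view = binarize(dataset, "pos")
        if view.P == 0 or view.N == 0:
            continue
        for ex in dataset.examples:
            if ex.label != "pos":
                continue
            star = generate_star(ex.id, view, {}, config)
            oracle = _brute_force_best_q(dataset, ex)
            assert star.candidates[0].q == pytest.approx(oracle, abs=1e-12)


# -- trimming, exceptions ----------------------------------------------------


def test_trim_drops_redundant_condition(color_dataset):
    view = binarize(color_dataset, "pos")
    rule = Rule(
        consequent="pos",
        premise=[
            Condition("color", {"red"}, mode="set"),
            Condition("shape", {"circle", "square"}, mode="set"),
            Condition("color", {"red", "blue"}, mode="set"),  # vacuous given the first
        ],
    )
    trimmed = trim_rule(rule, view, config=LearnerConfig())
    assert len(trimmed.premise) == 2
    assert trimmed.n == 0


def test_trim_keeps_necessary_conditions(color_dataset):
    view = binarize(color_dataset, "pos")
    rule = Rule(
        consequent="pos",
        premise=[
            Condition("color", {"red"}, mode="set"),
            Condition("shape", {"circle", "square"}, mode="set"),
        ],
    )
    before = [c.signature() for c in rule.premise]
    trimmed = trim_rule(rule, view, config=LearnerConfig())
    assert [c.signature() for c in trimmed.premise] == before


def test_trim_matches_exhaustive_subset_search(color_dataset):
    view = binarize(color_dataset, "pos")
    conds = [
        Condition("color", {"red"}, mode="set"),
        Condition("shape", {"circle", "square"}, mode="set"),
        Condition("color", {"red", "blue"}, mode="set"),
    ]
    rule = trim_rule(Rule(consequent="pos", premise=list(conds)), view,
                     config=LearnerConfig())
    # oracle: best q over all consistent (n=0) non-empty subsets
    best_q = 0.0
    for r in range(1, len(conds) + 1):
        for subset in itertools.combinations(conds, r):
            probe = Rule(consequent="pos", premise=list(subset))
            stats = count_coverage(probe, color_dataset)
            if stats.n == 0:
                best_q = max(best_q, probe.q)
    assert rule.q == pytest.approx(best_q, abs=1e-12)


def test_attach_exceptions_lists_covered_negatives(color_dataset):
    view = binarize(color_dataset, "pos")
    rule = Rule(consequent="pos", premise=[Condition("color", {"red"}, mode="set")])
    count_coverage(rule, color_dataset)
    attach_exceptions(rule, view)
    assert rule.exception_ids == ["e2", "e5"]  # the two red stars, dataset order
    clean = Rule(consequent="pos",
                 premise=[Condition("color", {"red"}, mode="set"),
                          Condition("shape", {"circle", "square"}, mode="set")])
    attach_exceptions(clean, view)
    assert clean.exception_ids == []


# -- sequential covering -----------------------------------------------------


def test_learn_class_separable_gives_single_perfect_rule():
    rows = [(f"e{i}", {"a": "x" if i < 3 else "y", "b": "u"},
             "pos" if i < 3 else "neg") for i in range(8)]
    dataset = make_dataset(rows)
    rules = learn_class(dataset, "pos", {}, LearnerConfig(rng_seed=1))
    assert len(rules) == 1
    assert (rules[0].p, rules[0].n) == (3, 0)
    assert rules[0].q == pytest.approx(1.0)


def test_learn_class_two_disjoint_clusters():
    # XOR layout: no single consistent conjunctive rule covers both clusters.
    rows = []
    for i in range(3):
        rows.append((f"p{i}", {"a": "x", "b": "u"}, "pos"))
    for i in range(3):
        rows.append((f"q{i}", {"a": "y", "b": "w"}, "pos"))
    for i in range(3):
        rows.append((f"n{i}", {"a": "x", "b": "w"}, "neg"))
    for i in range(3):
        rows.append((f"m{i}", {"a": "y", "b": "u"}, "neg"))
    dataset = make_dataset(rows)
    rules = learn_class(dataset, "pos", {}, LearnerConfig(rng_seed=3))
    assert len(rules) == 2
    covered = sum(r.p for r in rules)
    assert covered == 6 and all(r.n == 0 for r in rules)


def test_learn_class_no_positives_warns():
    dataset = make_dataset([("e0", {"a": "x"}, "neg")], classes=("neg", "pos"))
    with pytest.warns(UserWarning):
        assert learn_class(dataset, "pos", {}, LearnerConfig()) == []


def test_learn_empty_dataset_errors():
    dataset = make_dataset([("e0", {"a": "x"}, "neg")], classes=("neg", "pos"))
    with pytest.raises(ValueError):
        learn(dataset.with_examples([]), {}, LearnerConfig())


def test_learn_with_configured_discretization():
    attrs = {"age": AttributeSpec("age", "numeric", (0, 120))}
    rows = [(f"e{i}", {"age": str(50 + i)}, "pos" if i < 5 else "neg")
            for i in range(10)]
    dataset = make_dataset(rows, attrs=attrs)
    config = LearnerConfig(rng_seed=0, discretize_bins={"age": 2})
    model = learn(dataset, {}, config)
    assert model.schema[0].kind == "nominal"  # age was binned
    rule = model.rules["pos"][0]
    assert (rule.p, rule.n) == (5, 0)


def test_learn_is_deterministic(color_dataset):
    from ontorules.io_cli import model_to_dict

    config = LearnerConfig(rng_seed=9)
    m1 = learn(color_dataset, {}, config)
    m2 = learn(color_dataset, {}, config)
    assert model_to_dict(m1) == model_to_dict(m2)


# -- prediction --------------------------------------------------------------


def _model_with(rules, schema, majority="neg"):
    from ontorules.data_model import Model

    by_class = {}
    for r in rules:
        by_class.setdefault(r.consequent, []).append(r)
    return Model(rules=by_class, schema=schema, config=LearnerConfig(),
                 majority_class=majority, class_totals={})


def test_predict_single_matching_rule(color_dataset):
    rule = Rule(consequent="pos", premise=[Condition("color", {"red"}, mode="set")], q=0.8)
    model = _model_with([rule], color_dataset.schema)
    cls, matched = predict(model, color_dataset.examples[0], {})
    assert cls == "pos" and matched == ["pos#0"]


def test_predict_falls_back_to_majority(color_dataset):
    rule = Rule(consequent="pos", premise=[Condition("color", {"blue"}, mode="set")], q=0.8)
    model = _model_with([rule], color_dataset.schema, majority="neg")
    cls, matched = predict(model, color_dataset.examples[0], {})
    assert cls == "neg" and matched == []


def test_predict_tie_broken_by_summed_quality(color_dataset):
    r_pos = Rule(consequent="pos", premise=[Condition("color", {"red"}, mode="set")], q=0.6)
    r_pos2 = Rule(consequent="pos", premise=[Condition("shape", {"circle"}, mode="set")], q=0.3)
    r_neg = Rule(consequent="neg", premise=[Condition("shape", {"circle"}, mode="set")], q=0.6)
    model = _model_with([r_pos, r_pos2, r_neg], color_dataset.schema)
    cls, _ = predict(model, color_dataset.examples[0], {})
    assert cls == "pos"  # tie at q=0.6; pos wins on summed quality 0.9
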