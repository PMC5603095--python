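"""Train/test splitting, per-task metric rows, and method comparison.

The comparison protocol mirrors a small benchmark over several binary
outcome tasks: split each task 80/20, learn a model per method on the same
training partition, score the selected (highest-Q) rule of each model on
the held-out partition, and compare the per-task Q values with a paired
t-test.  Both one- and two-tailed p-values are always reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .data_model import Dataset, Model, Rule
from .learner import LearnerConfig, learn
from .quality import (
    UndefinedMeasureError,
    count_coverage,
    precision_recall_f1,
    rule_quality,
)


def split_train_test(dataset: Dataset, fraction: float, rng, stratify: bool = False):
    """Random partition into train (``round(fraction * n)``) and test.

    Plain random by default; ``stratify=True`` splits each class separately
    at the same fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(dataset.examples)
    if n < 2:
        raise ValueError("dataset too small to split")
    if stratify:
        train_idx: list = []
        by_class: dict = {}
        for i, ex in enumerate(dataset.examples):
            by_class.setdefault(ex.label, []).append(i)
        for cls in sorted(by_class):
            idx = np.array(by_class[cls])
            perm = rng.permutation(len(idx))
            take = int(round(fraction * len(idx)))
            train_idx.extend(idx[perm[:take]].tolist())
        train_set = set(train_idx)
    else:
        perm = rng.permutation(n)
        take = int(round(fraction * n))
        train_set = set(perm[:take].tolist())
    if not train_set or len(train_set) == n:
        raise ValueError("split leaves one partition empty")
    train = [ex for i, ex in enumerate(dataset.examples) if i in train_set]
    test = [ex for i, ex in enumerate(dataset.examples) if i not in train_set]
    return dataset.with_examples(train), dataset.with_examples(test)


def select_rule(rules) -> Rule:
    """The highest-Q rule; ties go to larger p, then to the earlier rule."""
    if not rules:
        raise ValueError("cannot select from an empty rule list")
    best = rules[0]
    for rule in rules[1:]:
        if (rule.q, rule.p) > (best.q, best.p):
            best = rule
    return best


@dataclass
class MetricsRow:
    """Selected-rule metrics for one task under one method."""

    task: str
    method: str
    q: float
    precision: float
    recall: float
    f1: float
    p: int
    n: int
    P: int
    N: int
    partition: str = "test"


def evaluate_task(model: Model, dataset: Dataset, target_class: str,
                  hierarchies=None, task: str = "", method: str = "",
                  partition: str = "test") -> MetricsRow:
    """Recount the selected rule of ``target_class`` on the given partition."""
    rules = model.rules.get(target_class, [])
    if not rules:
        warnings.warn(f"no rules for class {target_class!r}; zero metrics row")
        return MetricsRow(task, method, 0.0, 0.0, 0.0, 0.0, 0, 0, 0, 0, partition)
    rule = select_rule(rules).copy()
    stats = count_coverage(rule, dataset, hierarchies, weight=rule.w_used)
    try:
        precision, recall, f1 = precision_recall_f1(stats)
    except UndefinedMeasureError:
        precision = recall = f1 = 0.0
    try:
        q = rule_quality(stats, rule.w_used)
    except UndefinedMeasureError:
        q = 0.0
    return MetricsRow(task, method, q, precision, recall, f1,
                      stats.p, stats.n, stats.P, stats.N, partition)


@dataclass
class ComparisonReport:
    """Paired comparison of two methods over matched task Q values."""

    n_pairs: int
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    mean_diff: float
    t_stat: Optional[float]
    df: int
    p_one_tailed: Optional[float]
    p_two_tailed: Optional[float]
    degenerate: bool = False
    rows: list = field(default_factory=list)


def paired_ttest(pairs) -> ComparisonReport:
    """Classical paired t-test on (method A, method B) value pairs.

    ``t = mean(d) / (sd(d) / sqrt(k))`` with ``d = b - a`` and the n-1
    variance; df = k - 1.  All-zero differences yield a degenerate report;
    a zero-variance nonzero difference reports an infinite t.
    """
    a = np.asarray([x for x, _ in pairs], dtype=float)
    b = np.asarray([y for _, y in pairs], dtype=float)
    k = len(a)
    if k < 2:
        raise ValueError("need at least two pairs")
    d = b - a
    report = ComparisonReport(
        n_pairs=k,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        var_a=float(a.var(ddof=1)),
        var_b=float(b.var(ddof=1)),
        mean_diff=float(d.mean()),
        t_stat=None,
        df=k - 1,
        p_one_tailed=None,
        p_two_tailed=None,
    )
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        report.degenerate = True
        if d.mean() != 0.0:
            report.t_stat = math.copysign(math.inf, float(d.mean()))
            report.p_one_tailed = 0.0
            report.p_two_tailed = 0.0
        return report
    t = float(d.mean() / (sd / math.sqrt(k)))
    report.t_stat = t
    # one-tailed in the direction of a positive difference (b > a)
    report.p_one_tailed = float(sps.t.sf(t, k - 1))
    report.p_two_tailed = float(2.0 * sps.t.sf(abs(t), k - 1))
    return report


def compare_methods(tasks, config_a: LearnerConfig, config_b: LearnerConfig,
                    fraction: float = 0.8, split_seed: int = 0,
                    partition: str = "test") -> ComparisonReport:
    """Learn both configs on the same train split of every task and compare.

    ``tasks`` is a sequence of ``(label, dataset, target_class, hierarchies)``
    tuples.  Returns a :class:`ComparisonReport` whose ``rows`` hold one
    :class:`MetricsRow` per task and method; the t-test runs over the
    per-task (Q_a, Q_b) pairs.
    """
    pairs = []
    rows = []
    for t_index, (label, dataset, target_class, hierarchies) in enumerate(tasks):
        rng = np.random.default_rng((split_seed, t_index))
        train, test = split_train_test(dataset, fraction, rng)
        eval_part = test if partition == "test" else train
        row_pair = []
        for method, config in (("a", config_a), ("b", config_b)):
            model = learn(train, hierarchies, config)
            row = evaluate_task(model, eval_part, target_class, hierarchies,
                                task=label, method=method, partition=partition)
            rows.append(row)
            row_pair.append(row.q)
        pairs.append((row_pair[0], row_pair[1]))
    report = paired_ttest(pairs)
    report.rows = rows
    return report
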