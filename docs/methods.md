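# Methods

## Rule language and coverage semantics

A model is a set of attributional rules per output class. Each rule is a
conjunction of conditions, one attribute each:

* nominal conditions hold a value set and match by membership;
* numeric conditions hold a closed interval;
* hierarchical conditions hold an antichain of concept nodes and match when
  the example's code lies in the *descendant-or-self closure* of that set.

A missing value never matches any condition. This is a deliberate,
conservative convention: an unanswered survey item neither supports nor
refutes a condition, so a rule cannot claim coverage of it. The alternative
(missing matches everything) would let rules accrue completeness from
unobserved values.

Hierarchical value sets are kept in antichain normal form — a node that is a
descendant of another listed node is dropped at construction, since closure
semantics makes it redundant.

Exceptions (`|_ {ids}`) list the negative examples a rule covers. They
annotate the rule; they do not change the reported `p`/`n` counts, which are
raw coverage. This matches the output dialect in which a rule can print
`n = 2` while carrying exceptions.

## Quality measures

`Q(R, w) = compl(R)^w * consig(R)^(1-w)` with `compl = p/P` and
`consig = ((p/(p+n)) - P/(P+N)) * (P+N)/N`. Numerical conventions:

* `consig` is clamped below at 0 before exponentiation. A rule whose
  precision falls below the class prior gains nothing, and a negative base
  under a fractional power is undefined; clamping gives such rules Q = 0.
* `w = 1` reduces exactly to completeness and `w = 0` exactly to consistency
  gain (special-cased, no floating-point exponentiation).
* Measures raise an explicit error outside their domain (P = 0, N = 0, or an
  empty-coverage rule). Single-class datasets are rejected up front by the
  same mechanism. Inside the beam search a degenerate candidate simply
  scores 0 (or bare completeness when the dataset has no negatives at all).
* The default w = 0.3 mildly favors consistent rules over complete ones; it
  is the weight all shipped defaults and reports use.
* Reported q is rounded to 3 decimals at render time only; per-condition
  annotation percentages use truncation (`floor(100 p/(p+n))`), which is the
  convention of the text dialect the output imitates.

## Hierarchy sanitization

Merged terminologies contain self-loops, duplicate assertions, and cycles.
`sanitize` removes self-loops, collapses duplicate edges to their first
occurrence, and breaks cycles by deleting DFS back edges: traversing from the
roots (nodes without parents), children in lexicographic order, any edge
whose head is already on the current DFS path connects back to a concept
higher in the hierarchy and is deleted. The procedure is deterministic given
the input edge order; every deletion is recorded with a reason code
(`self_loop`, `duplicate`, `cycle_break`) for audit. Input with no parentless
node at all is rejected as fully cyclic; a cyclic component merely unreachable
from the roots is entered at its lexicographically smallest node, whose
closing back edge is then removed, making that node a root of the result.
Node depth is the minimum edge distance from any root — ties in "distance
from the root" resolve toward the shallowest reading.

## The learner

Sequential covering with seed/star search:

1. ambiguous examples (identical inputs, conflicting labels) are removed as a
   preprocessing step; equal-frequency discretization is available per
   numeric attribute;
2. a seed is drawn uniformly from the uncovered positives (single global RNG,
   seeded from the config — all stochastic choices flow from it);
3. the star grows a beam of candidate rules: for each covered negative (in
   dataset order), each candidate covering it is specialized by each
   condition from the extension-against operator, merging same-attribute
   conditions by intersection; candidates are deduplicated by premise, ranked
   by (Q, fewer conditions, earlier creation) and cut to the beam width
   (default 5);
4. the best candidate is trimmed (conditions dropped greedily, last added
   first, while Q does not decrease and covered negatives stay within the
   consistency tolerance, default 0), exceptions are attached, and its
   positives are marked covered. Learning stops when positives are exhausted,
   a rule adds no new positive, or the per-class cap (default 10) is hit.

One deliberate design choice: when a candidate is specialized against a
negative, the unspecialized parent stays in the pool. Rules that tolerate a
few negatives can therefore survive on quality and end up carrying
exceptions — the "approximately do not cover" behavior — and on small
datasets the star provably reaches the exhaustive-search optimum among
conjunctive rules covering the seed (the suite checks this against a brute
force oracle). With a consistency tolerance of 0 on clean data the winner is
always a consistent rule, so nothing changes in the noiseless regime.

The extension-against operator emits, per attribute where seed and negative
differ, the most general condition covering the seed and excluding the
negative: domain-minus-value for nominals, the half-interval up to the
midpoint for numerics, and for hierarchical attributes the *maximal* nodes
whose closure contains the seed's code but not the negative's.

Ontology-blind mode (`generalization_mode="off"`) treats hierarchical
attributes as flat nominal codes over the values observed in the data. This
is how a standard attributional learner sees a CUI column, and it is the
baseline arm of every comparison; using the full node set as the nominal
domain would be wrong there, because the closure of "all nodes minus one
leaf" still contains every leaf.

## Ontology generalization

A post-learning pass (placed in rule optimization, not interleaved with the
star) climbs every hierarchical condition of every rule, rules in descending
Q, conditions in premise order. Candidate replacements are ancestors `A` of
any subset `S` of the value set with `closure(A) ⊇ S`, enumerated nearest
ancestors first; the replacement substitutes `(values \ S) ∪ {A}`,
re-normalized to an antichain. Multi-parent concepts contribute all parent
lines.

* **strict** mode applies, repeatedly, the shallowest replacement that leaves
  the rule's covered-negative count exactly unchanged. "Consistent with the
  data" is read as *does not admit new negatives*, not "zero negatives": a
  learned rule may already carry exceptions, and generalization must not add
  to them. Since replacements only widen the extent, p can only grow while n
  is pinned, so Q never decreases.
* **quality** mode applies the replacement maximizing Q, accepted while Q
  does not decrease; ties break toward the shallower ancestor, then the
  lexicographically smallest, so maximal generality is preferred at equal
  quality.

Conditions learned flat (exact-match leaf sets) are first re-read under
closure semantics; that conversion is itself a widening and must pass the
same acceptance test. Each pass keeps a seen-set of value sets, so the climb
terminates and the whole pass is idempotent; every accepted step is recorded
in a trace (before/after sets, ΔQ, Δn) exportable as CSV.

## Synthetic cohorts

The generator emulates the shape of a linked cancer-registry/health-survey
cohort, with all constants overridable:

* n = 723 examples; binary outcome at 12% prevalence by default, task suites
  cycle 12/16/8/4/20/7% (post-diagnosis disability rates for the six
  activities of daily living);
* 3 demographic nominals with skewed marginals (race 70/15/5/10,
  ethnicity 90/10, marital status 55/25/10/10);
* 13 binary comorbidity flags with prevalences declining 60% -> 12%;
* 3 hierarchical tumor attributes (site, histology, morphology), each drawn
  uniformly from the leaves of a generated depth-3, branching-3 hierarchy in
  which 10% of deeper nodes carry a second parent.

Labels come from planted conjunctive rules whose hierarchical conditions sit
at internal nodes (level 1 or 2), so the concept is compact in the ontology
but requires leaf enumeration for a flat learner. The planted-rule firing
count is pinned to `round(n * prevalence)` by rejection sampling over whole
rows (capped at 100 x n draws; an error past the cap indicates an infeasible
prevalence for the planted closure sizes). Label noise, when requested, then
flips each label independently; noise defaults to 0, and the multi-task
comparison suite sets 5% explicitly as its study condition.

What the generator does **not** emulate: correlations among comorbidities and
demographics, site-specific histology distributions, longitudinal structure,
or informative missingness (generated cohorts have no missing values). A
passing recovery or comparison test therefore demonstrates the machinery —
not performance on real survey data, whose noise is neither independent nor
symmetric.

Recovery of a planted rule is scored per attribute as the Jaccard overlap of
the conditions' admitted value sets — for hierarchical conditions the closure
restricted to leaves, so a full leaf enumeration and its internal-node
generalization score as equal — averaged over the attributes in either
premise, maximized over learned rules, and averaged over planted rules.

## Evaluation protocol

Tasks are split 80/20 uniformly at random (unstratified by default, matching
the plain protocol the comparison emulates; a stratified option exists). Both
methods learn on the same training partition; the selected (highest-Q,
ties to larger p) rule per task is re-scored on the held-out partition, and
per-task Q pairs feed a classical paired t-test (n-1 variance, df = k-1).
Both one- and two-tailed p-values are always reported — published summaries
of this kind are often ambiguous about tails, so the report never silently
picks one. All-zero differences yield a flagged degenerate report; a
zero-variance nonzero shift reports an infinite t.

The headline property checked by the suite: across 6 synthetic tasks and 20
seeds (120 pairs), held-out rule quality under strict generalization is at
least that of the flat learner on average, with a one-sided paired p < 0.1.
Problem sizes (n = 723 per cohort, beam 5, 10-rule cap) keep the full check
under a minute of CPU; they are the package's default study conditions, not
tuned values.

## Known limitations

* Only IS-A relationships are used; other semantic relations (part-of,
  associated-with) are out of scope, as are downward (specializing) moves.
* The star search is a beam, not exhaustive: optimality is only guaranteed
  when the beam accommodates all distinct premises (as in the tiny-dataset
  oracle tests).
* Constructive induction, attribute selection, and validation-split pruning
  are not implemented.
* The rule-text dialect is write-only; models round-trip through JSON.
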