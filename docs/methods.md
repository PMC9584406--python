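# Methods

This note documents the model class, the algorithms, the tunable
parameters, and the design choices behind `hkmlearn`, in the order the
pipeline runs: formula class → simplification catalog → binarization →
exhaustive search → multi-instance evaluation → synthetic generators.

## The model class

A rule is an expression tree over Boolean atoms with node kinds
`VAR`, `NOT`, `AND`, `OR` and `SUMGE` (thresholded Boolean sum: true iff
at least *t* of its *k* conditions hold, 2 ≤ *t* ≤ *k* − 1; *t* = 1 and
*t* = *k* are by definition written as `OR`/`AND`). Admissibility:

* at most 4 distinct variables, each used at most once (read-once);
* at most 4 operators, counted as: `NOT` = 1, an *a*-ary `AND`/`OR`
  chain = *a* − 1 binary connectives, `SUMGE` = 1 regardless of arity.

The counting convention is a design choice (no canonical convention
exists for n-ary connectives). Counting the thresholded sum as a single
operator treats "count how many conditions hold and compare" as one
cognitive act, which makes the majority-of-3 rule (`SUM(a,b,c) >= 2`)
admissible — the canonical example of everyday threshold reasoning
(at least two of three criteria met). `SUMGE` children are restricted to literals
(a variable or its negation): the operator models counting *conditions*,
not evaluating nested subformulas, and only the `>=` direction exists
(`< t` is `NOT (SUM >= t)`).

One negation is special-cased: flipping the direction of a numeric
threshold atom (`age > 60` ↔ `age <= 60`) costs **zero** operators,
because both directions are the same cognitive effort. This discount
applies only where the variable is bound to a threshold atom; `NOT` on a
native Boolean or category-indicator atom costs 1.

Constant and degenerate functions (tables not depending on all their
variables) are rejected as *n*-variable models; they are found at their
true smaller size instead, which prevents duplicate models across sizes.

## Simplification catalog

Truth tables (the semantic identity of a formula; row *r* assigns
variable *i* the *i*-th bit of *r*, LSB = variable 0) are mapped to their
shortest admissible expression by exhaustive enumeration of read-once
trees over 1..4 variables: all set partitions of the variable set, all
connectives and SUM thresholds, all NOT placements. Tables unreachable
by any admissible expression (e.g. XOR, which requires a repeated
variable) are absent from the catalog and excluded from the search.

Each table stores *cost variants* `(total operators, leaf-NOT
positions)`: the effective cost for a concrete subset is the total minus
the leaf NOTs that land on threshold atoms. Variants are pruned by
dominance (`(o1, m1)` dominates `(o2, m2)` iff `o1 + |m2 \ m1| ≤ o2`),
ties broken by the canonical rendering, so catalog construction is
deterministic. The canonical child order inside `AND`/`OR`/`SUM` is
(node kind, smallest variable index, rendered text).

Class counts, computed by the catalog itself and verified against an
independent binary-tree enumerator for *n* ≤ 3: the reachable proper
labeled tables number 2 / 8 / 72 / 632 for *n* = 1..4, collapsing to
**2 / 6 / 24 / 84** permutation-distinct classes (116 summed over
sizes). The per-size count is the quantity that matters operationally —
it bounds the number of candidate expressions applied to each variable
subset, written B(*n*) in the complexity estimate — and stays below 100
at every size, so B(*n*) is treated as a constant ≤ 100 throughout.

## Binarization

* Numeric columns: up to K thresholds (default 3) at evenly spaced
  quantiles of the non-missing values, rounded to 2 significant digits
  (humanly memorable), deduplicated, and dropped if constant on the
  data. Quantile placement is a design choice; supervised split search
  (entropy/Gini) is deliberately out of scope to keep thresholds simple
  and model-agnostic.
* Boolean columns pass through; categorical columns become one indicator
  atom per level.
* A column with missing cells additionally yields an `is missing`
  indicator atom — missingness is preserved as information, never
  imputed. Degenerate cases produce nothing: constant and all-missing
  columns yield no threshold atoms, and an all-missing column yields no
  (constant) indicator either.
* Atoms of one source column are *siblings* and never co-occur in a
  formula (the read-once constraint lifted to source features): two
  thresholds on the same measurement are one variable read twice.

## Exhaustive search

For every subset of *n* atoms with pairwise distinct sources
(*n* ranging over the configured sizes), rows with any masked atom are
dropped; if the retained fraction (*coverage*) falls below the minimum
(default 0.8) the subset is skipped. One pass over the covered rows
builds a 2ⁿ-cell contingency table, after which each candidate formula
is scored in O(2ⁿ) from the table — the observation count L enters once
per subset, not per formula. Scores are confusion-matrix metrics
(default F1 = 2TP/(2TP + FP + FN)); zero denominators score 0. Both
target polarities are handled because the catalog is closed under output
negation wherever the negated form is admissible.

The top-M stack (default M = 25, following the practice of keeping
10–50 near-optimal rules for the user to choose among) orders models by
the total key *(higher score, fewer variables, fewer operators, higher
coverage, lexicographically smaller rendering)*. A total order is what
makes training deterministic and the subset loop partitionable: partial
stacks merge to the same result in any order (`merge_model_lists`).
Optional row subsampling (off by default) is a seeded, recorded draw.

## Multi-instance evaluation

Instance *i* of an experiment uses seed `master_seed + i` to draw a
random 80/20 train/test split; the best trained model's train score,
held-out score, and stability factor

    S = |Q_train − Q_test| / Q_train        (Q = F1)

are recorded (S is undefined at zero train score; such instances are
skipped and logged, as are single-class training splits). The stability
curve P(s) is the empirical CDF of S over instances, reported on a fixed
grid of 0.01 steps on [0, 1], the same binning used for the test-score
histogram. k-fold cross-validation scores can be attached per instance
as a diagnostic; the 80/20 test score is the authoritative quality
number. Binarization happens once on the full table before splitting:
thresholds are coarse 2-significant-digit quantile cuts, so they are
treated as part of the feature vocabulary rather than per-split fitted
parameters. External models (trees, boosters) plug into the identical
split protocol through the `model_hook` callback; no modelling library
is baked in.

## Synthetic generators

The planted-rule generator draws independent feature columns (Bernoulli,
or Gaussian read through a generating threshold), labels rows by an
admissible formula, flips each label independently with probability ε,
and inserts missing cells per feature (never in the target). The default
recipe emulates the shape of real screening tables: 2000 observations,
an unbalanced outcome (~27% positive before noise), three informative
markers among five distractors, and ~5% missingness on two features.
The analytic prevalence (truth-table expectation over the marginals,
mixed with ε) is exact because features are independent — which is also
the generator's main idealisation: real clinical/ecological/financial
tables have correlated features, non-Gaussian marginals and structured
missingness, so passing tests demonstrate correctness of the machinery,
not performance on any real distribution.

The Nim generator draws uniform pile configurations and labels them with
the exact game-theoretic outcome (mover wins iff the bitwise XOR of pile
sizes is nonzero), cross-checked against exhaustive minimax in tests.
The default layout is 2000 games with 3 piles of at most 7 objects,
padded with always-empty piles to 10 feature columns (an empty pile
changes nothing about the game, so the padding is semantically inert);
a per-bit Boolean layout (under which the winner becomes expressible by
small rules for few piles) is available as an option, not a default. Whether the winner is learnable by an admissible rule over
raw pile sizes is a property of the layout, left open by design.

## Numerical and degenerate-input choices

* F1 and friends are computed as exact integer-count ratios in float64;
  ties in the search are impossible to break inconsistently because the
  ordering key ends in the unique rendered string.
* Threshold comparisons on NaN cells evaluate to False but are always
  masked; masked cells can never influence a surviving score.
* `stability` requires a positive train score; constant truth tables are
  rejected by `dnf_of`/`simplify`; a single-class target or an atom-less
  dataset raises a degenerate-data error; a dataset where no subset is
  scorable returns an empty model list with a warning.
* Seeds: every random step (generators, subsampling, splits) flows from
  an explicit integer seed; instance seeds are `master + index`.

## Problem sizes in the test suite

The suite exercises the learner at deliberately desk-friendly sizes —
catalog construction is exact and takes well under a second; oracle
equivalence uses 20 random datasets of 60 rows × 12 atoms against a
naive all-pairs enumerator; noise-recovery uses 50 replicates of 2000
observations; the whole suite runs in under a minute. These sizes are a
package choice: the search scales as O(L·(NK)ⁿ), and the counting-based
inner loop makes much larger N and L practical.

## Known limitations

* The class cannot express repeated-variable logic (XOR, parity) or
  arithmetic feature interactions (products); outcomes driven by such
  structure will cap the achievable score regardless of search effort.
* Quantile thresholds are unsupervised; a true optimal cut lying far
  from every quantile will be missed unless K is raised.
* Exhaustive search over all subsets is polynomial but still heavy for
  very large NK at n = 4; subsampling L and lowering K are the intended
  relief valves (greedy/beam accelerations are out of scope).
* The stability harness evaluates the rule class itself; comparative
  claims against black-box learners require plugging those learners into
  the `model_hook` interface.
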