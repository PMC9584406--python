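# hkmlearn

Exhaustive learning of **human-computable Boolean decision rules** from
tabular data.

Many applied fields — clinical triage, screening, operations — need
decision logic that a person can carry in their head and apply at the
point of decision, without a computer. `hkmlearn` learns exactly that
class of models: Boolean rules constrained by what cognitive research
says an average person can evaluate mentally, in real time:

* operators limited to `AND`, `OR`, `NOT` and the thresholded Boolean
  `SUM` ("at least *t* of these *k* conditions hold");
* at most **4 variables**, each used at most once;
* at most **4 operators** (an *a*-ary AND/OR chain counts *a* − 1, a
  thresholded SUM counts 1, a NOT counts 1);
* non-Boolean inputs enter only through simple, memorable numeric
  thresholds (`age > 60`).

Rather than greedily growing trees or rule ensembles, the learner is
**exhaustive**: every Boolean function on *n* ≤ 4 variables is reduced to
its shortest admissible expression (via truth tables, DNF expansion and
semantically-equivalent simplification), and every (formula, variable
subset) pair is scored against the target, keeping a stack of the M best
models. The search cost factors as

    O(N, K, L, n) = S(N, K, n) × B(n) × F(n, L),    S(N, K, n) = C(NK, n)

where *N* is the raw feature count, *K* the thresholds per feature, *L*
the observation count, and B(*n*) — the number of admissible expression
classes per subset — is a small constant (84 at *n* = 4, below 100), so
the whole search is O(L·(NK)^n). Training is fully deterministic: the
same data and configuration always produce byte-identical model lists.
Missing values are never imputed; they become informative indicator atoms
and per-model coverage accounting.

## Worked example

Generate a screening-style synthetic dataset whose outcome follows the
planted rule `(marker_a AND marker_b) OR marker_c` with 10% label noise,
then learn the best rules of up to 3 variables:

```bash
hkm synth planted --obs 2000 --noise 0.1 --seed 7 --out demo.csv
hkm fit --data demo.csv --target y --n 3 --m 25 --out models.json
```

The top of `models.json` (score = F1 on the training data, `cov` = the
fraction of rows with no missing values among the rule's atoms, `ops` =
cognitive operator cost):

```
0.8455  cov=1.00  ops=2  marker_c OR (marker_a AND marker_b)
0.7868  cov=1.00  ops=1  SUM(marker_a, marker_b, marker_c) >= 2
0.7513  cov=1.00  ops=2  marker_a AND (marker_b OR marker_c)
0.7340  cov=1.00  ops=2  marker_b AND (marker_a OR marker_c)
```

The planted rule is recovered verbatim at rank 1 despite the noise; the
runners-up are near-equivalent decision logics — the learner keeps all of
them because in practice several different rules can explain an outcome
almost equally well, and the user picks the most actionable one.

Other entry points:

```bash
hkm enumerate-formulas --n 2          # admissible function classes + shortest forms
hkm evaluate --data demo.csv --target y --n 2 --n-exp 200 --seed 7 --out report.json
hkm synth nim --games 2000 --seed 1 --out nim.csv
```

`hkm evaluate` repeats seeded 80/20 train/test instances and reports the
model stability factor S = |F1_train − F1_test| / F1_train per instance
together with the empirical stability curve P(s) = Prob(S < s); the
small, hard-to-overfit rule class typically concentrates S near zero.
The Nim generator labels uniformly drawn pile positions with the exact
game-theoretic winner (mover wins iff the nim-sum of the piles is
nonzero).

The same functionality is available as a library: see
`hkmlearn.binarize`, `hkmlearn.fit`, `hkmlearn.run_experiments`,
`hkmlearn.build_catalog`, and `docs/methods.md` for the underlying
model and its assumptions.

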