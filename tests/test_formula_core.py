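import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkmlearn.errors import InputError
from hkmlearn.formula_core import (
    And,
    HKMConstraints,
    Not,
    Or,
    SumGe,
    TruthTable,
    Var,
    count_subsets,
    estimate_complexity,
    evaluate,
    is_admissible,
    operator_count,
    parse,
    render,
    truth_table,
    variable_count,
)


def _relabel(formula, mapping):
    if isinstance(formula, Var):
        return Var(mapping[formula.index])
    if isinstance(formula, Not):
        return Not(_relabel(formula.child, mapping))
    children = tuple(_relabel(c, mapping) for c in formula.children)
    if isinstance(formula, And):
        return And(children)
    if isinstance(formula, Or):
        return Or(children)
    return SumGe(children, formula.threshold)


class TestEvaluate:
    def test_and_is_elementwise_conjunction(self):
        f = And((Var(0), Var(1)))
        rows = np.array([[0, 0], [0, 1], [1, 1]], dtype=bool)
        assert evaluate(f, rows).tolist() == [False, False, True]

    def test_sum_threshold_counts_true_conditions(self):
        # "if two of the three conditions are met"
        f = SumGe((Var(0), Var(1), Var(2)), 2)
        assert evaluate(f, np.array([[1, 0, 1]], dtype=bool)).tolist() == [True]
        assert evaluate(f, np.array([[1, 0, 0]], dtype=bool)).tolist() == [False]

    def test_not_inverts(self):
        f = Not(Var(0))
        rows = np.array([[0], [1]], dtype=bool)
        assert evaluate(f, rows).tolist() == [True, False]

    def test_out_of_range_variable_rejected(self):
        with pytest.raises(InputError):
            evaluate(Var(3), np.zeros((2, 2), dtype=bool))


class TestOperatorCount:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            (And((Var(0), Var(1), Var(2), Var(3))), 3),  # chain of 3 binary ANDs
            (SumGe((Var(0), Var(1), Var(2)), 2), 1),  # one counting act
            (Or((And((Var(0), Var(1))), Not(Var(2)))), 3),
            (And((Not(Var(0)), Not(Var(1)), Not(Var(2)))), 5),
            (Not(Or((Var(0), Var(1), Var(2)))), 3),
        ],
    )
    def test_counting_convention(self, formula, expected):
        assert operator_count(formula) == expected


class TestTruthTable:
    def test_and_table(self):
        assert truth_table(And((Var(0), Var(1)))).bitstring() == "0001"

    def test_majority_of_three_has_four_true_rows(self):
        t = truth_table(SumGe((Var(0), Var(1), Var(2)), 2))
        assert t.bitstring().count("1") == 4
        # true exactly when >= 2 of the bits of the row index are set
        for r in range(8):
            assert t.value(r) == (bin(r).count("1") >= 2)

    def test_identity_table(self):
        assert truth_table(Var(0)).bitstring() == "01"

    def test_row_convention_matches_evaluate(self, catalog):
        # single-row evaluation agrees with the table bit at that assignment
        for n in catalog.sizes():
            for bits, entry in list(catalog.tables(n).items())[::7]:
                for r in range(1 << n):
                    row = [(r >> i) & 1 for i in range(n)]
                    got = evaluate(entry.formula, np.array([row], dtype=bool))[0]
                    assert got == entry.table.value(r)

    def test_permutation_and_properness(self):
        t = truth_table(And((Var(0), Not(Var(1)))))
        assert t.is_proper()
        swapped = t.permuted([1, 0])
        assert swapped == truth_table(And((Not(Var(0)), Var(1))))
        assert t.canonical_class() == swapped.canonical_class()


class TestAdmissibility:
    def test_majority_is_admissible(self):
        assert is_admissible(SumGe((Var(0), Var(1), Var(2)), 2))

    def test_five_variable_conjunction_rejected(self):
        f = And(tuple(Var(i) for i in range(5)))
        assert not is_admissible(f)

    def test_three_negated_literals_conjunction_exceeds_operator_budget(self):
        f = And((Not(Var(0)), Not(Var(1)), Not(Var(2))))
        assert operator_count(f) == 5
        assert not is_admissible(f)

    def test_repeated_variable_rejected(self):
        f = Or((Var(0), And((Var(0), Var(1)))))
        assert not is_admissible(f)

    def test_operator_whitelist(self):
        c = HKMConstraints(allowed_ops=frozenset({"AND", "OR", "NOT"}))
        assert not is_admissible(SumGe((Var(0), Var(1), Var(2)), 2), c)

    def test_sum_threshold_range_enforced(self):
        with pytest.raises(InputError):
            SumGe((Var(0), Var(1), Var(2)), 1)  # t=1 is OR
        with pytest.raises(InputError):
            SumGe((Var(0), Var(1), Var(2)), 3)  # t=arity is AND

    def test_sum_children_must_be_literals(self):
        with pytest.raises(InputError):
            SumGe((And((Var(0), Var(1))), Var(2), Var(3)), 2)


class TestSumMonotonicity:
    def test_raising_threshold_never_turns_false_row_true(self):
        for k in (3, 4):
            children = tuple(Var(i) for i in range(k))
            tables = [truth_table(SumGe(children, t)) for t in range(2, k)]
            for lo, hi in zip(tables, tables[1:]):
                for r in range(1 << k):
                    if hi.value(r):
                        assert lo.value(r)


class TestCountSubsets:
    def test_printed_search_space_size(self):
        assert count_subsets(300, 1, 3) == 4_455_100

    def test_single_full_subset(self):
        assert count_subsets(4, 1, 4) == 1

    @pytest.mark.parametrize("N,K,n", [(10, 2, 2), (5, 5, 4), (25, 1, 3), (3, 2, 1)])
    def test_matches_explicit_enumeration(self, N, K, n):
        items = range(N * K)
        explicit = sum(1 for _ in itertools.combinations(items, n))
        assert count_subsets(N, K, n) == explicit

    def test_too_few_atoms_gives_zero(self):
        assert count_subsets(1, 1, 3) == 0

    def test_invalid_arguments(self):
        with pytest.raises(InputError):
            count_subsets(0, 1, 2)
        with pytest.raises(InputError):
            count_subsets(10, 1, 5)


class TestComplexityEstimate:
    def test_product_structure_and_linearity_in_observations(self):
        est1 = estimate_complexity(20, 10, 1000, 4)
        est2 = estimate_complexity(20, 10, 2000, 4)
        assert est1.total == est1.subset_count * est1.formula_bound * est1.per_pair_cost
        assert est1.subset_count == math.comb(200, 4)
        assert est2.total == 2 * est1.total
        assert est2.subset_count == est1.subset_count
        assert est2.formula_bound == est1.formula_bound

    def test_formula_bound_is_capped_constant(self):
        est = estimate_complexity(300, 1, 100, 4)
        assert est.formula_bound <= 100


class TestGrammar:
    @pytest.mark.parametrize(
        "text",
        [
            "(x1 AND NOT x3) OR x7",
            "SUM(x1, x2, x5) >= 2",
            "NOT (x0 OR x1)",
            "x0 AND (SUM(x1, x2, NOT x3) >= 2)",
            "NOT x2",
        ],
    )
    def test_parse_accepts_grammar_examples(self, text):
        f = parse(text)
        assert variable_count(f) >= 1

    def test_render_examples(self):
        # canonical child order puts plain variables before compound children
        assert render(Or((And((Var(0), Var(1))), Var(2)))) == "x2 OR (x0 AND x1)"
        assert render(SumGe((Var(0), Var(1), Var(2)), 2)) == "SUM(x0, x1, x2) >= 2"
        assert render(And((Not(Var(3)), Var(1)))) == "x1 AND NOT x3"

    def test_rejects_malformed(self):
        for bad in ["x0 AND", "SUM(x0, x1) > 2", "(x0", "y1 OR x0", "SUM(x0, x1, x2) >= x"]:
            with pytest.raises(InputError):
                parse(bad)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(data=st.data())
    def test_round_trip_on_admissible_formulas(self, data, catalog):
        n = data.draw(st.sampled_from(catalog.sizes()))
        entries = list(catalog.tables(n).values())
        entry = data.draw(st.sampled_from(entries))
        perm = data.draw(st.permutations(range(n)))
        f = _relabel(entry.formula, dict(enumerate(perm)))
        assert parse(render(f)) == f
        # relabeling is cost-neutral
        assert operator_count(f) == entry.ops
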