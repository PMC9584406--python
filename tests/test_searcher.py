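import json

import numpy as np
import pandas as pd
import pytest

from hkmlearn.binarizer import binarize
from hkmlearn.errors import DegenerateDataError, InputError
from hkmlearn.formula_core import truth_table
from hkmlearn.searcher import (
    SearchConfig,
    fit,
    merge_model_lists,
    predict,
    score,
    score_on,
)
from hkmlearn.simplifier import build_catalog
from hkmlearn.formula_core import HKMConstraints

from conftest import random_bool_dataset
from naive_oracle import oracle_top_m


class TestScore:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert score(y, y, "f1") == 1.0
        assert score(y, y, "accuracy") == 1.0

    def test_f1_formula_arithmetic(self):
        target = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        preds = np.array([1, 1, 0, 1, 0, 0], dtype=bool)  # TP=2 FP=1 FN=1
        assert score(preds, target, "f1") == pytest.approx(2 / 3)
        assert score(preds, target, "precision") == pytest.approx(2 / 3)
        assert score(preds, target, "recall") == pytest.approx(2 / 3)
        assert score(preds, target, "accuracy") == pytest.approx(4 / 6)

    def test_all_negative_predictions_score_zero(self):
        target = np.array([1, 0, 1], dtype=bool)
        assert score(np.zeros(3, dtype=bool), target, "f1") == 0.0

    def test_matches_sklearn(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        rng = np.random.default_rng(0)
        for _ in range(10):
            y = rng.random(50) < 0.4
            p = rng.random(50) < 0.5
            assert score(p, y, "f1") == pytest.approx(f1_score(y, p, zero_division=0))
            assert score(p, y, "precision") == pytest.approx(
                precision_score(y, p, zero_division=0)
            )
            assert score(p, y, "recall") == pytest.approx(
                recall_score(y, p, zero_division=0)
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            score(np.zeros(3, dtype=bool), np.zeros(4, dtype=bool))


class TestFit:
    def test_atom_identical_to_target_wins_with_perfect_score(self):
        rng = np.random.default_rng(1)
        y = rng.random(60) < 0.4
        df = pd.DataFrame(
            {
                "hit": y.astype(int),
                "junk": (rng.random(60) < 0.5).astype(int),
                "y": y.astype(int),
            }
        )
        models = fit(binarize(df, "y"), SearchConfig(n_values=(1,), m=5))
        assert models[0].rendering == "hit"
        assert models[0].score == 1.0

    def test_planted_rule_recovered_exactly_on_noiseless_data(self, planted_noiseless):
        spec, ds = planted_noiseless
        models = fit(ds, SearchConfig(n_values=(1, 2, 3), m=10))
        best = models[0]
        assert best.score == 1.0
        assert truth_table(best.formula) == truth_table(spec.formula)
        assert set(best.atom_names) == set(spec.rule_features)

    def test_single_class_target_rejected(self):
        df = pd.DataFrame({"a": [1, 0, 1], "y": [1, 1, 1]})
        with pytest.raises(DegenerateDataError):
            fit(binarize(df, "y"))

    def test_no_scorable_subset_yields_empty_result_with_warning(self):
        # a single source feature cannot supply a 2-atom subset (atoms of
        # one source are siblings), so nothing can be scored
        df = pd.DataFrame(
            {"a": np.r_[np.linspace(0, 1, 25), [None] * 5], "y": [0, 1] * 15}
        )
        ds = binarize(df, "y", k=2)
        with pytest.warns(UserWarning, match="no candidate"):
            out = fit(ds, SearchConfig(n_values=(2,), min_coverage=0.95))
        assert out == []

    def test_determinism_byte_identical_model_lists(self):
        ds = random_bool_dataset(7)
        config = SearchConfig(n_values=(1, 2, 3), m=15)
        a = fit(ds, config)
        b = fit(ds, config)
        assert json.dumps([m.to_dict() for m in a]) == json.dumps(
            [m.to_dict() for m in b]
        )

    def test_subsample_is_seeded_and_reproducible(self):
        ds = random_bool_dataset(9, n_rows=200)
        config = SearchConfig(n_values=(1, 2), m=5, subsample=120, seed=42)
        assert [m.to_dict() for m in fit(ds, config)] == [
            m.to_dict() for m in fit(ds, config)
        ]

    def test_free_threshold_negation_reaches_flipped_directions(self):
        # target = (a <= 30) AND (b <= 4): needs two negated thresholds,
        # 5 strict operators, but direction flips are free on thresholds
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 100, 300).round(1)
        b = rng.uniform(0, 10, 300).round(2)
        y = (a <= 30) & (b <= 4)
        y[:4] = [True, False, True, False]  # guard both classes
        df = pd.DataFrame({"a": a, "b": b, "y": y.astype(int)})
        ds = binarize(df, "y", k=3)
        models = fit(ds, SearchConfig(n_values=(2,), m=5))
        best = models[0]
        assert best.score > 0.75
        assert "<=" in best.rendering
        assert best.n_ops <= 4


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_top_m_matches_naive_enumeration(self, seed, catalog):
        ds = random_bool_dataset(seed, n_rows=60, n_atoms=7)
        m = 12
        models = fit(ds, SearchConfig(n_values=(1, 2, 3), m=m))

        def renderer(n, bits, subset):
            from hkmlearn.formula_core import TruthTable
            from hkmlearn.searcher import render_with_atoms

            entry = catalog.lookup(TruthTable(n, bits))
            return render_with_atoms(entry.formula, [ds.atoms[j] for j in subset])

        expected = oracle_top_m(
            ds.X, ds.target, list(ds.source_ids), (1, 2, 3), m, renderer
        )
        assert len(models) == len(expected)
        for got, exp in zip(models, expected):
            exp_score, exp_n, exp_ops, exp_subset, exp_bits, exp_render = exp
            assert got.score == exp_score
            assert got.n_vars == exp_n
            assert got.n_ops == exp_ops
            assert got.atom_indices == exp_subset
            assert truth_table(got.formula).bits == exp_bits
            assert got.rendering == exp_render


class TestMergeAndPredict:
    def test_merge_is_partition_independent(self):
        ds = random_bool_dataset(4)
        config = SearchConfig(n_values=(1, 2), m=8)
        full = fit(ds, config)
        # simulate a partitioned subset loop by splitting sizes across runs
        part1 = fit(ds, SearchConfig(n_values=(1,), m=8))
        part2 = fit(ds, SearchConfig(n_values=(2,), m=8))
        merged_ab = merge_model_lists([part1, part2], 8)
        merged_ba = merge_model_lists([part2, part1], 8)
        assert [m.to_dict() for m in merged_ab] == [m.to_dict() for m in full]
        assert [m.to_dict() for m in merged_ba] == [m.to_dict() for m in full]

    def test_predict_reproduces_training_atom(self):
        ds = random_bool_dataset(2)
        model = fit(ds, SearchConfig(n_values=(1,), m=1))[0]
        preds, abstain = predict(model, ds)
        assert not abstain.any()
        j = model.atom_indices[0]
        col = ds.X[:, j]
        # the top single-atom model is the atom itself or its negation
        assert np.array_equal(preds, col) or np.array_equal(preds, ~col)

    def test_predict_abstains_on_masked_rows(self):
        df = pd.DataFrame(
            {"v": [1.0, 2.0, None, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0],
             "y": [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]}
        )
        ds = binarize(df, "y", k=1)
        model = fit(ds, SearchConfig(n_values=(1,), min_coverage=0.5, m=1))[0]
        if model.atom_names[0] != "v is missing":
            preds, abstain = predict(model, ds)
            assert abstain.tolist() == df["v"].isna().tolist()

    def test_predict_on_fresh_noiseless_draws_is_perfect(self, planted_noiseless):
        from hkmlearn.synthetic import default_planted_spec, generate_planted

        spec, ds = planted_noiseless
        model = fit(ds, SearchConfig(n_values=(1, 2, 3), m=1))[0]
        fresh_spec = default_planted_spec(seed=99, n_obs=500, noise=0.0, missing_rate=0.0)
        fresh = binarize(generate_planted(fresh_spec), "y", k=2)
        assert score_on(model, fresh) == 1.0

    def test_unresolvable_atom_rejected(self):
        ds = random_bool_dataset(2)
        other = random_bool_dataset(3, n_atoms=2)
        model = fit(ds, SearchConfig(n_values=(3,), m=1))[0]
        with pytest.raises(InputError):
            predict(model, other)
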