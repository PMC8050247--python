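import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metmix import (
    DecompositionProblem,
    MixtureDecomposer,
    cross_entropy,
    lambda_max,
    lambda_path_to_k,
    make_complex,
    make_library,
    objective,
    overlap_score,
    predict_ingredients,
    random_baseline,
    sigmoid,
    solve_fixed_lambda,
    write_result,
    read_result,
)
from metmix.decomposition import balance_weights
from metmix.validation import grid_search_minimum

from conftest import random_decomposition_problem

LN2 = float(np.log(2))


class TestElementaryFunctions:
    def test_sigmoid_at_zero_is_half(self):
        assert sigmoid(0.0) == 0.5

    @settings(max_examples=50, derandomize=True)
    @given(z=st.floats(-700, 700))
    def test_sigmoid_symmetry(self, z):
        assert sigmoid(-z) == pytest.approx(1.0 - sigmoid(z), abs=1e-12)

    def test_sigmoid_saturates_without_overflow(self):
        v = sigmoid(1000.0)
        assert 1.0 - 1e-12 < v <= 1.0
        assert sigmoid(-1000.0) >= 0.0

    @pytest.mark.parametrize("y", [0, 1])
    def test_cross_entropy_at_half_is_ln2(self, y):
        assert cross_entropy(y, 0.5) == pytest.approx(LN2, abs=1e-15)

    def test_cross_entropy_vanishes_at_confident_truth(self):
        assert cross_entropy(1, 1 - 1e-13) < 1e-10
        assert cross_entropy(1, 0.9) > cross_entropy(1, 0.99)

    def test_cross_entropy_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cross_entropy(1, 1.5)


class TestBalanceWeights:
    def test_weight_mass_two_for_mixed_vector(self):
        w = balance_weights(np.array([1, 0, 0, 0, 1]))
        assert w.sum() == pytest.approx(2.0, abs=1e-14)
        assert w[0] == pytest.approx(1 / 2) and w[1] == pytest.approx(1 / 3)

    def test_weight_mass_one_for_constant_vector(self):
        assert balance_weights(np.ones(7)).sum() == pytest.approx(1.0)


class TestObjective:
    def test_zero_vector_gives_two_ln2(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = random_decomposition_problem(rng, d=3, n_rows=30)
            assert objective(np.zeros(3), p) == pytest.approx(2 * LN2, abs=1e-12)

    def test_zero_vector_value_independent_of_lambda(self):
        rng = np.random.default_rng(2)
        p = random_decomposition_problem(rng, d=2)
        p2 = DecompositionProblem(D=p.D, c=p.c, lam=p.lam * 17)
        x0 = np.zeros(2)
        assert objective(x0, p) == objective(x0, p2)

    def test_doubling_lambda_adds_lambda_l1(self):
        rng = np.random.default_rng(3)
        p = random_decomposition_problem(rng, d=3)
        x = rng.normal(size=3)
        p2 = DecompositionProblem(D=p.D, c=p.c, lam=2 * p.lam)
        assert objective(x, p2) - objective(x, p) == pytest.approx(
            p.lam * np.abs(x).sum(), rel=1e-12
        )

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(4)
        p = random_decomposition_problem(rng, d=2)
        with pytest.raises(ValueError):
            objective(np.zeros(3), p)

    def test_appending_empty_features_moves_weights_not_minimizer(self):
        # extra rows with c=0 and all-zero D contribute a constant CE term:
        # the weight of the 0-class changes but the minimizer does not
        rng = np.random.default_rng(5)
        p = random_decomposition_problem(rng, d=2)
        D2 = np.vstack([p.D, np.zeros((15, 2))])
        c2 = np.concatenate([p.c, np.zeros(15)])
        p2 = DecompositionProblem(D=D2, c=c2, lam=p.lam)
        assert p2.weights.sum() == pytest.approx(2.0)
        x1 = solve_fixed_lambda(p)
        x2 = solve_fixed_lambda(p2)
        assert np.allclose(x1, x2, atol=5e-4)


class TestSolver:
    def test_above_lambda_max_solution_is_exactly_zero(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            p = random_decomposition_problem(rng, d=3)
            lm = lambda_max(p)
            sol = solve_fixed_lambda(
                DecompositionProblem(D=p.D, c=p.c, lam=lm * 1.0001)
            )
            assert np.all(sol == 0.0)

    def test_just_below_lambda_max_solution_is_nonzero(self):
        rng = np.random.default_rng(7)
        p = random_decomposition_problem(rng, d=3)
        lm = lambda_max(p)
        sol = solve_fixed_lambda(DecompositionProblem(D=p.D, c=p.c, lam=lm * 0.5))
        assert np.abs(sol).max() > 0

    def test_solution_never_worse_than_zero(self):
        rng = np.random.default_rng(8)
        for d in (1, 2, 3, 4):
            p = random_decomposition_problem(rng, d=d)
            assert objective(solve_fixed_lambda(p), p) <= objective(
                np.zeros(d), p
            ) + 1e-12

    def test_disjoint_two_ingredient_toy_selects_the_right_one(self):
        # D columns with disjoint supports; c equals ingredient 1's support.
        # Unconstrained: the present ingredient gets a large positive
        # coefficient and the absent one a *negative* coefficient (negative
        # evidence also reduces cross-entropy on the 0-class); in the
        # nonnegative mode the absent ingredient is pinned at exactly 0.
        D = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        c = np.array([1.0, 1.0, 0.0, 0.0])
        p = DecompositionProblem(D=D, c=c, lam=0.02)
        x = solve_fixed_lambda(p)
        xg, fg = grid_search_minimum(p)
        assert objective(x, p) <= fg + 1e-3
        assert x[0] > 0.5 and x[1] < x[0]
        p_nn = DecompositionProblem(D=D, c=c, lam=0.02, nonneg=True)
        x_nn = solve_fixed_lambda(p_nn)
        assert x_nn[0] > 0.5 and x_nn[1] == 0.0

    @pytest.mark.parametrize("d", [2, 3])
    def test_matches_grid_search_oracle(self, d):
        rng = np.random.default_rng(100 + d)
        for _ in range(5):
            p = random_decomposition_problem(rng, d=d)
            x = solve_fixed_lambda(p)
            _, fg = grid_search_minimum(p)
            assert abs(objective(x, p) - fg) <= 1e-3

    def test_deterministic_resolve(self):
        rng = np.random.default_rng(9)
        p = random_decomposition_problem(rng, d=3)
        x1 = solve_fixed_lambda(p)
        x2 = solve_fixed_lambda(p)
        assert np.array_equal(x1, x2)

    def test_nonneg_mode_stays_nonnegative(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            base = random_decomposition_problem(rng, d=3)
            p = DecompositionProblem(D=base.D, c=base.c, lam=base.lam, nonneg=True)
            assert np.all(solve_fixed_lambda(p) >= 0)


class TestLambdaPath:
    def test_union_of_five_disjoint_ingredients_recovered(self):
        lib = make_library(800, 10, 20, overlap=0.0, seed=21)
        c, truth = make_complex(lib, 5, seed=22)
        res = predict_ingredients(lib, c, k=5)
        assert sorted(res.selected) == sorted(truth.true_ingredients)
        assert not res.fallback and res.nonzero_count == 5

    def test_single_ingredient_k1(self):
        lib = make_library(200, 8, 15, overlap=0.0, seed=23)
        c = lib.column(lib.sample_ids[3]).astype(float)
        res = predict_ingredients(lib, c, k=1)
        assert res.selected == [lib.sample_ids[3]]

    def test_all_zero_sample_is_degenerate(self):
        lib = make_library(100, 6, 10, seed=24)
        res = predict_ingredients(lib, np.zeros(100), k=3)
        assert res.degenerate and res.selected == [] and np.all(res.x == 0)

    def test_k_exceeding_candidates_raises(self):
        lib = make_library(100, 4, 10, seed=25)
        with pytest.raises(ValueError, match="exceeds"):
            predict_ingredients(lib, lib.column("ing000"), k=5)

    def test_path_counts_weakly_decrease_with_lambda(self):
        lib = make_library(400, 20, 15, overlap=0.1, seed=26)
        c, _ = make_complex(lib, 4, dropout=0.05, spurious=0.01, seed=27)
        res = predict_ingredients(lib, c, k=4)
        by_lambda = sorted(res.path_log)  # ascending lambda
        counts = [cnt for _, cnt in by_lambda]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_repeated_invocation_bit_identical(self):
        lib = make_library(300, 12, 12, seed=28)
        c, _ = make_complex(lib, 3, seed=29)
        r1 = predict_ingredients(lib, c, k=3)
        r2 = predict_ingredients(lib, c, k=3)
        assert np.array_equal(r1.x, r2.x) and r1.path_log == r2.path_log

    def test_model_object_equivalent_to_wrapper(self):
        lib = make_library(300, 12, 12, seed=30)
        c, _ = make_complex(lib, 3, seed=31)
        assert MixtureDecomposer(lib, c).fit(k=3) == predict_ingredients(lib, c, k=3)

    def test_sample_with_unknown_features_aligns(self):
        from metmix import FeatureMatrix

        lib = make_library(120, 6, 10, seed=32)
        c, truth = make_complex(lib, 2, seed=33)
        extra = FeatureMatrix(
            np.concatenate([c, [1, 1]])[:, None],
            lib.feature_ids + ["novel1", "novel2"],
            ["dish"],
        )
        res = predict_ingredients(lib, extra, k=2)
        assert sorted(res.selected) == sorted(truth.true_ingredients)


class TestOverlapAndBaseline:
    @pytest.mark.parametrize(
        "pred,ann,expected",
        [
            (list("abcde"), list("abcde"), 5),
            (list("abcde"), list("xyz"), 0),
            (list("abcde"), list("cef"), 2),
        ],
    )
    def test_overlap_counts_intersection(self, pred, ann, expected):
        assert overlap_score(pred, ann) == expected

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            overlap_score([], ["a"])

    def test_baseline_full_library_and_reproducibility(self):
        lib = make_library(100, 6, 10, seed=40)
        assert random_baseline(lib, k=6, seed=1) == set(lib.sample_ids)
        assert random_baseline(lib, k=3, seed=5) == random_baseline(lib, k=3, seed=5)
        with pytest.raises(ValueError):
            random_baseline(lib, k=7, seed=1)

    def test_baseline_mean_matches_hypergeometric(self):
        lib = make_library(200, 20, 8, seed=41)
        annotated = set(lib.sample_ids[:4])  # m = 4, n = 20, k = 5
        draws = [
            len(random_baseline(lib, k=5, seed=s) & annotated) for s in range(400)
        ]
        expect = 5 * 4 / 20
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expect) < 3 * se + 1e-9


class TestResultSerialization:
    @pytest.mark.parametrize("fmt", ["json", "tsv"])
    def test_roundtrip_equal(self, tmp_path, fmt):
        lib = make_library(200, 8, 12, seed=50)
        c, _ = make_complex(lib, 3, seed=51)
        res = predict_ingredients(lib, c, k=3)
        path = tmp_path / f"res.{fmt}"
        write_result(res, path, format=fmt)
        assert read_result(path, format=fmt) == res

    def test_empty_selection_roundtrips(self, tmp_path):
        lib = make_library(100, 5, 10, seed=52)
        res = predict_ingredients(lib, np.zeros(100), k=2)
        path = tmp_path / "empty.json"
        write_result(res, path)
        back = read_result(path)
        assert back.selected == [] and back.degenerate

    def test_tsv_has_one_row_per_selected_ingredient(self, tmp_path):
        lib = make_library(200, 8, 12, seed=53)
        c, _ = make_complex(lib, 3, seed=54)
        res = predict_ingredients(lib, c, k=3)
        path = tmp_path / "res.tsv"
        write_result(res, path, format="tsv")
        lines = [l for l in path.read_text().splitlines() if l and not l.startswith("#")]
        assert lines[0].split("\t") == ["ingredient_id", "abundance"]
        assert len(lines) - 1 == len(res.selected) == 3
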