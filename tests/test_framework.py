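"""The multiple-holdout framework: splits, stability metrics, grid search,
joint selection, permutation inference, and the end-to-end deflation loop."""
import numpy as np
import pytest

from conftest import make_paired
from crosslatent import (
    EffectModel,
    GeneratorSpec,
    RunConfig,
    SparsityPair,
    choose_best_split,
    corrected_overlap,
    decide_significance,
    generate,
    grid_search,
    holdout_permutation_test,
    make_splits,
    out_of_sample_correlation,
    run_framework,
    select_hyperparams,
    weight_correlation_stability,
)
from crosslatent.config import ConfigError
from crosslatent.framework import GridCell, SplsBackend


class TestMakeSplits:
    def test_sizes_match_the_80_20_and_50_split_scheme(self):
        cfg = RunConfig(seed=1)
        scheme = make_splits(345, cfg)
        assert len(scheme.outer_splits) == 10
        for opt, hold in scheme.outer_splits:
            assert (len(opt), len(hold)) == (276, 69)
        for pairs in scheme.inner_splits:
            assert len(pairs) == 50
            for train, val in pairs:
                assert (len(train), len(val)) == (221, 55)

    def test_partition_invariants(self):
        cfg = RunConfig(n_outer_splits=4, n_inner_splits=6, seed=3)
        scheme = make_splits(57, cfg)
        for (opt, hold), pairs in zip(scheme.outer_splits, scheme.inner_splits):
            assert not set(opt) & set(hold)
            assert set(opt) | set(hold) == set(range(57))
            for train, val in pairs:
                assert not set(train) & set(val)
                assert set(train) | set(val) == set(opt)

    def test_same_seed_reproduces_indices(self):
        cfg = RunConfig(n_outer_splits=3, n_inner_splits=4, seed=11)
        a, b = make_splits(60, cfg), make_splits(60, cfg)
        for (oa, ha), (ob, hb) in zip(a.outer_splits, b.outer_splits):
            assert np.array_equal(oa, ob) and np.array_equal(ha, hb)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ConfigError):
            make_splits(9, RunConfig())
        with pytest.raises(ConfigError):
            make_splits(20, RunConfig(holdout_fraction=0.05))


class TestStabilityMetrics:
    def test_identical_supports_score_one(self):
        assert corrected_overlap([{1, 2}, {1, 2}, {1, 2}], 10) == pytest.approx(1.0)

    def test_disjoint_supports_worked_example(self):
        # (0 - 0.4) / (2 - 0.4) = -0.25
        assert corrected_overlap([{1, 2}, {3, 4}], 10) == pytest.approx(-0.25)

    def test_empty_or_full_supports_contribute_zero(self):
        assert corrected_overlap([set(), {1, 2}], 10) == pytest.approx(0.0)
        assert corrected_overlap([set(range(10)), {1, 2}], 10) == pytest.approx(0.0)

    def test_random_supports_average_near_zero(self):
        rng = np.random.default_rng(0)
        d, k = 200, 10
        supports = [set(rng.choice(d, size=k, replace=False).tolist()) for _ in range(46)]
        # 46 sets -> 1035 pairs
        assert abs(corrected_overlap(supports, d)) < 0.05

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            corrected_overlap([{1}], 5)

    def test_weight_stability_identical_and_sign_flipped(self, rng):
        w = rng.standard_normal(30)
        assert weight_correlation_stability([w, w]) == pytest.approx(1.0)
        assert weight_correlation_stability([w, -w]) == pytest.approx(1.0)

    def test_weight_stability_independent_vectors_low(self):
        rng = np.random.default_rng(5)
        ws = [rng.standard_normal(1000) for _ in range(12)]
        assert weight_correlation_stability(ws) < 0.1

    def test_zero_variance_vector_contributes_zero(self, rng):
        w = rng.standard_normal(20)
        assert weight_correlation_stability([w, np.zeros(20)]) == pytest.approx(0.0)


class TestOutOfSampleCorrelation:
    def _model(self, p, q):
        u = np.zeros(p)
        u[0] = 1.0
        v = np.zeros(q)
        v[0] = 1.0
        return EffectModel(u, v, SparsityPair(1.0, 1.0), 1.0, 1, True)

    def test_equal_and_opposite_scores(self, rng):
        m = self._model(3, 3)
        x = rng.standard_normal((10, 3))
        y = np.zeros((10, 3))
        y[:, 0] = x[:, 0]
        assert out_of_sample_correlation(m, x, y) == pytest.approx(1.0)
        y[:, 0] = -x[:, 0]
        assert out_of_sample_correlation(m, x, y) == pytest.approx(-1.0)

    def test_independent_views_near_zero(self):
        rng = np.random.default_rng(8)
        m = self._model(4, 4)
        x, y = rng.standard_normal((1000, 4)), rng.standard_normal((1000, 4))
        assert abs(out_of_sample_correlation(m, x, y)) < 0.1

    def test_degenerate_scores_return_zero(self, rng):
        m = self._model(3, 3)
        x = rng.standard_normal((10, 3))
        y = np.ones((10, 3))
        assert out_of_sample_correlation(m, x, y) == 0.0


class TestGridSearchAndSelection:
    def _inner(self, n, k=5, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(k):
            perm = rng.permutation(n)
            out.append((np.sort(perm[n // 5 :]), np.sort(perm[: n // 5])))
        return out

    def test_single_cell_grid_forces_selection(self, rng):
        x, y = rng.standard_normal((50, 6)), rng.standard_normal((50, 6))
        backend = SplsBackend()
        cells = [SparsityPair(2.0, 2.0)]
        grid = grid_search(x, y, self._inner(50), cells, backend)
        assert len(grid) == 1
        assert select_hyperparams(grid, backend).hyperparams == cells[0]

    def test_duplicate_cells_get_identical_statistics(self, rng):
        x, y = rng.standard_normal((50, 6)), rng.standard_normal((50, 6))
        backend = SplsBackend()
        cells = [SparsityPair(2.0, 2.0), SparsityPair(2.0, 2.0)]
        grid = grid_search(x, y, self._inner(50), cells, backend)
        assert grid[0].mean_validation_correlation == pytest.approx(
            grid[1].mean_validation_correlation, abs=1e-12
        )
        assert grid[0].stability == pytest.approx(grid[1].stability, abs=1e-12)

    def test_dominating_cell_selected(self):
        cells = [
            GridCell(SparsityPair(2.0, 2.0), 0.9, 0.9),
            GridCell(SparsityPair(3.0, 3.0), 0.5, 0.5),
        ]
        assert select_hyperparams(cells).mean_validation_correlation == 0.9

    def test_rank_sum_arithmetic(self):
        # A ranks (1,3), B ranks (2,1), C ranks (3,2): B wins with sum 3
        cells = [
            GridCell(SparsityPair(2.0, 2.0), 0.9, 0.5),
            GridCell(SparsityPair(2.5, 2.5), 0.8, 0.9),
            GridCell(SparsityPair(3.0, 3.0), 0.7, 0.8),
        ]
        chosen = select_hyperparams(cells)
        assert chosen.mean_validation_correlation == 0.8
        assert chosen.rank_sum == 3.0

    def test_exact_tie_prefers_more_regularized(self):
        cells = [
            GridCell(SparsityPair(3.0, 3.0), 0.8, 0.6),
            GridCell(SparsityPair(1.5, 1.5), 0.8, 0.6),
        ]
        chosen = select_hyperparams(cells, SplsBackend())
        assert chosen.hyperparams.c_u == 1.5

    def test_no_valid_cells_raises(self):
        from crosslatent.framework import FrameworkError

        bad = [GridCell(SparsityPair(2.0, 2.0), float("nan"), float("nan"), valid=False)]
        with pytest.raises(FrameworkError):
            select_hyperparams(bad)

    def test_true_sparsity_more_stable_than_least_sparse(self):
        """On sparse-truth data, the near-true sparsity cell is more stable
        across inner fits than the unconstrained cell, most of the time."""
        wins = 0
        for seed in range(10):
            spec = GeneratorSpec(
                n=150, p=20, q=20, n_effects=1, support_fraction=0.15,
                effect_strengths=(3.0,), noise_sd=1.0, seed=seed,
            )
            data, _ = generate(spec)
            x = data.x.values - data.x.values.mean(0)
            y = data.y.values - data.y.values.mean(0)
            backend = SplsBackend()
            true_c = np.sqrt(3)  # L1 norm of a 3-sparse equal-magnitude unit vector
            cells = [
                SparsityPair(true_c, true_c),
                SparsityPair(np.sqrt(20), np.sqrt(20)),
            ]
            grid = grid_search(x, y, self._inner(150, k=10, seed=seed), cells, backend)
            if grid[0].stability > grid[1].stability:
                wins += 1
        assert wins >= 8


class TestPermutationTest:
    def _fit_null(self, seed, n=60, p=6, q=6):
        rng = np.random.default_rng(seed)
        xt, yt = rng.standard_normal((n, p)), rng.standard_normal((n, q))
        from crosslatent import spls_fit

        model = spls_fit(xt - xt.mean(0), yt - yt.mean(0), SparsityPair(2.0, 2.0))
        return model, rng

    def test_extreme_observed_correlation_gives_minimal_p(self, rng):
        u = np.zeros(3)
        u[0] = 1.0
        model = EffectModel(u, u.copy(), SparsityPair(1.0, 1.0), 1.0, 1, True)
        x = rng.standard_normal((40, 3))
        y = x.copy()  # perfectly paired scores
        r, p = holdout_permutation_test(model, x, y, 199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_constant_y_scores_give_p_one(self, rng):
        model, _ = self._fit_null(0)
        x = rng.standard_normal((20, 6))
        y = np.ones((20, 6))
        r, p = holdout_permutation_test(model, x, y, 199, seed=0)
        assert p == 1.0

    def test_tiny_holdout_rejected(self, rng):
        model, _ = self._fit_null(1)
        with pytest.raises(ValueError):
            holdout_permutation_test(
                model, rng.standard_normal((4, 6)), rng.standard_normal((4, 6)), 199, 0
            )

    def test_p_values_uniformly_distributed_under_null(self):
        """Under independence the permutation p-value is (sub)uniform: the
        rejection rate at several thresholds stays near the threshold."""
        ps = []
        for seed in range(200):
            model, rng = self._fit_null(seed)
            xh, yh = rng.standard_normal((50, 6)), rng.standard_normal((50, 6))
            _, p = holdout_permutation_test(model, xh, yh, 99, seed=seed)
            ps.append(p)
        ps = np.array(ps)
        for thresh in (0.1, 0.25, 0.5):
            assert abs(np.mean(ps <= thresh) - thresh) < 0.09


class TestDecisionRules:
    def test_bonferroni_worked_examples(self):
        p = [0.001, 0.4, 0.3, 0.5, 0.2, 0.9, 0.8, 0.7, 0.6, 0.45]
        assert decide_significance(p, 0.05)[0] is True
        p = [0.006, 0.4, 0.3, 0.5, 0.2, 0.9, 0.8, 0.7, 0.6, 0.45]
        assert decide_significance(p, 0.05)[0] is False
        assert decide_significance([0.5] * 10, 0.05) == (False, 0)

    def test_majority_rule(self):
        p = [0.01, 0.02, 0.03, 0.6, 0.7]
        assert decide_significance(p, 0.05, rule="majority") == (True, 3)
        assert decide_significance([0.01, 0.6, 0.7, 0.8, 0.9], 0.05, "majority")[0] is False

    def test_best_split_dominance_and_tie_break(self):
        assert choose_best_split([0.9, 0.2, 0.1], [0.8, 0.3, 0.2]) == 0
        # ranks (1,2) vs (2,1): equal sums, higher holdout correlation wins
        assert choose_best_split([0.9, 0.5], [0.3, 0.7]) == 0
        assert choose_best_split([0.4], [0.2]) == 0


class TestRunFramework:
    @pytest.fixture(scope="class")
    def small_config(self):
        return RunConfig(
            model="spls", n_outer_splits=3, n_inner_splits=5, n_permutations=99,
            grid_x=[1.5, 3.0], grid_y=[1.5, 3.0], max_effects=3, seed=17,
        )

    def test_one_planted_effect_found_then_loop_stops(self, small_config):
        spec = GeneratorSpec(
            n=100, p=12, q=12, n_effects=1, support_fraction=0.25,
            effect_strengths=(3.0,), noise_sd=1.0, seed=5,
        )
        data, _ = generate(spec)
        results = run_framework(data, small_config)
        assert results[0].significant
        assert not results[-1].significant
        assert len(results) <= 3

    def test_max_effects_caps_extraction(self):
        spec = GeneratorSpec(
            n=100, p=12, q=12, n_effects=2, support_fraction=0.2,
            effect_strengths=(3.0, 2.0), noise_sd=1.0, seed=6,
        )
        data, _ = generate(spec)
        cfg = RunConfig(
            model="spls", n_outer_splits=3, n_inner_splits=5, n_permutations=99,
            grid_x=[2.0], grid_y=[2.0], max_effects=1, seed=2,
        )
        results = run_framework(data, cfg)
        assert len(results) == 1

    def test_identical_seeds_give_identical_results(self, small_config):
        spec = GeneratorSpec(n=80, p=10, q=10, seed=9, effect_strengths=(2.5,))
        data, _ = generate(spec)
        a = run_framework(data, small_config)
        b = run_framework(data, small_config)
        for ra, rb in zip(a, b):
            assert ra.p_values == rb.p_values
            assert ra.holdout_correlations == rb.holdout_correlations
            for sa, sb in zip(ra.per_split, rb.per_split):
                assert np.array_equal(sa.model.u, sb.model.u)

    def test_confounds_handled_out_of_sample(self):
        """A shared confound alone must not manufacture a significant effect
        when it is supplied to the framework."""
        spec = GeneratorSpec(
            n=120, p=10, q=10, n_effects=0, effect_strengths=(),
            noise_sd=1.0, confound_strength=3.0, n_confounds=1, seed=13,
        )
        data, _ = generate(spec)
        cfg = RunConfig(
            model="spls", n_outer_splits=3, n_inner_splits=5, n_permutations=199,
            grid_x=[2.0, 3.0], grid_y=[2.0, 3.0], max_effects=1, seed=4,
        )
        results = run_framework(data, cfg)
        assert not results[0].significant

    def test_kcca_branch_runs_end_to_end(self):
        spec = GeneratorSpec(
            n=90, p=8, q=8, n_effects=1, support_fraction=0.5,
            effect_strengths=(3.0,), noise_sd=1.0, seed=3,
        )
        data, _ = generate(spec)
        cfg = RunConfig(
            model="kcca", n_outer_splits=3, n_inner_splits=5, n_permutations=99,
            grid_x=[0.0, 0.5, 1.0], grid_y=[0.0, 0.5, 1.0], max_effects=1, seed=8,
        )
        results = run_framework(data, cfg)
        assert results[0].significant
        assert all(abs(np.linalg.norm(s.model.u) - 1) < 1e-8 for s in results[0].per_split)
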