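"""Nested-CV machinery: metrics, tuning, leakage, selection, permutation."""

import math

import numpy as np
import pytest

from splsmorph.validation import (
    NestedCvConfig,
    _cap_grid,
    _inner_loo_mse_fast_k1,
    _inner_loo_mse_naive,
    cv_bic,
    default_keepx_grid,
    evaluate,
    outer_loocv,
    permutation_test,
    q_squared,
    r_squared_cv,
    rmsep,
    select_components,
    tune_keepx_inner,
)

from conftest import standardize


class TestMetrics:
    def test_rmsep_values(self):
        assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0
        # residuals (3, 4): sqrt(25/2)
        assert rmsep([3.0, 4.0], [0.0, 0.0]) == pytest.approx(
            math.sqrt(12.5), abs=1e-12
        )
        # constant residual c -> |c|
        assert rmsep([5.0, 6.0, 7.0], [3.0, 4.0, 5.0]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            rmsep([1.0], [1.0, 2.0])

    def test_q_squared_baseline_perfect_and_printed_example(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert q_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)
        assert q_squared(y, y) == pytest.approx(1.0)
        assert q_squared(y, np.ones(4)) == pytest.approx(-0.2, abs=1e-12)
        with pytest.raises(ValueError):
            q_squared(np.ones(4), y)

    def test_r_squared_affine_invariance_and_sign_blindness(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        assert r_squared_cv(y, 2 * y + 7) == pytest.approx(1.0)
        # anti-correlated predictions still give r^2 = 1
        assert r_squared_cv(y, -y) == pytest.approx(1.0)

    def test_r_squared_oracle_on_textbook_formula(self):
        y_obs = np.array([1.0, 2.0, 3.0, 4.0])
        y_pred = np.array([1.0, 2.0, 3.0, 100.0])
        a, b = y_obs - y_obs.mean(), y_pred - y_pred.mean()
        r = (a @ b) / math.sqrt((a @ a) * (b @ b))
        assert r_squared_cv(y_obs, y_pred) == pytest.approx(r**2, abs=1e-12)

    def test_r_squared_constant_input_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            out = r_squared_cv([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert math.isnan(out)


class TestCvBic:
    def test_penalty_only_when_rss_equals_n(self):
        # RSS/n = 1 so only the component penalty remains: 1 * log(62)
        assert cv_bic(np.ones(62), 62, 1) == pytest.approx(math.log(62), abs=1e-12)

    def test_equal_residuals_identity(self):
        e = 0.7
        for k in (1, 3):
            assert cv_bic(np.full(10, e), 10, k) == pytest.approx(
                10 * math.log(e**2) + k * math.log(10), abs=1e-12
            )

    def test_printed_reference_value(self):
        # n=62, RSS=620, k=2: 62 log 10 + 2 log 62
        resid = np.full(62, math.sqrt(10.0))
        expected = 62 * math.log(10.0) + 2 * math.log(62.0)
        assert cv_bic(resid, 62, 2) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(151.015, abs=5e-3)

    def test_zero_rss_guard(self):
        with pytest.warns(UserWarning):
            assert cv_bic(np.zeros(5), 5, 1) == float("-inf")


class TestKeepxTuning:
    def test_grid_capped_at_retained_count_with_cap_appended(self):
        assert _cap_grid([5, 10, 15, 20], 12) == [5, 10, 12]
        assert _cap_grid([5, 10], 10) == [5, 10]
        assert default_keepx_grid(23) == [5, 10, 15, 20]

    def test_full_budget_wins_when_y_needs_all_features(self, rng):
        # y exactly linear in all 10 features: only the dense budget fits it
        n, p = 24, 10
        X = rng.normal(size=(n, p))
        beta = rng.uniform(1.0, 2.0, size=p) * rng.choice([-1, 1], size=p)
        y = standardize(X) @ beta
        cfg = NestedCvConfig(keepx_grid=[5, 10])
        assert tune_keepx_inner(X, y, 1, cfg) == 10

    def test_deterministic_and_within_grid(self, rng):
        X = rng.normal(size=(20, 10))
        y = 3.0 * standardize(X)[:, 0] + 0.1 * rng.normal(size=20)
        cfg = NestedCvConfig(keepx_grid=[5, 10])
        k1 = tune_keepx_inner(X, y, 1, cfg)
        k2 = tune_keepx_inner(X, y, 1, cfg)
        assert k1 == k2 and k1 in (5, 10)

    def test_requires_three_training_subjects(self, rng):
        with pytest.raises(ValueError):
            tune_keepx_inner(rng.normal(size=(2, 4)), rng.normal(size=2), 1,
                             NestedCvConfig(keepx_grid=[1, 2]))

    def test_fast_path_matches_naive_loop(self, rng):
        """The closed-form K=1 inner LOO equals the per-fold reference loop."""
        for _ in range(5):
            m, p = 14, 11
            X = rng.normal(size=(m, p)) * rng.uniform(0.3, 3.0, size=p)
            X[:, 2] = 42.0  # constant column exercises fold-internal filtering
            y = X[:, 0] * 0.8 + rng.normal(size=m)
            grid = [1, 3, 5, 11]
            fast = _inner_loo_mse_fast_k1(X, y, grid, 1e-8)
            naive = _inner_loo_mse_naive(X, y, 1, grid, 1e-8)
            for g in grid:
                assert fast[g] == pytest.approx(naive[g], rel=1e-9, abs=1e-12)


class TestOuterLoocv:
    def test_exactly_n_predictions(self, small_cohort):
        morph, pheno = small_cohort
        cfg = NestedCvConfig(keepx_grid=[5, 30])
        cvp = outer_loocv(morph.values, pheno.teq.astype(float), 1, cfg)
        assert len(cvp.y_pred) == morph.n_subjects
        assert np.all(np.isfinite(cvp.y_pred))

    def test_constant_features_fall_back_to_training_mean(self):
        X = np.ones((6, 4))
        y = np.arange(6.0)
        cvp = outer_loocv(X, y, 1, NestedCvConfig(keepx_grid=[2, 4]))
        assert cvp.fallback.all()
        for i in range(6):
            assert cvp.y_pred[i] == pytest.approx(np.delete(y, i).mean())

    def test_no_leakage_from_held_out_response(self, rng):
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        cfg = NestedCvConfig(keepx_grid=[4, 8])
        base = outer_loocv(X, y, 1, cfg)
        y2 = y.copy()
        y2[3] += 100.0
        pert = outer_loocv(X, y2, 1, cfg)
        # subject 3's own prediction never saw its response
        assert pert.y_pred[3] == pytest.approx(base.y_pred[3], abs=1e-10)

    def test_fold_model_ignores_held_out_features(self, rng):
        """Fold i's tuned model is a function of the training rows only: with
        subject i's features replaced by arbitrary values, its prediction is
        exactly the unchanged fold model applied to the new row."""
        from splsmorph.validation import _fold_fit_predict

        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        cfg = NestedCvConfig(keepx_grid=[4, 8])
        base = outer_loocv(X, y, 1, cfg)
        X2 = X.copy()
        X2[3] = 1e3 * rng.normal(size=8)
        pert = outer_loocv(X2, y, 1, cfg)
        assert pert.keepx[3] == base.keepx[3]  # tuning never saw row 3
        tr = np.arange(12) != 3
        kx = tune_keepx_inner(X[tr], y[tr], 1, cfg)
        expected, _ = _fold_fit_predict(
            X[tr], y[tr], X2[3:4], 1, kx, cfg.var_tol
        )
        assert pert.y_pred[3] == pytest.approx(expected[0], abs=1e-10)

    def test_three_subject_univariate_matches_per_fold_ols(self):
        """n=3, p=1, noiseless line: each fold reduces to 2-point OLS."""
        x = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])
        cvp = outer_loocv(x, y, 1, NestedCvConfig(keepx_grid=[1]))
        for i in range(3):
            tr = np.delete(np.arange(3), i)
            xt, yt = x[tr, 0], y[tr]
            slope = ((xt - xt.mean()) @ (yt - yt.mean())) / (
                (xt - xt.mean()) @ (xt - xt.mean())
            )
            expected = yt.mean() + slope * (x[i, 0] - xt.mean())
            assert cvp.y_pred[i] == pytest.approx(expected, abs=1e-10)

    def test_requires_three_subjects(self):
        with pytest.raises(ValueError):
            outer_loocv(np.eye(2), np.arange(2.0), 1, NestedCvConfig())


class TestComponentSelection:
    def test_constant_x_picks_one_component(self):
        X = np.ones((8, 5))
        y = np.arange(8.0)
        sel = select_components(X, y, NestedCvConfig(
            keepx_grid=[5], component_candidates=[1, 2, 3]))
        # identical residuals for every k: penalty makes BIC increase in k
        assert sel.chosen == 1
        assert np.all(np.diff(sel.bic) > 0)

    def test_single_candidate_returned_without_search(self, small_cohort):
        morph, pheno = small_cohort
        sel = select_components(
            morph.values, pheno.teq.astype(float),
            NestedCvConfig(keepx_grid=[10, 30], component_candidates=[1]),
        )
        assert sel.chosen == 1 and sel.candidates == [1]

    def test_two_component_structure_selects_small_k(self, rng):
        """High-SNR 2-latent-variable data: chosen k stays in {1..4}."""
        chosen = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, p = 60, 12
            T = r.normal(size=(n, 2))
            load = r.normal(size=(2, p))
            X = T @ load + 0.3 * r.normal(size=(n, p))
            y = T @ np.array([2.0, -1.5]) + 0.5 * r.normal(size=n)
            sel = select_components(X, y, NestedCvConfig(
                keepx_grid=[12], component_candidates=[1, 2, 3, 4, 5, 6]))
            chosen.append(sel.chosen)
        assert all(1 <= k <= 4 for k in chosen)

    def test_candidates_must_be_below_n(self):
        with pytest.raises(ValueError):
            select_components(np.eye(4), np.arange(4.0),
                              NestedCvConfig(component_candidates=[4]))


class TestPermutationTest:
    def test_add_one_convention_when_observed_beats_all(self, rng):
        # signal-bearing cohort: observed Q2 should beat all 19 nulls
        n, p = 25, 6
        X = rng.normal(size=(n, p))
        y = 3.0 * standardize(X)[:, 0] + 0.3 * rng.normal(size=n)
        cfg = NestedCvConfig(keepx_grid=[3, 6], component_candidates=[1])
        rep = permutation_test(X, y, cfg, n_permutations=19, seed=11)
        assert np.all(rep.null_q2 < rep.q2)
        assert rep.permutation_p == pytest.approx(1.0 / 20.0)

    def test_single_exceeding_null_gives_p_one(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        cfg = NestedCvConfig(keepx_grid=[4], component_candidates=[1])
        rep = evaluate(X, y, cfg)
        # brute-force over seeds until the single null beats the observed
        for seed in range(50):
            out = permutation_test(X, y, cfg, n_permutations=1, seed=seed,
                                   report=rep)
            if out.null_q2[0] >= out.q2:
                assert out.permutation_p == pytest.approx(1.0)
                break
        else:
            pytest.fail("no permutation produced a null >= observed")

    def test_reproducible_under_same_master_seed(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        cfg = NestedCvConfig(keepx_grid=[5], component_candidates=[1])
        a = permutation_test(X, y, cfg, n_permutations=7, seed=42)
        b = permutation_test(X, y, cfg, n_permutations=7, seed=42)
        assert np.array_equal(a.null_q2, b.null_q2)
        assert a.permutation_p == b.permutation_p

    def test_rejects_zero_permutations(self, rng):
        with pytest.raises(ValueError):
            permutation_test(np.eye(4), np.arange(4.0), n_permutations=0)


def test_evaluate_report_fields(small_cohort):
    morph, pheno = small_cohort
    cfg = NestedCvConfig(keepx_grid=[5, 15, 30], component_candidates=[1, 2])
    rep = evaluate(morph.values, pheno.teq.astype(float), cfg)
    assert rep.n == morph.n_subjects
    assert rep.rmsep >= 0
    assert rep.q2 <= 1
    assert 0 <= rep.r2 <= 1 or math.isnan(rep.r2)
    assert rep.selection.chosen in (1, 2)
    assert len(rep.predictions.keepx) == rep.n
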