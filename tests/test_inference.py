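"""Partial Spearman, model fitting, permutation/bootstrap machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats

import frsa
from frsa.inference import _PartialCorrEngine, bonferroni, t_tests
from frsa.rsm import from_lower_triangle, lower_triangle


def _brute_partial_spearman(x, y, cov):
    """Independent oracle: explicit rank OLS residual Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = stats.rankdata(cov)
    X = np.column_stack([np.ones_like(rc), rc])
    ex = rx - X @ np.linalg.solve(X.T @ X, X.T @ rx)
    ey = ry - X @ np.linalg.solve(X.T @ X, X.T @ ry)
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


class TestSpearmanPartial:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=10)
        cov = rng.normal(size=10)
        assert frsa.spearman_partial(x, x, cov) == pytest.approx(1.0)

    def test_null_behavior_near_zero(self, rng):
        # x monotone in cov, y independent: expect rho ~ 0 on average
        rhos = []
        for _ in range(200):
            cov = rng.normal(size=20)
            x = np.exp(cov) + rng.normal(0, 0.05, 20)  # monotone in cov + jitter
            y = rng.normal(size=20)
            rhos.append(frsa.spearman_partial(x, y, cov))
        # rank-degenerate draws (x rank-identical to cov) are undefined
        assert abs(np.nanmean(rhos)) < 0.1

    def test_six_element_hand_case_matches_brute_force(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 8.5])
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert frsa.spearman_partial(x, y, cov) == pytest.approx(
            _brute_partial_spearman(x, y, cov), abs=1e-12
        )

    def test_pingouin_cross_check(self, rng):
        import pandas as pd
        import pingouin as pg

        x, y, cov = rng.normal(size=(3, 30))
        ours = frsa.spearman_partial(x, y, cov)
        theirs = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "c": cov}), "x", "y", covar="c",
            method="spearman",
        )["r"].iloc[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_engine_matches_residual_route(self, models, acoustic, rng):
        x = rng.normal(size=78)
        cov = lower_triangle(acoustic)
        eng = _PartialCorrEngine(
            np.stack([lower_triangle(m) for m in models]), cov
        )
        fast = eng.rho_per_model(x)
        slow = [frsa.spearman_partial(x, lower_triangle(m), cov) for m in models]
        np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestFitCategoricalModels:
    def test_planted_model_wins(self, continuum, models, acoustic):
        fit = frsa.inference.fit_categorical_models(models[3], models, acoustic)
        assert fit.best_model == models[3].boundary_after
        assert fit.best_rho == max(fit.rho_per_model)

    def test_acoustic_response_explained_away(self, acoustic, models):
        # response = noisy monotone transform of the acoustic structure:
        # partialing the acoustic RSM leaves no categorical structure
        rng = np.random.default_rng(4)
        # ties in the acoustic triangle (Toeplitz, 12 distinct values) keep
        # rank partialing from removing the structure perfectly, so "near
        # zero" is loose; the planted-model rho of ~1 is the contrast
        tri = lower_triangle(acoustic) ** 3 + rng.normal(0, 0.01, 78)
        resp = frsa.RSM(from_lower_triangle(tri))
        fit = frsa.inference.fit_categorical_models(resp, models, acoustic)
        assert abs(fit.best_rho) < 0.5

    def test_noisy_recovery_rate(self, continuum, models, acoustic):
        rng = np.random.default_rng(0)
        target = [m for m in models if m.boundary_after == 5][0]
        hits = 0
        for _ in range(100):
            tri = lower_triangle(target) + rng.normal(0, 0.15, 78)
            resp = frsa.RSM(from_lower_triangle(tri))
            fit = frsa.inference.fit_categorical_models(resp, models, acoustic)
            hits += fit.best_model == 5
        assert hits >= 95


class TestPermutationTests:
    def test_floor_p_when_observed_beats_all(self, models, acoustic):
        fit, null = frsa.permutation_test_individual(
            models[3], models, acoustic, n_iter=500, seed=0
        )
        assert fit.p_perm == pytest.approx(1 / 501)
        assert null.values.size == 500

    def test_rank_invariance_under_monotone_transform(self, models, acoustic, rng):
        tri = rng.normal(size=78)
        resp1 = frsa.RSM(from_lower_triangle(tri))
        resp2 = frsa.RSM(from_lower_triangle(np.exp(tri)))  # order-preserving
        f1, _ = frsa.permutation_test_individual(resp1, models, acoustic, 300, seed=7)
        f2, _ = frsa.permutation_test_individual(resp2, models, acoustic, 300, seed=7)
        assert f1.p_perm == f2.p_perm
        np.testing.assert_allclose(f1.rho_per_model, f2.rho_per_model, atol=1e-12)

    def test_calibrated_type_one_error_exchangeable_null(self, models, acoustic):
        # pure-noise response RSMs: triangle entries are exchangeable, so
        # the permutation test is exact and rejects at ~alpha
        rng = np.random.default_rng(42)
        n_rep, rejections = 200, 0
        for _ in range(n_rep):
            resp = frsa.RSM(from_lower_triangle(rng.normal(size=78)))
            fit, _ = frsa.permutation_test_individual(
                resp, models, acoustic, n_iter=300, seed=int(rng.integers(2**31))
            )
            rejections += fit.p_perm < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_group_statistic_is_mean_of_individual(self, models, acoustic, rng):
        resps = [
            frsa.RSM(from_lower_triangle(lower_triangle(models[3]) + rng.normal(0, 0.3, 78)))
            for _ in range(4)
        ]
        p, null, obs, fits = frsa.permutation_test_group(
            resps, models, acoustic, n_iter=500, seed=1
        )
        assert obs == pytest.approx(np.mean([f.best_rho for f in fits]))

    def test_single_participant_group_equals_individual_statistic(
        self, models, acoustic, rng
    ):
        resp = frsa.RSM(from_lower_triangle(rng.normal(size=78)))
        _, _, obs, fits = frsa.permutation_test_group(
            [resp], models, acoustic, n_iter=100, seed=2
        )
        ind = frsa.inference.fit_categorical_models(resp, models, acoustic)
        assert obs == pytest.approx(ind.best_rho)


class TestBonferroni:
    def test_paper_scale(self):
        assert bonferroni(0.0001, 10) == pytest.approx(0.001)

    def test_capping_and_identity(self):
        assert bonferroni(0.2, 10) == 1.0
        assert bonferroni(0.03, 1) == 0.03

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bonferroni(0.0, 10)


class TestBootstrapMedianCI:
    def test_degenerate_all_equal(self):
        med, lo, hi = frsa.bootstrap_median_ci([0.56] * 5, n_boot=200, seed=0)
        assert (med, lo, hi) == (0.56, 0.56, 0.56)

    def test_seeded_determinism(self):
        a = frsa.bootstrap_median_ci([1, 2, 3, 4, 5], n_boot=500, seed=42)
        b = frsa.bootstrap_median_ci([1, 2, 3, 4, 5], n_boot=500, seed=42)
        assert a == b

    def test_coverage_about_95_percent(self):
        # 18 draws of a known normal; CI should cover the true median ~95%
        rng = np.random.default_rng(3)
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            sample = rng.normal(0.56, 0.02, size=18)
            _, lo, hi = frsa.bootstrap_median_ci(
                sample, n_boot=1000, seed=int(rng.integers(2**31))
            )
            cover += lo <= 0.56 <= hi
        assert 0.85 <= cover / n_rep <= 1.0


class TestCompareRSMs:
    def test_identical_rsms_rho_one(self, models, acoustic, rng):
        resp = frsa.RSM(from_lower_triangle(rng.normal(size=78)))
        rho, p = frsa.compare_rsms(resp, resp, acoustic, n_iter=200, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_acoustic_vs_itself_explained(self, acoustic):
        rho, _ = frsa.compare_rsms(acoustic, acoustic, acoustic, n_iter=100, seed=0)
        assert np.isnan(rho)  # zero-variance residuals: undefined, reported

    def test_independent_noise_calibrated(self, acoustic):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            a = frsa.RSM(from_lower_triangle(rng.normal(size=78)))
            b = frsa.RSM(from_lower_triangle(rng.normal(size=78)))
            _, p = frsa.compare_rsms(a, b, acoustic, n_iter=200,
                                     seed=int(rng.integers(2**31)))
            rejections += p < 0.05
        assert 0.005 <= rejections / n_rep <= 0.12

    def test_group_variant_mean_of_rhos(self, acoustic, rng):
        a_list = [frsa.RSM(from_lower_triangle(rng.normal(size=78))) for _ in range(3)]
        b_list = [frsa.RSM(from_lower_triangle(rng.normal(size=78))) for _ in range(3)]
        mean_rho, p, rhos = frsa.compare_rsms_group(
            a_list, b_list, acoustic, n_iter=200, seed=5
        )
        assert mean_rho == pytest.approx(np.mean(rhos))


class TestProfilesAndTTests:
    def test_identical_profiles(self, rng):
        prof = rng.uniform(-0.5, 0.5, 10)
        z = frsa.model_profile_similarity(prof, prof)
        assert np.tanh(z) == pytest.approx(1.0)

    def test_negated_profile(self, rng):
        prof = rng.uniform(-0.5, 0.5, 10)
        z = frsa.model_profile_similarity(prof, -prof)
        assert np.tanh(z) == pytest.approx(-1.0)

    def test_three_participant_group_t_matches_hand_computation(self):
        rng = np.random.default_rng(9)
        zs = []
        for _ in range(3):
            a, b = rng.uniform(-0.6, 0.6, (2, 10))
            zs.append(frsa.model_profile_similarity(a, b))
        t, df, p = t_tests(np.array(zs))
        m, s = np.mean(zs), np.std(zs, ddof=1)
        assert t == pytest.approx(m / (s / np.sqrt(3)))
        assert df == 2

    def test_textbook_one_sample(self):
        t, df, p = t_tests(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert t == pytest.approx(3.0 / (np.sqrt(2.5) / np.sqrt(5)))
        assert df == 4

    def test_paired_identical_p_one(self):
        with pytest.warns(UserWarning):
            t, _, p = t_tests(np.ones(5), np.ones(5))
        assert p == 1.0

    def test_constant_nonzero_difference(self):
        t, _, p = t_tests(np.arange(5.0) + 2, np.arange(5.0))
        assert np.isinf(t) and p == 0.0


class TestCategoricalRSAModel:
    def test_fit_summary_and_recovery(self, continuum, models, acoustic, rng):
        target = [m for m in models if m.boundary_after == 5][0]
        resps = [
            frsa.RSM(from_lower_triangle(lower_triangle(target) + rng.normal(0, 0.2, 78)))
            for _ in range(5)
        ]
        res = frsa.CategoricalRSA(resps, acoustic, models, continuum).fit(
            n_perm_individual=300, n_perm_group=500, n_boot=500, seed=0
        )
        assert res.group_p == pytest.approx(1 / 501)
        assert np.median(res.best_boundaries) == 5
        assert res.boundary_median == pytest.approx(0.5625, abs=0.02)
        text = res.summary()
        assert "median boundary ratio" in text and "participants: 5" in text
        d = res.to_dict()
        assert len(d["participants"]) == 5 and d["group"]["bayes_factor"] is None
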