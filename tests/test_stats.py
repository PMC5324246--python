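"""Mixed models, posterior simulation, repeatability and r² decompositions."""

import numpy as np
import pandas as pd
import pytest

from antiphony.stats import (ModelSpec, credible_interval, derived_p, fit_lmm,
                             posterior_sim, r2_nakagawa, repeatability,
                             run_paper_models, unstandardize_slope, zscore)


def simulate_lmm_data(n_groups=20, per_group=10, beta=(1.0, 2.0),
                      sd_group=1.0, sd_e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sd_group)
        x = rng.normal(0, 1, per_group)
        y = beta[0] + beta[1] * x + u + rng.normal(0, sd_e, per_group)
        rows.append(pd.DataFrame(dict(y=y, x=x, grp=f"g{g}")))
    return pd.concat(rows, ignore_index=True)


class TestFitLMM:
    def test_intercept_only_estimate_is_grand_mean(self):
        df = simulate_lmm_data(seed=1)
        fit = fit_lmm(ModelSpec("y", "1", ("grp",)), df)
        # ML intercept equals the grand mean for balanced groups
        assert fit.params.iloc[0] == pytest.approx(df.y.mean(), abs=0.02)

    def test_parameter_recovery_within_sampling_error(self):
        hits = 0
        for seed in range(20):
            df = simulate_lmm_data(seed=seed)
            fit = fit_lmm(ModelSpec("y", "x", ("grp",)), df)
            se = np.sqrt(np.diag(fit.cov_params))
            ok = all(abs(fit.params.iloc[j] - b) < 1.96 * se[j]
                     for j, b in enumerate((1.0, 2.0)))
            hits += ok
        assert hits >= 16  # ≈95% coverage, allow binomial slack

    def test_zero_group_variance_flagged_singular(self):
        # group means made exactly equal: the ML group variance sits on the
        # zero boundary and must be flagged, not silently accepted
        df = simulate_lmm_data(sd_group=0.0, beta=(5.0, 0.0), seed=2)
        df["y"] = df.y - df.groupby("grp").y.transform("mean") + 5.0
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_lmm(ModelSpec("y", "1", ("grp",)), df)
        assert fit.singular
        assert list(fit.vcomps.values())[0] == pytest.approx(0.0, abs=1e-3)

    def test_sqrt_transform_applied_before_fit(self):
        df = simulate_lmm_data(seed=3)
        df["y"] = (df["y"] - df["y"].min() + 1.0) ** 2
        fit = fit_lmm(ModelSpec("y", "1", ("grp",), transform="sqrt"), df)
        assert fit.params.iloc[0] == pytest.approx(np.sqrt(df.y).mean(), abs=0.05)

    def test_requires_two_group_levels(self):
        df = simulate_lmm_data(n_groups=1)
        with pytest.raises(ValueError, match="levels"):
            fit_lmm(ModelSpec("y", "x", ("grp",)), df)


class TestPosteriorSim:
    def test_draw_mean_matches_ml_estimates(self):
        df = simulate_lmm_data(seed=4)
        fit = fit_lmm(ModelSpec("y", "x", ("grp",)), df)
        draws = posterior_sim(fit, n_draws=10_000, seed=0)
        se = np.sqrt(np.diag(fit.cov_params))
        for j in range(2):
            mc_tol = 3 * se[j] / np.sqrt(10_000)
            assert draws.draws[:, j].mean() == pytest.approx(
                fit.params.iloc[j], abs=4 * mc_tol)

    def test_credible_interval_of_standard_normal_draws(self):
        rng = np.random.default_rng(0)
        lo, hi = credible_interval(rng.normal(0, 1, 200_000))
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_reproducible_per_seed(self):
        df = simulate_lmm_data(seed=5)
        fit = fit_lmm(ModelSpec("y", "x", ("grp",)), df)
        a = posterior_sim(fit, n_draws=100, seed=9).draws
        b = posterior_sim(fit, n_draws=100, seed=9).draws
        assert np.array_equal(a, b)

    def test_interval_converges_to_wald(self):
        """CrI from many draws approaches the ±1.96 SE Wald interval."""
        df = simulate_lmm_data(seed=6)
        fit = fit_lmm(ModelSpec("y", "x", ("grp",)), df)
        draws = posterior_sim(fit, n_draws=200_000, seed=1)
        se = np.sqrt(np.diag(fit.cov_params))
        lo, hi = credible_interval(draws.draws[:, 1])
        assert lo == pytest.approx(fit.params.iloc[1] - 1.96 * se[1], abs=0.01 * se[1] + 5e-3)
        assert hi == pytest.approx(fit.params.iloc[1] + 1.96 * se[1], abs=0.01 * se[1] + 5e-3)


class TestDerivedP:
    def test_dominance_gives_extremes(self):
        a = np.arange(100.0)
        assert derived_p(a + 1, a) == 1.0
        assert derived_p(a - 1, a) == 0.0

    def test_independent_normals_give_half(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000)
        assert derived_p(a, b) == pytest.approx(0.5, abs=0.015)

    def test_complementarity_without_ties(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 5000), rng.normal(0, 1, 5000)
        assert derived_p(a, b) + derived_p(b, a) == pytest.approx(1.0)


class TestZScore:
    def test_simple_vector(self):
        assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        z = zscore(rng.uniform(0, 100, 500))
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            zscore([5, 5, 5])

    def test_backtransformed_slope_worked_example(self):
        """A standardized slope of 0.300 with response SD 10.1% means ≈3%
        more answers per one SD (627 s) of clumping time."""
        effect = unstandardize_slope(0.300, 10.1)
        assert round(effect) == 3


class TestRepeatability:
    def test_matches_hand_anova_on_3x4_table(self):
        vals = [1, 2, 3, 4, 11, 12, 13, 14, 21, 22, 23, 24]
        grp = list("aaaabbbbcccc")
        res = repeatability(vals, grp)
        # one-way ANOVA by hand: MS_A = 400, MS_W = 15/9, n0 = 4
        ms_w = 15 / 9
        s2a = (400 - ms_w) / 4
        assert res.n0 == pytest.approx(4.0)
        assert res.s2_among == pytest.approx(s2a)
        assert res.r == pytest.approx(s2a / (s2a + ms_w))

    def test_perfect_repeatability_boundary(self):
        res = repeatability([1, 1, 2, 2, 3, 3], ["a", "a", "b", "b", "c", "c"])
        assert res.r == pytest.approx(1.0)

    def test_shuffled_labels_give_near_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 400)
        grp = rng.permutation(np.repeat(np.arange(40), 10))
        res = repeatability(vals, grp)
        assert res.r < 0.1

    def test_negative_component_truncated(self):
        # within-group spread larger than between: s2_among would be negative
        res = repeatability([0, 10, 5, 5.1], ["a", "a", "b", "b"])
        assert res.truncated and res.r == 0.0

    def test_unequal_group_sizes_use_lessells_boag_n0(self):
        vals = [1.0, 2.0, 3.0, 10.0, 11.0]
        grp = ["a", "a", "a", "b", "b"]
        res = repeatability(vals, grp)
        n0 = (5 - (9 + 4) / 5) / 1
        assert res.n0 == pytest.approx(n0)


class TestR2Nakagawa:
    def test_known_variance_partition(self):
        """fixed var 2, group var 1, residual 1 → r²m ≈ 0.5, r²c ≈ 0.75."""
        rng = np.random.default_rng(6)
        rows = []
        for g in range(60):
            u = rng.normal(0, 1.0)
            x = rng.normal(0, 1, 20)
            y = np.sqrt(2.0) * x + u + rng.normal(0, 1.0, 20)
            rows.append(pd.DataFrame(dict(y=y, x=x, grp=f"g{g}")))
        df = pd.concat(rows, ignore_index=True)
        fit = fit_lmm(ModelSpec("y", "x", ("grp",)), df)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)
        assert r2c >= r2m

    def test_null_fixed_effect_gives_near_zero_marginal(self):
        df = simulate_lmm_data(beta=(0.0, 0.0), seed=7)
        fit = fit_lmm(ModelSpec("y", "x", ("grp",)), df)
        r2m, r2c = r2_nakagawa(fit)
        assert r2m < 0.02


class TestRunPaperModels:
    def test_model_set_runs_end_to_end_on_synthetic_cohort(self):
        from antiphony.fixtures import analyze_cohort, make_cohort
        cohort = make_cohort("new_pair_convergence", seed=11, duration_s=900)
        tabs = analyze_cohort(cohort)
        res = run_paper_models(tabs["pair_days"], tabs["state_rates"],
                               n_draws=2000, seed=0)
        for name in ("clumping", "abs_directionality", "rate_by_position",
                     "stack_totals", "stack_answers", "answers_vs_clumping_m"):
            assert name in res
            assert not res[name].coefficients.estimate.isna().any()
            assert 0 <= res[name].r2_marginal <= res[name].r2_conditional <= 1
        assert "new_day1_gt_day7" in res["abs_directionality"].derived_ps

    def test_insufficient_replication_refused(self):
        df = pd.DataFrame(dict(
            pair_id=["p1"] * 4, experience=["new"] * 4, day=[1, 3, 5, 7],
            clumping_s=[0, 1, 2, 3], abs_directionality_display=[1, 2, 3, 4],
            total_stacks_f=[10] * 4, total_stacks_m=[10] * 4,
            answer_stacks_f=[1] * 4, answer_stacks_m=[2] * 4,
            answer_prop_f=[0.1] * 4, answer_prop_m=[0.2] * 4))
        with pytest.raises(ValueError, match="at least 2 pairs"):
            run_paper_models(df)
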