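"""Cohort statistics: summaries, t-tests, OLS and the bias analysis."""

import numpy as np
import pandas as pd
import pytest

from acetaver.errors import DegenerateInputError, ValidationError
from acetaver.phantom import BiasModel, TiltModel, make_cohort
from acetaver.stats import (
    cohort_with_delta,
    ols,
    run_bias_analysis,
    summarize,
    t_test_independent,
)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        df = pd.DataFrame({"g": ["a"] * 3, "av3d_deg": [1.0, 2.0, 3.0]})
        out = summarize(df, "g", measures=("av3d_deg",))
        assert out.loc["a", ("av3d_deg", "mean")] == pytest.approx(2.0)
        assert out.loc["a", ("av3d_deg", "std")] == pytest.approx(1.0)

    def test_single_observation_sd_missing(self):
        df = pd.DataFrame({"g": ["a"], "av3d_deg": [5.0]})
        out = summarize(df, "g", measures=("av3d_deg",))
        assert np.isnan(out.loc["a", ("av3d_deg", "std")])

    def test_identical_groups_identical_summaries(self):
        df = pd.DataFrame(
            {"g": ["a"] * 4 + ["b"] * 4, "av3d_deg": [1.0, 2, 3, 4] * 2}
        )
        out = summarize(df, "g", measures=("av3d_deg",))
        assert out.loc["a"].equals(out.loc["b"])


class TestTTest:
    def test_identical_samples_t_zero_p_one(self):
        res = t_test_independent([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_pooled_variant_matches_closed_form(self):
        """Hand-computed pooled-variance t for a={1..4}, b={2..5}."""
        a = np.array([1.0, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5])
        res = t_test_independent(a, b, equal_variance=True)
        # by hand: sp² = ((3)(5/3)+(3)(5/3))/6 = 5/3; t = −1/sqrt(5/3·(1/2))
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.df == pytest.approx(6.0)
        from scipy import stats as sps

        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t_hand), 6), abs=1e-12)

    def test_swap_negates_t_preserves_p(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1.2, 25)
        r1 = t_test_independent(a, b)
        r2 = t_test_independent(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            t_test_independent([1.0], [1.0, 2.0])

    def test_sex_difference_detected_in_simulated_cohorts(self, rng):
        """Cohorts drawn at the reported male/female moments separate at
        p < 0.0001 in nearly every replicate (hemipelvis-level n)."""
        hits = 0
        for rep in range(20):
            r = np.random.default_rng(500 + rep)
            male = r.normal(14.0, 5.4, 136)
            female = r.normal(18.4, 5.6, 122)
            hits += t_test_independent(male, female).p_value < 1e-4
        assert hits >= 19


class TestOLS:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        y = 2.0 + 3.0 * x
        res = ols(y, {"x": x})
        assert res.coef("intercept") == pytest.approx(2.0, abs=1e-10)
        assert res.coef("x") == pytest.approx(3.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(0, 2, 60)
        y = 1.5 - 0.7 * x + rng.normal(0, 0.5, 60)
        res = ols(y, {"x": x})
        X = np.column_stack([np.ones(60), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent brute force
        assert res.coef("intercept") == pytest.approx(beta[0], abs=1e-9)
        assert res.coef("x") == pytest.approx(beta[1], abs=1e-9)

    def test_duplicated_predictor_rejected_by_name(self, rng):
        x = rng.normal(0, 1, 30)
        with pytest.raises(DegenerateInputError, match="x2"):
            ols(x * 2 + 1, {"x1": x, "x2": x})

    def test_residuals_orthogonal_to_design(self, rng):
        x1 = rng.normal(0, 1, 80)
        x2 = rng.normal(0, 1, 80)
        y = 1 + x1 - 2 * x2 + rng.normal(0, 1, 80)
        res = ols(y, {"x1": x1, "x2": x2}, interactions=[("x1", "x2")])
        X = np.column_stack([np.ones(80), x1, x2, x1 * x2])
        resid = y - X @ res.coefficients
        assert np.max(np.abs(X.T @ resid)) < 1e-8 * 80

    def test_interaction_model_r2_not_below_nested(self, rng):
        x1 = rng.normal(0, 1, 50)
        x2 = rng.normal(0, 1, 50)
        y = x1 + 0.5 * x1 * x2 + rng.normal(0, 1, 50)
        main = ols(y, {"x1": x1, "x2": x2})
        inter = ols(y, {"x1": x1, "x2": x2}, interactions=[("x1", "x2")])
        assert inter.r_squared >= main.r_squared


class TestBiasAnalysis:
    def test_zero_noise_cohort_recovers_coefficients_exactly(self):
        df = make_cohort(
            n_subjects=40,
            bias_model=BiasModel(b0=-36.643, b_lambda=0.474, b_rho=-0.318,
                                 b_interaction=0.0, noise_sd=0.0),
            rng_seed=3,
        )
        rep = run_bias_analysis(df)
        for side in ("left", "right"):
            m = rep[side]["multiple"]
            assert m.coef("intercept") == pytest.approx(-36.643, abs=1e-8)
            assert m.coef("lambda") == pytest.approx(0.474, abs=1e-10)
            assert m.coef("rho") == pytest.approx(-0.318, abs=1e-10)
            assert m.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_delta_exactly_linear_in_lambda_when_rho_off(self):
        df = make_cohort(
            n_subjects=30,
            bias_model=BiasModel(b_rho=0.0, b_interaction=0.0, noise_sd=0.0),
            rng_seed=4,
        )
        df = cohort_with_delta(df)
        res = ols(df["delta_deg"].to_numpy(), {"lam": df["lambda_deg"].to_numpy()})
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_lambda_is_rank_deficient(self):
        df = make_cohort(n_subjects=30, rng_seed=5)
        df["lambda_deg"] = 65.0
        with pytest.raises(DegenerateInputError, match="lambda"):
            run_bias_analysis(df)

    def test_too_small_cohort_refused(self):
        df = make_cohort(n_subjects=4, rng_seed=6)
        with pytest.raises(ValidationError):
            run_bias_analysis(df)

    def test_inconsistent_delta_column_is_recomputed(self):
        df = make_cohort(n_subjects=12, rng_seed=7)
        df["delta_deg"] = 999.0  # stored garbage must be ignored
        out = cohort_with_delta(df)
        assert np.allclose(out["delta_deg"], out["av3d_deg"] - out["av2d_deg"])
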