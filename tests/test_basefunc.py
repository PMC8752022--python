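import json

import numpy as np
import pytest

from mhecosim.basefunc import (
    BaseFunctionModel,
    VariableTransform,
    fit_exponential,
    fit_product_unit,
    select_best,
)


def grid_search_exponential(z, y, ln_alpha_range, beta_range, resolution=1e-4):
    """Independent oracle: refine a (ln alpha, beta) grid minimizing log-scale SSE.

    The refinement window stays wide (20x the previous step) because the SSE
    valley is strongly correlated in (ln alpha, beta); a narrow window can
    lose the minimum along the valley direction.
    """
    logy = np.log(y)
    la_lo, la_hi = ln_alpha_range
    b_lo, b_hi = beta_range
    step = max(la_hi - la_lo, b_hi - b_lo) / 40
    while True:
        las = np.arange(la_lo, la_hi + step / 2, step)
        bs = np.arange(b_lo, b_hi + step / 2, step)
        LA, B = np.meshgrid(las, bs, indexing="ij")
        sse = ((logy[None, None, :] - (LA[..., None] + B[..., None] * z[None, None, :])) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (LA[i, j], B[i, j])
        if step <= resolution:
            return best
        la_lo, la_hi = best[0] - 20 * step, best[0] + 20 * step
        b_lo, b_hi = best[1] - 20 * step, best[1] + 20 * step
        step /= 4


class TestExponentialFit:
    def test_noiseless_closed_form(self):
        z = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2.0 * np.exp(0.5 * z)
        m = fit_exponential(z, y)
        assert m.alpha == pytest.approx(2.0, abs=1e-9)
        assert m.betas[0] == pytest.approx(0.5, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        z = rng.uniform(0, 10, 13)
        y = 3.0 * np.exp(0.3 * z) * np.exp(rng.normal(0, 0.2, 13))
        m = fit_exponential(z, y)
        ln_a, beta = grid_search_exponential(z, y, (0.0, 2.5), (0.0, 0.8))
        assert np.log(m.alpha) == pytest.approx(ln_a, abs=2e-4)
        assert m.betas[0] == pytest.approx(beta, abs=2e-4)

    def test_r_squared_invariant_to_affine_regressor_rescaling(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 5, 13)
        y = 2.0 * np.exp(0.4 * z) * np.exp(rng.normal(0, 0.1, 13))
        m1 = fit_exponential(z, y)
        m2 = fit_exponential(3.0 * z + 7.0, y)
        assert m1.r_squared == pytest.approx(m2.r_squared, rel=1e-12)

    def test_parameters_inside_their_intervals(self):
        rng = np.random.default_rng(2)
        z = rng.uniform(0, 5, 13)
        y = 2.0 * np.exp(0.4 * z) * np.exp(rng.normal(0, 0.15, 13))
        m = fit_exponential(z, y)
        assert m.alpha_ci[0] <= m.alpha <= m.alpha_ci[1]
        assert m.beta_cis[0][0] <= m.betas[0] <= m.beta_cis[0][1]

    @pytest.mark.parametrize(
        "z,y,match",
        [
            ([0, 1, 2], [1.0, -1.0, 2.0], "must be > 0"),
            ([0, 1], [1.0, 2.0], "at least 3"),
            ([2, 2, 2, 2], [1.0, 2.0, 3.0, 4.0], "zero variance"),
        ],
    )
    def test_invalid_inputs_rejected(self, z, y, match):
        with pytest.raises(ValueError, match=match):
            fit_exponential(np.asarray(z, float), np.asarray(y, float))


class TestProductUnitFit:
    def test_noiseless_power_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        y = 3.0 * x**-2.0
        m = fit_product_unit(x, y)
        assert m.alpha == pytest.approx(3.0, abs=1e-9)
        assert m.betas[0] == pytest.approx(-2.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_identity(self):
        """x -> 10x leaves beta unchanged and multiplies alpha by 10^-beta."""
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 9, 13)
        y = 5.0 * x**1.3 * np.exp(rng.normal(0, 0.2, 13))
        m1 = fit_product_unit(x, y)
        m2 = fit_product_unit(10.0 * x, y)
        assert m2.betas[0] == pytest.approx(m1.betas[0], rel=1e-9)
        assert m2.alpha == pytest.approx(m1.alpha * 10.0 ** (-m1.betas[0]), rel=1e-9)
        assert m2.r_squared == pytest.approx(m1.r_squared, rel=1e-12)

    def test_two_regressor_fit_recovers_exponents(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 10, (20, 2))
        y = 2.0 * x[:, 0] ** 0.7 * x[:, 1] ** -0.4
        m = fit_product_unit(x, y)
        assert m.betas == pytest.approx((0.7, -0.4), abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            fit_product_unit(np.array([1.0, -2.0, 3.0, 4.0]), np.ones(4))
        x = np.ones((4, 2))
        x[:, 1] = 2 * x[:, 0]  # log-collinear with the intercept
        with pytest.raises(ValueError, match="rank-deficient|zero variance"):
            fit_product_unit(x, np.array([1.0, 2.0, 3.0, 4.0]))


class TestFStatistic:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_f_equals_r2_identity(self, seed):
        """F = R^2/(1-R^2) x (n-p-1)/p on every (non-exact) fit."""
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, 5, 13)
        y = 2.0 * np.exp(0.4 * z) * np.exp(rng.normal(0, 0.3, 13))
        m = fit_exponential(z, y)
        n, p = m.n_obs, len(m.betas)
        expected = m.r_squared / (1 - m.r_squared) * (n - p - 1) / p
        assert m.f_stat == pytest.approx(expected, rel=1e-9)


class TestPredictionIntervals:
    def test_zero_residual_variance_degenerates(self):
        z = np.array([0.0, 1.0, 2.0, 3.0])
        m = fit_exponential(z, 2.0 * np.exp(0.5 * z))
        point, lo, hi = m.predict_interval(1.7)
        assert lo == point == hi
        assert point == pytest.approx(2.0 * np.exp(0.5 * 1.7), rel=1e-9)

    def test_width_grows_away_from_training_mean(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(0, 10, 13)
        y = 2.0 * np.exp(0.3 * z) * np.exp(rng.normal(0, 0.2, 13))
        m = fit_exponential(z, y)
        center = z.mean()
        # log-scale width is symmetric and non-decreasing in |x - mean|
        widths = []
        for dx in (0.0, 1.0, 2.0, 4.0, 8.0):
            _, lo, hi = m.predict_interval(center + dx)
            widths.append(np.log(hi) - np.log(lo))
        assert all(b >= a - 1e-12 for a, b in zip(widths, widths[1:]))

    def test_interval_ordering_and_positivity(self):
        rng = np.random.default_rng(6)
        z = rng.uniform(0, 10, 13)
        y = 2.0 * np.exp(0.3 * z) * np.exp(rng.normal(0, 0.2, 13))
        m = fit_exponential(z, y)
        point, lo, hi = m.predict_interval(3.0)
        assert 0 < lo <= point <= hi

    def test_empirical_coverage_of_fresh_observations(self):
        """95% prediction intervals cover fresh draws 95% +/- 3% of the time.

        200 independent training sets x 50 fresh observations each: coverage
        is marginal over both training and observation noise.
        """
        rng = np.random.default_rng(7)
        alpha, beta, sigma = 2.0, 0.4, 0.25
        hits = total = 0
        for _ in range(200):
            z = rng.uniform(0, 5, 13)
            y = alpha * np.exp(beta * z) * np.exp(rng.normal(0, sigma, 13))
            m = fit_exponential(z, y)
            z_new = rng.uniform(0, 5, 50)
            y_new = alpha * np.exp(beta * z_new) * np.exp(rng.normal(0, sigma, 50))
            for zi, yi in zip(z_new, y_new):
                _, lo, hi = m.predict_interval(zi, level=0.95)
                hits += lo <= yi <= hi
                total += 1
        assert abs(hits / total - 0.95) < 0.03

    def test_matches_statsmodels_prediction_interval(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        z = rng.uniform(0, 10, 13)
        y = 2.0 * np.exp(0.3 * z) * np.exp(rng.normal(0, 0.2, 13))
        m = fit_exponential(z, y)
        design = np.column_stack([np.ones_like(z), z])
        res = sm.OLS(np.log(y), design).fit()
        pred = res.get_prediction(np.array([[1.0, 4.2]])).summary_frame(alpha=0.05)
        _, lo, hi = m.predict_interval(4.2)
        assert lo == pytest.approx(float(np.exp(pred["obs_ci_lower"].iloc[0])), rel=1e-9)
        assert hi == pytest.approx(float(np.exp(pred["obs_ci_upper"].iloc[0])), rel=1e-9)

    def test_domain_violation_rejected(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        m = fit_product_unit(x, 3.0 * x**-2.0)
        with pytest.raises(ValueError, match="> 0"):
            m.predict_interval(-1.0)


class TestModelSelection:
    def test_single_candidate_identity(self):
        z = np.array([0.0, 1.0, 2.0, 3.0])
        m = fit_exponential(z, 2.0 * np.exp(0.5 * z))
        assert select_best([m]) is m

    def test_true_form_wins_on_noiseless_data(self):
        z = np.linspace(1, 5, 13)
        y = 2.0 * np.exp(0.5 * z)
        exp_fit = fit_exponential(z, y, response_name="y")
        pu_fit = fit_product_unit(z, y, response_name="y")
        assert select_best([pu_fit, exp_fit]) is exp_fit

    def test_tie_breaks_on_fewer_parameters(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 9, (13, 2))
        y = 2.0 * x[:, 0] ** 0.5
        m1 = fit_product_unit(x[:, 0], y, response_name="y")
        m2 = fit_product_unit(x, y, response_name="y")
        m2.sigma2 = m1.sigma2  # force the tie
        assert select_best([m2, m1]) is m1

    def test_mismatched_responses_rejected(self):
        z = np.array([0.0, 1.0, 2.0, 3.0])
        a = fit_exponential(z, np.exp(z), response_name="stay_days")
        b = fit_exponential(z, np.exp(z), response_name="discharges")
        with pytest.raises(ValueError, match="different responses"):
            select_best([a, b])
        with pytest.raises(ValueError, match="empty"):
            select_best([])


class TestSerialization:
    def test_json_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(10)
        z = rng.uniform(0, 10, 13)
        y = 2.0 * np.exp(0.3 * z) * np.exp(rng.normal(0, 0.2, 13))
        transform = VariableTransform(("population_adults",), (1000.0,), "single")
        m = fit_exponential(z, y, response_name="x", response_divisor=1000.0, transform=transform)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = BaseFunctionModel.from_json(path)
        assert back.to_dict() == m.to_dict()
        assert back.predict_interval(4.2) == m.predict_interval(4.2)

    def test_transform_product_combination(self):
        t = VariableTransform(("a", "b"), (10.0, 1.0), "product")
        out = t.apply({"a": np.array([10.0, 20.0]), "b": np.array([3.0, 4.0])})
        np.testing.assert_allclose(out, [3.0, 8.0])
        with pytest.raises(ValueError, match="exactly one source"):
            VariableTransform(("a", "b"), (1.0, 1.0), "single")
        with pytest.raises(ValueError, match="divisors"):
            VariableTransform(("a",), (0.0,), "single")
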