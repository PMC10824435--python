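import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from egm.growth_model import (
    FieldCurveParams,
    FitConfig,
    FittedModel,
    ModelError,
    RandomEffects,
    eb_random_effects,
    field_params,
    fit,
    logistic_mean,
    marginal_loglik,
    r_squared,
    random_effect_correlations,
)
from egm.io_data import Dataset
from egm.synthetic import SimConfig, simulate

from conftest import one_year_params


# ---------------------------------------------------------------------------
# curve evaluation
# ---------------------------------------------------------------------------


class TestLogisticMean:
    def test_half_asymptote_at_midpoint(self):
        p = FieldCurveParams(log_asymptote=8.0, steepness=1.3, midpoint=2.0)
        assert logistic_mean(p, 2.0) == pytest.approx(np.exp(8.0) / 2.0)

    def test_asymptote_limit(self):
        p = FieldCurveParams(log_asymptote=8.0, steepness=1.3, midpoint=2.0)
        assert logistic_mean(p, 1e6) == pytest.approx(np.exp(8.0))

    def test_direct_evaluation_day_scale(self):
        # unstandardized-time variant: exp(8) / (1 + e^{-0.1 * 20})
        p = FieldCurveParams(log_asymptote=8.0, steepness=0.1, midpoint=60.0)
        expected = np.exp(8.0) / (1.0 + np.exp(-2.0))
        assert logistic_mean(p, 80.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        p = FieldCurveParams(log_asymptote=7.0, steepness=2.0, midpoint=1.0)
        t = np.linspace(-5, 8, 200)
        y = logistic_mean(p, t)
        assert np.all(np.diff(y) > 0)
        assert np.all(y < np.exp(7.0))

    def test_no_overflow_far_left(self):
        p = FieldCurveParams(log_asymptote=8.0, steepness=5.0, midpoint=0.0)
        assert logistic_mean(p, -500.0) == pytest.approx(0.0)

    def test_positive_steepness_required(self):
        with pytest.raises(ModelError):
            FieldCurveParams(log_asymptote=8.0, steepness=-0.1, midpoint=0.0)


class TestFieldParams:
    def test_zero_random_effects_give_year_average(self):
        params = one_year_params()
        p = field_params(params, 2015, RandomEffects(0, 0, 0))
        assert p.log_asymptote == pytest.approx(params.alpha0[2015])
        assert p.steepness == pytest.approx(np.exp(params.beta0[2015]))
        assert p.midpoint == pytest.approx(params.gamma0[2015])

    def test_unit_scale_on_midpoint_when_sigma_gamma_zero(self):
        params = one_year_params(sigma_alpha=0.0, sigma_beta=0.0, sigma_gamma=0.0)
        p = field_params(params, 2015, RandomEffects(1, 1, 1))
        assert p.log_asymptote == pytest.approx(params.alpha0[2015])
        assert p.steepness == pytest.approx(np.exp(params.beta0[2015]))
        assert p.midpoint == pytest.approx(params.gamma0[2015] + 1.0)

    def test_direct_evaluation(self):
        params = one_year_params(
            alpha0={2015: 8.0},
            beta0={2015: 0.5},
            gamma0={2015: 3.0},
            sigma_alpha=0.4,
            sigma_beta=0.2,
            sigma_gamma=float(np.log(0.5)),
        )
        p = field_params(params, 2015, RandomEffects(1, -1, 2))
        assert p.log_asymptote == pytest.approx(8.4)
        assert p.steepness == pytest.approx(np.exp(0.3))
        assert p.midpoint == pytest.approx(4.0)

    def test_unknown_year(self):
        with pytest.raises(ModelError):
            field_params(one_year_params(), 1999, RandomEffects(0, 0, 0))


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def _cond_loglik_oracle(params, year, t, logy, u):
    """Independent plain-python lognormal conditional log-density."""
    a = params.alpha0[year] + params.sigma_alpha * u[..., 0]
    b = np.exp(params.beta0[year] + params.sigma_beta * u[..., 1])
    c = params.gamma0[year] + np.exp(params.sigma_gamma) * u[..., 2]
    eta = b[..., None] * (t - c[..., None])
    mu = a[..., None] - np.log1p(np.exp(-np.clip(eta, -700, 700)))
    s2 = params.sigma_resid**2
    return (
        -0.5 * np.log(2 * np.pi * s2) * t.size
        - ((logy - mu) ** 2).sum(axis=-1) / (2 * s2)
        - logy.sum()
    )


class TestMarginalLoglik:
    def test_degenerate_scales_equal_closed_form(self, toy_two_fields):
        ds, params, _ = toy_two_fields
        params = params.rescale_time(ds.time_scale)
        # vanishing random-effect scales: the marginal equals the fixed-effect
        # lognormal density; the quadrature must reproduce it at any n_points
        degen = dataclasses.replace(
            params, sigma_alpha=0.0, sigma_beta=0.0, sigma_gamma=-30.0
        )
        closed = 0.0
        for _, g in ds.observations.groupby("unit_id"):
            year = int(g["year"].iloc[0])
            closed += float(
                _cond_loglik_oracle(
                    degen,
                    year,
                    g["t_std"].to_numpy(),
                    g["log_weight"].to_numpy(),
                    np.zeros((1, 3)),
                )[0]
            )
        for n_points in (1, 7):
            assert marginal_loglik(degen, ds, n_points) == pytest.approx(
                closed, abs=1e-6
            )

    def test_monte_carlo_oracle(self, toy_two_fields):
        # brute-force integration: 1e6 prior draws per field vs 9-point AGQ
        ds, params, _ = toy_two_fields
        params = params.rescale_time(ds.time_scale)
        rng = np.random.default_rng(123)
        N = 1_000_000
        L = np.linalg.cholesky(params.corr_matrix())
        total_mc, var_total = 0.0, 0.0
        for _, g in ds.observations.groupby("unit_id"):
            year = int(g["year"].iloc[0])
            u = rng.standard_normal((N, 3)) @ L.T
            ll = _cond_loglik_oracle(
                params, year, g["t_std"].to_numpy(), g["log_weight"].to_numpy(), u
            )
            log_mean = logsumexp(ll) - np.log(N)
            w = np.exp(ll - ll.max())
            se_log = w.std() / (w.mean() * np.sqrt(N))
            total_mc += log_mean
            var_total += se_log**2
        agq = marginal_loglik(params, ds, n_points=9)
        assert abs(agq - total_mc) < 3.0 * np.sqrt(var_total)

    def test_quadrature_self_convergence(self, toy_two_fields):
        ds, params, _ = toy_two_fields
        params = params.rescale_time(ds.time_scale)
        ll5 = marginal_loglik(params, ds, n_points=5)
        ll25 = marginal_loglik(params, ds, n_points=25)
        assert abs(ll5 - ll25) < 1e-4

    def test_laplace_close_to_adaptive(self, toy_two_fields):
        ds, params, _ = toy_two_fields
        params = params.rescale_time(ds.time_scale)
        ll1 = marginal_loglik(params, ds, n_points=1)
        ll9 = marginal_loglik(params, ds, n_points=9)
        assert abs(ll1 - ll9) < 0.01 * abs(ll9)

    def test_time_rescaling_invariance(self, toy_two_fields):
        # likelihood is invariant to expressing time in days vs standardized
        # units when the parameters are converted consistently
        ds, params, _ = toy_two_fields
        obs_days = ds.observations.copy()
        obs_days["t_std"] = obs_days["days_after_planting"]
        ds_days = Dataset(
            fields=ds.fields, observations=obs_days, time_scale=1.0
        )
        ll_days = marginal_loglik(params, ds_days, n_points=5)
        ll_std = marginal_loglik(
            params.rescale_time(ds.time_scale), ds, n_points=5
        )
        assert ll_days == pytest.approx(ll_std, abs=1e-6)

    def test_invalid_inputs(self, toy_two_fields):
        ds, params, _ = toy_two_fields
        bad = dataclasses.replace(params, rho12=0.99, rho13=-0.99, rho23=0.99)
        with pytest.raises(ModelError):
            marginal_loglik(bad, ds, 3)
        with pytest.raises(ModelError):
            marginal_loglik(params, ds, 0)


# ---------------------------------------------------------------------------
# empirical-Bayes effects
# ---------------------------------------------------------------------------


def _field_obs(ds, unit_id):
    return ds.observations[ds.observations["unit_id"] == unit_id]


class TestEmpiricalBayes:
    def test_observations_on_average_curve_give_zero(self):
        params = one_year_params()
        std = params.rescale_time(30.0)
        t = np.array([1.0, 2.0, 2.5, 3.0, 4.0])
        p = field_params(std, 2015, RandomEffects(0, 0, 0))
        obs = pd.DataFrame(
            {
                "year": 2015,
                "t_std": t,
                "log_weight": np.log(logistic_mean(p, t)),
            }
        )
        re = eb_random_effects(std, obs)
        assert np.allclose([re.a, re.b, re.c], 0.0, atol=1e-6)

    def test_grid_search_oracle(self, toy_two_fields):
        # two-stage dense grid over [-4, 4]^3 as an independent posterior-mode
        # oracle (coarse 0.08 step, then 0.005 refinement around the optimum)
        ds, params, _ = toy_two_fields
        params = params.rescale_time(ds.time_scale)
        unit = ds.unit_ids[0]
        g = _field_obs(ds, unit)
        t, logy = g["t_std"].to_numpy(), g["log_weight"].to_numpy()
        Rinv = np.linalg.inv(params.corr_matrix())

        def neg_joint(u):
            prior = 0.5 * np.einsum("...i,ij,...j->...", u, Rinv, u)
            return -_cond_loglik_oracle(params, 2015, t, logy, u) + prior

        def argmin_on(axes):
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            vals = neg_joint(grid)
            return grid[np.argmin(vals)]

        coarse = argmin_on([np.arange(-4, 4.001, 0.08)] * 3)
        fine = argmin_on(
            [np.arange(c - 0.1, c + 0.1001, 0.005) for c in coarse]
        )
        re = eb_random_effects(params, g)
        assert np.abs(np.array([re.a, re.b, re.c]) - fine).max() < 0.02

    def test_shrinkage_with_fewer_observations(self, toy_two_fields):
        ds, params, _ = toy_two_fields
        params = params.rescale_time(ds.time_scale)
        unit = ds.unit_ids[0]
        g = _field_obs(ds, unit)
        re_full = eb_random_effects(params, g)
        re_one = eb_random_effects(params, g.iloc[[3]])
        norm_full = np.linalg.norm([re_full.a, re_full.b, re_full.c])
        norm_one = np.linalg.norm([re_one.a, re_one.b, re_one.c])
        assert norm_one < norm_full

    def test_requires_observations(self):
        with pytest.raises(ModelError):
            eb_random_effects(
                one_year_params(),
                pd.DataFrame(columns=["year", "t_std", "log_weight"]),
            )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    @pytest.fixture(scope="class")
    def noise_free_fit(self):
        params = one_year_params(
            alpha0={2015: 8.4, 2016: 8.1},
            beta0={2015: -2.3, 2016: -2.4},
            gamma0={2015: 74.0, 2016: 78.0},
            sigma_alpha=0.0,
            sigma_beta=0.0,
            sigma_gamma=-30.0,
            rho12=0.0,
            rho13=0.0,
            rho23=0.0,
            sigma_resid=0.01,
        )
        cfg = SimConfig(
            years=(2015, 2016),
            n_fields_per_year=20,
            params=params,
            obs_per_field=(6, 6),
            seed=5,
        )
        ds, _ = simulate(cfg)
        model = fit(ds, FitConfig(n_quadrature=1, max_iter=400))
        return ds, params, model

    def test_noise_free_limit_recovers_fixed_effects(self, noise_free_fit):
        ds, true_day, model = noise_free_fit
        true_std = true_day.rescale_time(ds.time_scale)
        assert model.converged
        p = model.params
        assert p.sigma_alpha < 0.05
        assert p.sigma_beta < 0.05
        assert np.exp(p.sigma_gamma) < 0.05
        for year in (2015, 2016):
            assert p.alpha0[year] == pytest.approx(true_std.alpha0[year], abs=0.05)
            assert p.beta0[year] == pytest.approx(true_std.beta0[year], abs=0.05)
            assert p.gamma0[year] == pytest.approx(true_std.gamma0[year], abs=0.05)

    def test_fitted_loglik_beats_truth(self, noise_free_fit):
        ds, true_day, model = noise_free_fit
        true_std = true_day.rescale_time(ds.time_scale)
        assert model.loglik >= marginal_loglik(true_std, ds, model.n_quadrature)

    def test_correlation_matrix_shape(self, noise_free_fit):
        _, _, model = noise_free_fit
        R = random_effect_correlations(model)
        assert R.shape == (3, 3)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)

    def test_eb_available_for_every_field(self, noise_free_fit):
        ds, _, model = noise_free_fit
        assert set(model.eb) == set(ds.unit_ids)

    def test_degenerate_data_rejected(self, toy_two_fields):
        ds, _, _ = toy_two_fields
        obs = ds.observations.copy()
        obs["log_weight"] = 5.0
        obs["weight_g_m2"] = np.exp(5.0)
        with pytest.raises(ModelError):
            fit(Dataset(fields=ds.fields, observations=obs, time_scale=ds.time_scale))

    def test_serialization_roundtrip(self, noise_free_fit, tmp_path):
        _, _, model = noise_free_fit
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedModel.from_json(path)
        assert back.loglik == pytest.approx(model.loglik)
        assert back.params.alpha0 == model.params.alpha0
        u = next(iter(model.eb))
        assert back.eb[u] == model.eb[u]


# ---------------------------------------------------------------------------
# R^2
# ---------------------------------------------------------------------------


def _dataset_with_predictions(pred, obs_weights):
    """1-field dataset whose EB-curve predictions equal `pred` exactly."""
    params = one_year_params(
        alpha0={2015: float(np.log(8.0))},
        beta0={2015: 0.0},
        gamma0={2015: 0.0},
    )
    # invert the logistic: t such that exp(a)/(1+exp(-t)) = p
    t = np.array([-np.log(8.0 / p - 1.0) for p in pred])
    obs = pd.DataFrame(
        {
            "unit_id": "A::2015",
            "field_id": "A",
            "year": 2015,
            "days_after_planting": t,
            "t_std": t,
            "weight_g_m2": obs_weights,
            "log_weight": np.log(obs_weights),
        }
    )
    fields = pd.DataFrame({"field_id": ["A"], "year": [2015]}, index=["A::2015"])
    ds = Dataset(fields=fields, observations=obs, time_scale=1.0)
    model = FittedModel(
        params=params,
        loglik=0.0,
        eb={"A::2015": RandomEffects(0, 0, 0)},
        converged=True,
        n_quadrature=1,
        time_scale=1.0,
    )
    return model, ds


class TestRSquared:
    def test_perfect_fit(self):
        model, ds = _dataset_with_predictions([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
        assert r_squared(model, ds) == pytest.approx(1.0)

    def test_hand_ols_oracle(self):
        # observed {1,2,3} on predicted {1,2,4}: R^2 = 27/28
        model, ds = _dataset_with_predictions([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert r_squared(model, ds) == pytest.approx(27.0 / 28.0, abs=1e-9)

    def test_needs_three_observations(self):
        model, ds = _dataset_with_predictions([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ModelError):
            r_squared(model, ds)
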