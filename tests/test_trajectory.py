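"""Restricted cubic spline trajectory modelling."""

import numpy as np
import pandas as pd
import pytest

from tractspan import synthetic
from tractspan import trajectory as traj
from tractspan.trajectory import PipelineConfig, RCSBasisSpec


def make_df(ages, values, sex=None):
    n = len(ages)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "session_id": [f"s{i}_ses1" for i in range(n)],
            "age": ages,
            "sex": sex if sex is not None else ["M"] * n,
            "cohort": ["x"] * n,
            "bundle": ["b"] * n,
            "f": values,
        }
    )


class TestBasis:
    def test_six_knots_give_five_columns(self):
        X = traj.rcs_basis(np.linspace(0, 100, 50))
        assert X.shape[1] == 5

    def test_nonlinear_columns_zero_below_first_knot(self):
        X = traj.rcs_basis(np.array([0.0, 1.0, 1.99]))
        assert np.all(X[:, 1:] == 0.0)

    def test_second_derivative_vanishes_beyond_last_knot(self):
        h = 1e-3
        for a in (92.0, 95.0, 110.0):
            trio = traj.rcs_basis(np.array([a - h, a, a + h]))
            d2 = (trio[0] - 2 * trio[1] + trio[2]) / h**2
            assert np.max(np.abs(d2)) < 1e-6

    def test_analytic_derivative_matches_finite_differences(self):
        ages = np.linspace(0.5, 110.0, 400)
        h = 1e-5
        fd = (traj.rcs_basis(ages + h) - traj.rcs_basis(ages - h)) / (2 * h)
        an = traj.rcs_basis_derivative(ages)
        assert np.max(np.abs(fd - an)) < 1e-4 * max(1.0, np.max(np.abs(an)))

    def test_continuity_at_knots(self):
        for t in traj.DEFAULT_KNOTS:
            pair = traj.rcs_basis(np.array([t - 1e-9, t + 1e-9]))
            assert np.max(np.abs(pair[1] - pair[0])) < 1e-6

    def test_unordered_knots_rejected(self):
        with pytest.raises(ValueError):
            RCSBasisSpec(knots=(2.0, 4.0, 3.0))
        with pytest.raises(ValueError):
            RCSBasisSpec(knots=(2.0, 4.0))


class TestFit:
    def test_interpolates_own_model_class(self):
        rng = np.random.default_rng(0)
        ages = rng.uniform(0, 100, 500)
        spec = RCSBasisSpec()
        true_coef = np.array([0.3, 0.01, -0.5, 0.8, -0.4, 0.2])
        X = traj.rcs_basis(ages, spec)
        values = true_coef[0] + X @ true_coef[1:]
        model = traj.fit_trajectory(make_df(ages, values), "f", spec, covariates=())
        assert np.allclose(model.coefficients, true_coef, rtol=1e-6, atol=1e-9)

    def test_linear_data_has_zero_nonlinear_terms(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(0, 100, 300)
        model = traj.fit_trajectory(
            make_df(ages, 2.0 + 0.3 * ages), "f", covariates=()
        )
        assert model.coefficients[1] == pytest.approx(0.3, abs=1e-6)
        assert np.max(np.abs(model.coefficients[2:])) < 1e-6

    def test_quadratic_peak_recovered(self, quad_table):
        table = quad_table(noise_sd=0.0225, n_per_cohort=500, seed=0)
        model = traj.fit_trajectory(table, "f")
        ext = traj.find_extremum(model)
        assert ext.kind == "peak"
        assert ext.age == pytest.approx(25.0, abs=2.0)

    def test_sex_covariate_estimated(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(0, 100, 400)
        sex = np.where(rng.random(400) < 0.5, "F", "M")
        values = 1.0 + 0.01 * ages + 0.2 * (sex == "F")
        model = traj.fit_trajectory(make_df(ages, values, sex=list(sex)), "f")
        assert model.coefficients[-1] == pytest.approx(0.2, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        ages = np.full(50, 30.0)  # constant age: basis columns collinear
        with pytest.raises(ValueError, match="collinear"):
            traj.fit_trajectory(make_df(ages, np.ones(50)), "f", covariates=())

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            traj.fit_trajectory(
                make_df(np.linspace(0, 100, 5), np.zeros(5)), "f", covariates=()
            )


class TestPredict:
    def test_mean_prediction_equals_mean_of_data(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(0, 100, 300)
        values = 0.5 + 0.01 * ages + rng.normal(0, 0.1, 300)
        model = traj.fit_trajectory(make_df(ages, values), "f", covariates=())
        # OLS with intercept: mean fitted value equals mean observed value
        assert traj.predict_curve(model, ages).mean() == pytest.approx(
            values.mean(), abs=1e-8
        )

    def test_affine_beyond_last_knot(self, quad_table):
        model = traj.fit_trajectory(quad_table(noise_sd=0.01, seed=4), "f")
        y = traj.predict_curve(model, np.array([95.0, 100.0, 105.0]))
        assert y[1] - y[0] == pytest.approx(y[2] - y[1], abs=1e-8)

    def test_constant_data_gives_constant_prediction(self):
        ages = np.linspace(0, 100, 100)
        model = traj.fit_trajectory(make_df(ages, np.full(100, 2.5)), "f", covariates=())
        assert np.allclose(traj.predict_curve(model, np.linspace(0, 100, 7)), 2.5)

    def test_out_of_range_ages_rejected(self, quad_table):
        model = traj.fit_trajectory(quad_table(seed=5, n_per_cohort=30), "f")
        with pytest.raises(ValueError):
            traj.predict_curve(model, np.array([150.0]))


class TestDerivative:
    def test_constant_fit_zero_derivative(self):
        ages = np.linspace(0, 100, 100)
        model = traj.fit_trajectory(make_df(ages, np.full(100, 1.0)), "f", covariates=())
        assert np.allclose(traj.difference_per_year(model, ages), 0.0, atol=1e-10)

    def test_linear_fit_constant_slope(self):
        ages = np.linspace(0, 100, 200)
        model = traj.fit_trajectory(make_df(ages, 2 + 0.3 * ages), "f", covariates=())
        assert np.allclose(traj.difference_per_year(model, ages), 0.3, atol=1e-8)

    def test_matches_finite_differences(self, quad_table):
        model = traj.fit_trajectory(quad_table(noise_sd=0.02, seed=6), "f")
        grid = np.linspace(1.0, 99.0, 500)
        h = 0.01
        fd = (
            traj.predict_curve(model, grid + h) - traj.predict_curve(model, grid - h)
        ) / (2 * h)
        an = traj.difference_per_year(model, grid)
        assert np.max(np.abs(fd - an)) < 1e-4 * max(np.max(np.abs(an)), 1e-3)


class TestPercentDifference:
    def test_exponential_truth_two_percent_per_year(self):
        rng = np.random.default_rng(7)
        ages = rng.uniform(0, 100, 3000)
        values = np.exp(0.02 * ages)
        model = traj.fit_trajectory(make_df(ages, values), "f", covariates=())
        grid = np.linspace(10, 90, 50)
        pct = traj.percent_difference_per_year(model, grid)
        assert np.all(np.abs(pct - 2.0) < 0.2)

    def test_constant_truth_zero_percent(self):
        ages = np.linspace(0, 100, 100)
        model = traj.fit_trajectory(make_df(ages, np.full(100, 3.0)), "f", covariates=())
        assert np.allclose(
            traj.percent_difference_per_year(model, ages), 0.0, atol=1e-8
        )

    def test_composition_identity(self, quad_table):
        model = traj.fit_trajectory(quad_table(noise_sd=0.02, seed=8), "f")
        grid = np.linspace(1, 99, 99)
        expected = 100.0 * traj.difference_per_year(model, grid) / traj.predict_curve(
            model, grid
        )
        assert np.allclose(
            traj.percent_difference_per_year(model, grid), expected, equal_nan=True
        )


class TestExtremum:
    def test_monotone_curve_has_none(self):
        ages = np.linspace(0, 100, 300)
        model = traj.fit_trajectory(make_df(ages, 1 + 0.01 * ages), "f", covariates=())
        assert traj.find_extremum(model).kind == "none"

    def test_u_shape_minimum(self):
        rng = np.random.default_rng(9)
        truth = synthetic.TruthRecord(
            "b", "f", "quadratic", (1.0, -0.008, 0.0001), noise_sd=0.01
        )  # vertex (minimum) at age 40
        table, _ = synthetic.generate_feature_table(
            [truth], synthetic.default_cohorts(300), 9
        )
        ext = traj.find_extremum(traj.fit_trajectory(table, "f"))
        assert ext.kind == "minimum"
        assert ext.age == pytest.approx(40.0, abs=2.0)

    def test_empty_range_rejected(self, quad_table):
        model = traj.fit_trajectory(quad_table(seed=10, n_per_cohort=30), "f")
        with pytest.raises(ValueError):
            traj.find_extremum(model, age_range=(50.0, 50.0))


class TestBootstrap:
    def test_same_seed_identical_bands(self, quad_table):
        table = quad_table(noise_sd=0.02, n_per_cohort=50, seed=11)
        cfg = PipelineConfig(B=50, seed=42)
        b1 = traj.bootstrap_trajectory(table, "f", config=cfg)
        b2 = traj.bootstrap_trajectory(table, "f", config=cfg)
        assert np.array_equal(b1.band_low, b2.band_low)
        assert np.array_equal(b1.band_high, b2.band_high)
        assert b1.extremum == b2.extremum

    def test_noise_free_in_class_truth_collapses_bands(self):
        # linear truth lies in the spline span: every resample refits exactly
        rng = np.random.default_rng(12)
        ages = rng.uniform(0, 100, 200)
        table = make_df(ages, 1.0 + 0.02 * ages)
        boot = traj.bootstrap_trajectory(
            table, "f", covariates=(), config=PipelineConfig(B=50, seed=1)
        )
        assert np.max(boot.band_high - boot.band_low) < 1e-6

    def test_extremum_ci_brackets_point_estimate(self, quad_table):
        table = quad_table(noise_sd=0.0225, n_per_cohort=100, seed=13)
        boot = traj.bootstrap_trajectory(
            table, "f", config=PipelineConfig(B=100, seed=2)
        )
        assert boot.extremum.kind == "peak"
        assert boot.extremum.ci_low <= boot.extremum.age <= boot.extremum.ci_high

    def test_longitudinal_subjects_resampled_whole(self, quad_truth):
        cohorts = synthetic.default_cohorts(60, infant_sessions=(2, 3))
        table, _ = synthetic.generate_feature_table(
            [quad_truth(noise_sd=0.02)], cohorts, 14
        )
        boot = traj.bootstrap_trajectory(
            table, "f", config=PipelineConfig(B=20, seed=3)
        )
        assert boot.n_replicates == 20


class TestBinRates:
    def test_constant_rate_in_every_bin(self):
        rng = np.random.default_rng(15)
        ages = rng.uniform(0, 100, 3000)
        model = traj.fit_trajectory(
            make_df(ages, np.exp(0.01 * ages)), "f", covariates=()
        )
        rates = traj.bin_rates(model)
        for name, rate in rates.items():
            assert rate == pytest.approx(1.0, abs=0.1), name

    def test_sign_flip_across_bins(self, quad_table):
        # quadratic peaking at 25: rising in development, falling in aging
        model = traj.fit_trajectory(quad_table(noise_sd=0.01, seed=16), "f")
        rates = traj.bin_rates(model)
        assert rates["development"] > 0 > rates["aging"]

    def test_matches_grid_average_oracle(self, quad_table):
        model = traj.fit_trajectory(quad_table(noise_sd=0.01, seed=17), "f")
        rates = traj.bin_rates(model, step=0.1)
        lo, hi = max(5.0, model.age_range[0]), min(21.0, model.age_range[1])
        grid = np.arange(lo, hi + 0.05, 0.1)
        oracle = np.nanmean(traj.percent_difference_per_year(model, grid))
        assert rates["development"] == pytest.approx(oracle, abs=1e-6)

    def test_bin_outside_fit_range_is_nan(self):
        ages = np.linspace(10, 100, 200)
        model = traj.fit_trajectory(make_df(ages, 1 + 0.01 * ages), "f", covariates=())
        rates = traj.bin_rates(model)
        assert np.isnan(rates["infant"])


class TestModelInvariances:
    def test_additive_shift_moves_curve_not_derivative(self, quad_table):
        table = quad_table(noise_sd=0.02, seed=18)
        shifted = table.assign(f=table["f"] + 5.0)
        m1 = traj.fit_trajectory(table, "f")
        m2 = traj.fit_trajectory(shifted, "f")
        grid = np.linspace(1, 99, 50)
        assert np.allclose(
            traj.predict_curve(m2, grid), traj.predict_curve(m1, grid) + 5.0, atol=1e-8
        )
        assert np.allclose(
            traj.difference_per_year(m2, grid),
            traj.difference_per_year(m1, grid),
            atol=1e-10,
        )

    def test_rescaling_preserves_percent_difference(self, quad_table):
        table = quad_table(noise_sd=0.02, seed=19)
        scaled = table.assign(f=table["f"] * 3.0)
        m1 = traj.fit_trajectory(table, "f")
        m2 = traj.fit_trajectory(scaled, "f")
        grid = np.linspace(1, 99, 50)
        assert np.allclose(
            traj.difference_per_year(m2, grid),
            3.0 * traj.difference_per_year(m1, grid),
            atol=1e-9,
        )
        assert np.allclose(
            traj.percent_difference_per_year(m2, grid),
            traj.percent_difference_per_year(m1, grid),
            atol=1e-8,
            equal_nan=True,
        )
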