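"""ML discrepancy, optimisation, standard errors and standardisation."""

import numpy as np
import pytest

from gpresem import (
    MLPathAnalysis,
    NonPositiveDefiniteError,
    SampleMoments,
    build_path_model,
    fit_ml,
    implied_covariance,
    ml_discrepancy,
    to_ram,
    triticale_gpre_model,
)
from gpresem.fit import recursive_ml_start


class TestSampleMoments:
    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            SampleMoments(np.array([[1.0, 0.5], [0.2, 1.0]]), 10, ("a", "b"))

    def test_rejects_non_pd(self):
        with pytest.raises(NonPositiveDefiniteError):
            SampleMoments(np.array([[1.0, 2.0], [2.0, 1.0]]), 10, ("a", "b"))

    def test_divisor_conversion_roundtrip(self):
        m = SampleMoments(np.eye(3) * 2, 10, ("a", "b", "c"), divisor="n-1")
        m2 = m.to_divisor("n")
        assert np.allclose(m2.S, m.S * 9 / 10)
        assert np.allclose(m2.to_divisor("n-1").S, m.S)

    def test_from_data_matches_numpy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        m = SampleMoments.from_data(X, divisor="n")
        assert np.allclose(m.S, np.cov(X, rowvar=False, ddof=0))


class TestImpliedCovariance:
    def test_no_paths_gives_diagonal(self):
        m = build_path_model(["a", "b", "c"])
        ram = to_ram(m)
        theta = np.array([2.0, 3.0, 4.0])  # variances only
        assert np.allclose(implied_covariance(ram, theta), np.diag(theta))

    def test_two_variable_chain_closed_form(self):
        m = build_path_model(["x", "y"], [("x", "y", "b")])
        ram = to_ram(m)
        b = 0.7
        theta_by_label = {"b": b, "resid(y)": 1.0, "var(x)": 1.0}
        theta = np.array([theta_by_label[lab] for lab in ram.labels()])
        sigma = implied_covariance(ram, theta)
        i, j = m.variables.index("x"), m.variables.index("y")
        assert sigma[i, j] == pytest.approx(b)
        assert sigma[j, j] == pytest.approx(b**2 + 1.0)

    def test_triticale_implied_cu_variance(self, gpre_fit):
        # the exogenous Cu variance passes straight through to the implied matrix
        i = gpre_fit.model.variables.index("Cu")
        assert gpre_fit.implied_sigma[i, i] == pytest.approx(12.4414, abs=1e-3)


class TestDiscrepancy:
    def test_zero_iff_equal(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert ml_discrepancy(S, S) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # S = diag(2,2), Sigma = diag(1,1): F = 2*(ln(1/2) + 2 - 1) = 2(1 - ln 2)
        S, sigma = np.diag([2.0, 2.0]), np.eye(2)
        assert ml_discrepancy(S, sigma) == pytest.approx(2 * (1 - np.log(2)), rel=1e-12)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        B = rng.normal(size=(4, 4))
        sigma = B @ B.T + 4 * np.eye(4)
        for c in (0.1, 3.0, 250.0):
            assert ml_discrepancy(c * S, c * sigma) == pytest.approx(
                ml_discrepancy(S, sigma), rel=1e-10
            )

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + 3 * np.eye(3)
            B = rng.normal(size=(3, 3))
            sigma = B @ B.T + 3 * np.eye(3)
            assert ml_discrepancy(S, sigma) >= 0

    def test_non_pd_reports_matrix_name(self):
        S = np.eye(2)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NonPositiveDefiniteError, match="Sigma"):
            ml_discrepancy(S, bad)


def _chain_moments(n=50):
    """Covariance for x -> y -> z generated from known coefficients."""
    rng = np.random.default_rng(11)
    x = rng.normal(size=2000)
    y = 0.8 * x + rng.normal(size=2000)
    z = -0.5 * y + rng.normal(size=2000)
    X = np.column_stack([x, y, z])
    return SampleMoments.from_data(X, variable_names=("x", "y", "z"), divisor="n")


class TestFitML:
    def test_saturated_model_perfect_fit(self):
        moments = _chain_moments()
        m = build_path_model(
            ["x", "y", "z"], [], [("x", "y", "c1"), ("x", "z", "c2"), ("y", "z", "c3")]
        )
        fit = fit_ml(m, moments)
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.implied_sigma, moments.S, atol=1e-8)
        assert fit.df == 0

    def test_just_identified_chain_equals_ols(self):
        """ML path estimates match per-equation least squares (normal equations)."""
        moments = _chain_moments()
        m = build_path_model(["x", "y", "z"], [("x", "y", "byx"), ("y", "z", "bzy")])
        fit = fit_ml(m, moments)
        S = moments.S
        # independent normal-equation oracle
        b_yx = S[0, 1] / S[0, 0]
        b_zy = S[1, 2] / S[1, 1]
        assert fit.estimates["byx"] == pytest.approx(b_yx, abs=1e-9)
        assert fit.estimates["bzy"] == pytest.approx(b_zy, abs=1e-9)

    def test_single_predictor_beta_is_correlation(self):
        moments = _chain_moments()
        m = build_path_model(["x", "y"], [("x", "y", "b")])
        fit = fit_ml(m, moments.reorder(("x", "y")))
        S = moments.S
        r = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert fit.standardized["b"] == pytest.approx(r, abs=1e-9)

    def test_gradient_norm_at_optimum(self, gpre_fit):
        assert gpre_fit.gradient_norm < 1e-6

    def test_perturbed_restart_reaches_same_minimum(self, gpre_model, gpre_moments, gpre_fit):
        rng = np.random.default_rng(5)
        theta0 = gpre_fit.theta * (1 + 0.25 * rng.normal(size=gpre_fit.theta.size))
        refit = fit_ml(gpre_model, gpre_moments, theta0=theta0)
        assert refit.f_min == pytest.approx(gpre_fit.f_min, abs=1e-8)

    def test_chi_square_invariant_to_divisor(self, gpre_model, gpre_moments):
        fit_n = fit_ml(gpre_model, gpre_moments)
        fit_nm1 = fit_ml(gpre_model, gpre_moments.to_divisor("n-1"))
        assert fit_nm1.chi_square == pytest.approx(fit_n.chi_square, abs=1e-8)
        # variance estimates differ by exactly (n-1)/n
        n = gpre_moments.n
        assert fit_n.estimates["var(Cu)"] == pytest.approx(
            fit_nm1.estimates["var(Cu)"] * (n - 1) / n, rel=1e-9
        )

    def test_scale_equivariance(self, gpre_model, gpre_moments, gpre_fit):
        """Rescaling a variable leaves chi-square and betas unchanged and
        transforms unstandardised paths by the scale ratio."""
        c = 1000.0
        i = gpre_model.variables.index("GSH")
        D = np.eye(gpre_moments.p)
        D[i, i] = c
        scaled = SampleMoments(
            D @ gpre_moments.S @ D, gpre_moments.n, gpre_moments.variable_names, "n"
        )
        refit = fit_ml(gpre_model, scaled)
        assert refit.chi_square == pytest.approx(gpre_fit.chi_square, abs=1e-7)
        for lab in (f"lambda{i}" for i in range(1, 13)):
            assert refit.standardized[lab] == pytest.approx(
                gpre_fit.standardized[lab], abs=1e-8
            )
        # GSH -> GPRE unstandardised coefficient shrinks by 1/c
        assert refit.estimates["lambda9"] == pytest.approx(
            gpre_fit.estimates["lambda9"] / c, rel=1e-7
        )
        assert refit.standard_errors["lambda9"] == pytest.approx(
            gpre_fit.standard_errors["lambda9"] / c, rel=1e-6
        )

    def test_improper_solution_detection(self, gpre_fit):
        """Negative variance entries are flagged as improper (Heywood);
        residual variances here are conditional variances, so a proper
        sample matrix yields a proper solution."""
        from gpresem.fit import has_negative_variance

        assert not gpre_fit.heywood
        assert not has_negative_variance(gpre_fit.ram, gpre_fit.theta)
        broken = gpre_fit.theta.copy()
        broken[list(gpre_fit.ram.labels()).index("delta5")] = -0.1
        assert has_negative_variance(gpre_fit.ram, broken)
        # path coefficients may be negative without tripping the flag
        broken2 = gpre_fit.theta.copy()
        broken2[list(gpre_fit.ram.labels()).index("lambda7")] = -5.0
        assert not has_negative_variance(gpre_fit.ram, broken2)

    def test_missing_variable_in_moments(self, gpre_model):
        moments = SampleMoments(np.eye(2), 10, ("Cu", "LMP"))
        with pytest.raises(ValueError, match="do not cover"):
            fit_ml(gpre_model, moments)

    def test_start_values_are_deterministic(self, gpre_model, gpre_moments):
        t1 = recursive_ml_start(gpre_model, gpre_moments.S)
        t2 = recursive_ml_start(gpre_model, gpre_moments.S)
        assert np.array_equal(t1, t2)


class TestEstimatorAPI:
    def test_fit_from_dataframe(self, gpre_model):
        import pandas as pd

        from gpresem import generate_dataset, published_theta
        from gpresem.fit import implied_covariance

        ram = to_ram(gpre_model)
        sigma = implied_covariance(ram, published_theta(gpre_model))
        # delta3 prints as 0, which would make GSH collinear; bump it
        theta = published_theta(gpre_model)
        theta[list(ram.labels()).index("delta3")] = 1e-8
        sigma = implied_covariance(ram, theta)
        ds = generate_dataset(
            mean=np.zeros(7), covariance=sigma, n=200, seed=42,
            variable_names=gpre_model.variables,
        )
        est = MLPathAnalysis(model=gpre_model).fit(ds.data)
        assert est.converged_
        assert est.df_ == 8
        assert est.chi_square_ >= 0

    def test_get_set_params_clone(self, gpre_model):
        from sklearn.base import clone

        est = MLPathAnalysis(model=gpre_model, divisor="n-1", max_iter=123)
        cloned = clone(est)
        assert cloned.get_params()["max_iter"] == 123
        assert cloned.get_params()["divisor"] == "n-1"

    def test_score_is_negative_discrepancy(self, gpre_model, gpre_moments):
        est = MLPathAnalysis(model=gpre_model).fit_moments(gpre_moments)
        assert est.score() == pytest.approx(-est.f_min_)
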