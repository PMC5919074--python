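"""SEM engine: model language, implied covariance, ML fit, indices, rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from ecoimmune.sem import (
    SemModelSpec, acceptance_report, default_models, fit_indices, fit_ml,
    implied_covariance, parameter_names, parse_model,
)


def data_with_exact_covariance(cov, n, columns, seed=0):
    """A data matrix whose *sample* covariance (ddof=1) equals ``cov`` exactly."""
    rng = np.random.default_rng(seed)
    p = cov.shape[0]
    Z = rng.normal(size=(n, p))
    Z -= Z.mean(axis=0)
    # whiten, then color with the Cholesky factor of the target
    S = Z.T @ Z / (n - 1)
    Z = Z @ np.linalg.inv(np.linalg.cholesky(S)).T
    X = Z @ np.linalg.cholesky(cov).T
    return pd.DataFrame(X, columns=columns)


class TestModelLanguage:
    def test_parse_round_trip_of_structure(self):
        spec = parse_model("""
            # adaptive compartment
            immune =~ cd4 + cd8 + cd19
            condition ~ age + season
            immune ~ condition + age
            season ~~ age
        """)
        assert spec.latents == {"immune": ["cd4", "cd8", "cd19"]}
        assert ("age", "condition") in spec.paths
        assert ("condition", "immune") in spec.paths
        assert ("season", "age") in spec.covariances
        assert "immune" not in spec.observed

    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="cycle"):
            parse_model("a ~ b\nb ~ a")

    def test_overidentified_model_rejected(self):
        # 2 observed variables give 3 moments; a single-indicator latent with
        # its own residual variance asks for 4 free parameters
        spec = parse_model("f =~ y\nf ~ x")
        with pytest.raises(ValueError, match="not identified"):
            spec.n_free_parameters()


class TestDefaultModels:
    @pytest.mark.parametrize("name,n_obs,df", [
        ("adaptive", 7, 8), ("innate", 8, 14), ("humoral", 7, 8),
    ])
    def test_degrees_of_freedom(self, name, n_obs, df):
        spec = default_models()[name]
        assert len(spec.observed) == n_obs
        assert spec.degrees_of_freedom() == df

    def test_no_reverse_path_into_infection_from_condition(self):
        spec = default_models()["adaptive"]
        assert ("condition", "infection") not in spec.paths
        assert ("immune_state", "infection") not in spec.paths


class TestImpliedCovariance:
    def test_no_paths_unit_variances_identity(self):
        spec = parse_model("x ~~ y")  # two exogenous observed
        names = parameter_names(spec)
        theta = [1.0 if "~~" in n and n.split("~~")[0] == n.split("~~")[1]
                 else 0.0 for n in names]
        np.testing.assert_allclose(implied_covariance(spec, theta), np.eye(2))

    def test_single_path_tracing_algebra(self):
        spec = parse_model("y ~ x")
        names = parameter_names(spec)
        theta = np.zeros(len(names))
        theta[names.index("y~x")] = 0.7
        theta[names.index("x~~x")] = 1.0
        theta[names.index("y~~y")] = 1.0
        sigma = implied_covariance(spec, theta)
        i, j = spec.observed.index("x"), spec.observed.index("y")
        assert sigma[i, j] == pytest.approx(0.7)
        assert sigma[j, j] == pytest.approx(0.7 ** 2 + 1.0)

    def test_matches_generating_covariance_of_synthetic_model(self):
        # build theta from known generating values and compare against
        # hand-propagated covariance of the same linear system
        spec = parse_model("""
            immune =~ y1 + y2
            immune ~ x
        """)
        names = parameter_names(spec)
        lam2, beta = 0.8, 0.5
        var_x, psi, th1, th2 = 2.0, 1.0, 0.3, 0.4
        theta = np.zeros(len(names))
        theta[names.index("immune=~y2")] = lam2
        theta[names.index("immune~x")] = beta
        theta[names.index("x~~x")] = var_x
        theta[names.index("immune~~immune")] = psi
        theta[names.index("y1~~y1")] = th1
        theta[names.index("y2~~y2")] = th2
        var_l = beta ** 2 * var_x + psi
        expected = {
            ("y1", "y1"): var_l + th1,
            ("y2", "y2"): lam2 ** 2 * var_l + th2,
            ("y1", "y2"): lam2 * var_l,
            ("y1", "x"): beta * var_x,
            ("y2", "x"): lam2 * beta * var_x,
            ("x", "x"): var_x,
        }
        sigma = implied_covariance(spec, theta)
        for (a, b), v in expected.items():
            i, j = spec.observed.index(a), spec.observed.index(b)
            assert sigma[i, j] == pytest.approx(v, abs=1e-12)

    def test_theta_length_checked(self):
        spec = parse_model("y ~ x")
        with pytest.raises(ValueError, match="length"):
            implied_covariance(spec, [1.0])


class TestFitMl:
    def test_saturated_model_perfect_fit(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["x", "y"])
        spec = parse_model("y ~ x")  # just-identified: df = 0
        assert spec.degrees_of_freedom() == 0
        fit = fit_ml(spec, df, rescale=False, seed=0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0
        assert fit.srmr == pytest.approx(0.0, abs=1e-6)

    def test_one_factor_loadings_recovered_from_exact_covariance(self):
        loadings = np.array([0.7, 0.8, 0.9])
        cov = np.outer(loadings, loadings)
        np.fill_diagonal(cov, 1.0)  # unit-variance indicators
        df = data_with_exact_covariance(cov, 500, ["y1", "y2", "y3"])
        spec = parse_model("f =~ y1 + y2 + y3")
        fit = fit_ml(spec, df, rescale=False, seed=0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        # factor variance absorbs the first loading: lambda_k / lambda_1
        assert fit.estimate("f=~y2").estimate == pytest.approx(0.8 / 0.7, abs=1e-6)
        assert fit.estimate("f=~y3").estimate == pytest.approx(0.9 / 0.7, abs=1e-6)
        assert fit.estimate("f~~f").estimate == pytest.approx(0.49, abs=1e-6)
        # standardized loadings recover the original values
        assert fit.estimate("f=~y2").std_estimate == pytest.approx(0.8, abs=1e-6)

    def test_chi2_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        y = 0.5 * x + rng.normal(size=400)
        z = 0.3 * y + rng.normal(size=400)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        spec = parse_model("y ~ x\nz ~ y")
        f1 = fit_ml(spec, df, rescale=False, seed=0)
        df2 = df.copy()
        df2["y"] = df2["y"] * 37.0
        f2 = fit_ml(spec, df2, rescale=False, seed=0)
        assert f1.chi2 == pytest.approx(f2.chi2, abs=1e-6)
        # standardized estimates are scale-free
        assert f1.estimate("y~x").std_estimate == pytest.approx(
            f2.estimate("y~x").std_estimate, abs=1e-8)

    def test_standardized_solution_invariant_to_pow10_rescale(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 2, size=300)
        y = 50.0 * x + rng.normal(0, 40, size=300)
        df = pd.DataFrame({"x": x, "y": y})
        spec = parse_model("y ~ x")
        raw = fit_ml(spec, df, rescale=False, seed=0)
        scaled = fit_ml(spec, df, rescale=True, seed=0)
        assert scaled.rescale_exponents["y"] != 0
        assert raw.estimate("y~x").std_estimate == pytest.approx(
            scaled.estimate("y~x").std_estimate, abs=1e-8)

    def test_listwise_deletion_reported(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(60, 2)), columns=["x", "y"])
        df.loc[:9, "y"] = np.nan
        fit = fit_ml(parse_model("y ~ x"), df, rescale=False, seed=0)
        assert fit.n == 50

    def test_too_few_rows_raise(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 2)),
                          columns=["x", "y"])
        with pytest.raises(ValueError, match="complete rows"):
            fit_ml(parse_model("y ~ x"), df)

    def test_fml_nonnegative_and_zero_only_at_saturation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = 0.4 * x + rng.normal(size=300)
        z = rng.normal(size=300)  # unrelated; model forces z ~ y only
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        spec = parse_model("y ~ x\nz ~ y")
        fit = fit_ml(spec, df, rescale=False, seed=0)
        assert fit.fml >= 0

    def test_parametric_bootstrap_chi2_matches_reference_distribution(self):
        # simulate from a fitted model with Gaussian errors: the engine's
        # chi2 must follow chi2_df (KS test over replicates)
        spec = parse_model("f =~ y1 + y2 + y3 + y4")
        assert spec.degrees_of_freedom() == 2
        loadings = np.array([1.0, 0.8, 0.9, 0.7])
        rng = np.random.default_rng(5)
        chi2s = []
        for rep in range(150):
            n = 300
            f = rng.normal(size=n)
            Y = np.column_stack([
                lam * f + rng.normal(0, 0.6, size=n) for lam in loadings
            ])
            df = pd.DataFrame(Y, columns=["y1", "y2", "y3", "y4"])
            fit = fit_ml(spec, df, rescale=False, seed=rep, n_starts=2)
            chi2s.append(fit.chi2)
        ks = stats.kstest(chi2s, stats.chi2(df=2).cdf)
        assert ks.pvalue > 0.01, f"KS p = {ks.pvalue:.4f}"
        assert np.mean(chi2s) == pytest.approx(2.0, rel=0.25)


class TestFitIndices:
    def test_rmsea_formula_arithmetic(self):
        S = np.eye(3)
        out = fit_indices(20.0, 10, 110.0, 15, 101, S, S)
        assert out["rmsea"] == pytest.approx(0.1)

    def test_cfi_formula_arithmetic(self):
        S = np.eye(3)
        out = fit_indices(20.0, 10, 110.0, 15, 101, S, S)
        assert out["cfi"] == pytest.approx(1 - 10 / 95)

    def test_rmsea_ci_matches_independent_root_finder(self):
        chi2, df, n = 20.0, 10, 101
        S = np.eye(3)
        out = fit_indices(chi2, df, 110.0, 15, n, S, S)

        def bound(tail):
            # independent search on the survival function
            f = lambda lam: stats.ncx2.sf(chi2, df, lam) - (1 - tail)
            if stats.chi2.cdf(chi2, df) <= tail:
                return 0.0
            lam = optimize.brentq(f, 0.0, 1000.0, xtol=1e-12)
            return np.sqrt(lam / (df * (n - 1)))

        assert out["rmsea_ci"][0] == pytest.approx(bound(0.95), abs=1e-6)
        assert out["rmsea_ci"][1] == pytest.approx(bound(0.05), abs=1e-6)

    def test_df_zero_degenerate(self):
        S = np.eye(2)
        out = fit_indices(0.0, 0, 5.0, 1, 50, S, S)
        assert out["rmsea"] == 0.0 and out["rmsea_ci"] == (0.0, 0.0)

    def test_srmr_on_known_residuals(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        sigma = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = fit_indices(1.0, 1, 10.0, 1, 50, S, sigma)
        # residuals: 0 on both diagonal entries, 0.2 on the off-diagonal
        assert out["srmr"] == pytest.approx(np.sqrt(0.2 ** 2 / 3))


class TestAcceptanceReport:
    def _result(self, **kw):
        from ecoimmune.sem import SemFitResult

        base = dict(
            spec=default_models()["adaptive"], n=100, estimates=[],
            theta=np.zeros(1), fml=0.0, chi2=7.64, df=8, chi2_p=0.469,
            baseline_chi2=300.0, baseline_df=21, rmsea=0.0,
            rmsea_ci=(0.0, 0.126), cfi=1.0, srmr=0.03,
            sample_cov=np.eye(2), implied_cov=np.eye(2), converged=True,
            gradient_norm=0.0, warnings=[], rescale_exponents={},
        )
        base.update(kw)
        return SemFitResult(**base)

    def test_small_rmsea_small_srmr_high_cfi_is_good(self):
        report = acceptance_report(self._result())
        assert report["verdict"] == "good"

    def test_rmsea_above_05_accepted_when_ci_lower_zero(self):
        report = acceptance_report(self._result(
            rmsea=0.058, rmsea_ci=(0.0, 0.139), cfi=0.987, srmr=0.031,
            chi2=10.65, chi2_p=0.22))
        assert report["verdict"] == "good"

    def test_significant_chi2_flagged(self):
        report = acceptance_report(self._result(
            rmsea=0.137, rmsea_ci=(0.089, 0.188), cfi=0.891, srmr=0.082,
            chi2=40.46, df=14, chi2_p=0.0002))
        assert report["verdict"] == "not_good_fit"
        assert not report["chi2_ok"]
        assert any("not a significantly good fit" in r for r in report["reasons"])

    def test_cfi_between_080_and_095_acceptable(self):
        report = acceptance_report(self._result(
            rmsea=0.04, cfi=0.90, srmr=0.06))
        assert report["verdict"] == "acceptable"
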