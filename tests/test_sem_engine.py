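import numpy as np
import pandas as pd
import pytest

from potsim import (
    SemInputError,
    SemModelSpec,
    factor_scores,
    fit_indices,
    fit_ml,
    implied_covariance,
    model1_spec,
    model2_spec,
    rmsea_ci,
    saturated_spec,
    study2_spec,
)
from potsim.sem_engine import Param, _fml_and_grad, rmsea_point, srmr


def one_factor_spec(names, loadings_fixed_first=True):
    params = []
    for k, n in enumerate(names):
        params.append(Param(n, "~", "F", 1.0 if (loadings_fixed_first and k == 0) else None))
        params.append(Param(n, "~~", n))
    if loadings_fixed_first:
        params.append(Param("F", "~~", "F"))
    else:
        params.append(Param("F", "~~", "F", 1.0))
    return SemModelSpec(observed=tuple(names), latent=("F",), params=tuple(params))


STRUCT_2006 = {
    "factors": {
        "inh": ["antisaccade", "stopsignal", "stroop"],
        "upd": ["keeptrack", "lettermem", "s2back"],
        "shf": ["numlet", "colshape", "catswitch"],
    },
    "g": {"indicators": ["raven", "blockdesign", "wais"]},
}
STRUCT_2011 = {
    "factors": STRUCT_2006["factors"],
    "g": {"composite": "wiq"},
}
STRUCT_BENEDEK = {
    "factors": {
        "inh": ["stroop1", "stroop2", "stroop3"],
        "upd": ["nback1", "nback2", "nback3"],
        "shf": ["numlet1", "numlet2", "numlet3"],
    },
    "g": {"indicators": ["nir", "vdr"]},
}


class TestModelSpecs:
    def test_model1_structure_and_df(self):
        spec = model1_spec()
        assert spec.n_observed == 9 and spec.df == 24 and spec.n_free == 21
        # each observed has exactly one loading
        for obs in spec.observed:
            loadings = [p for p in spec.params if p.op == "~" and p.lhs == obs]
            assert len(loadings) == 1

    def test_model2_adds_orthogonal_predictors(self):
        m1, m2 = model1_spec(), model2_spec()
        assert m2.df == 51
        assert m2.df - m1.df == 27
        zeros = [
            p for p in m2.params
            if p.op == "~~" and p.lhs != p.rhs and p.value == 0.0
        ]
        assert len(zeros) == 3  # EF-EF covariances fixed at 0
        # dropping the three regressions recovers model 1's directed pattern
        m2_paths = {(p.lhs, p.rhs) for p in m2.params if p.op == "~" and p.lhs != "g"}
        m1_paths = {(p.lhs, p.rhs) for p in m1.params if p.op == "~"}
        assert m1_paths == m2_paths

    @pytest.mark.parametrize(
        "structure,n_obs,df",
        [
            (STRUCT_2006, 12, 51),
            (STRUCT_2011, 10, 33),
            (STRUCT_BENEDEK, 11, 41),
        ],
    )
    def test_study2_degrees_of_freedom(self, structure, n_obs, df):
        spec = study2_spec(structure)
        assert spec.n_observed == n_obs
        assert spec.df == df

    def test_study2_free_correlations_variant(self):
        spec = study2_spec({**STRUCT_2006, "ef_covariances": "free"})
        assert spec.df == 48  # 3 extra free covariances

    def test_study2_single_factor_reduces_to_plain_cfa(self):
        spec = study2_spec(
            {"factors": {"upd": ["a", "b", "c"]}, "g": {"composite": "y"}}
        )
        assert spec.n_observed == 4
        assert spec.latent == ("upd",)

    def test_study2_rejects_bad_structures(self):
        with pytest.raises(SemInputError):
            study2_spec({"factors": {}, "g": {"composite": "y"}})
        with pytest.raises(SemInputError):
            study2_spec({"factors": {"f": ["a", "a"]}, "g": {"composite": "y"}})
        with pytest.raises(SemInputError):
            study2_spec({"factors": {"f": ["a", "b"]}})

    def test_serialization_round_trip(self):
        for spec in (model1_spec(), model2_spec(), study2_spec(STRUCT_2011)):
            assert SemModelSpec.from_json(spec.to_json()) == spec


class TestImpliedCovariance:
    def test_zero_loadings_give_diagonal(self):
        spec = one_factor_spec(["a", "b", "c"], loadings_fixed_first=False)
        theta = []
        for p in spec.free_params:
            theta.append(0.0 if p.op == "~" else 2.0)
        sigma = implied_covariance(spec, np.array(theta))
        np.testing.assert_allclose(sigma, np.eye(3) * 2.0, atol=1e-12)

    def test_one_factor_closed_form(self):
        spec = one_factor_spec(["a", "b", "c"], loadings_fixed_first=False)
        lam = np.array([0.9, 0.7, 0.5])
        resid = np.array([0.3, 0.4, 0.5])
        theta = np.r_[lam[0], resid[0], lam[1], resid[1], lam[2], resid[2]]
        # free params interleave (loading, residual) per variable
        sigma = implied_covariance(spec, theta)
        expected = np.outer(lam, lam) + np.diag(resid)
        np.testing.assert_allclose(sigma, expected, atol=1e-12)

    def test_matches_large_sample_simulation(self, rng):
        lam = np.array([1.0, 0.8, 0.6])
        resid = np.array([0.5, 0.6, 0.7])
        spec = one_factor_spec(["a", "b", "c"], loadings_fixed_first=False)
        theta = np.r_[lam[0], resid[0], lam[1], resid[1], lam[2], resid[2]]
        sigma = implied_covariance(spec, theta)
        n = 200_000
        f = rng.standard_normal(n)
        X = np.outer(f, lam) + rng.standard_normal((n, 3)) * np.sqrt(resid)
        np.testing.assert_allclose(np.cov(X, rowvar=False), sigma, atol=0.01)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, one_iteration):
        spec = model1_spec()
        S = one_iteration.fit1.sample_cov
        logdet = np.linalg.slogdet(S)[1]
        theta = one_iteration.fit1.theta * 1.05  # off-optimum point
        f0, grad = _fml_and_grad(spec, theta, S, logdet)
        eps = 1e-6
        for k in range(len(theta)):
            tp = theta.copy(); tp[k] += eps
            tm = theta.copy(); tm[k] -= eps
            fd = (_fml_and_grad(spec, tp, S, logdet)[0]
                  - _fml_and_grad(spec, tm, S, logdet)[0]) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestFitML:
    def test_saturated_model_has_zero_discrepancy(self, rng):
        A = rng.standard_normal((4, 4))
        S = pd.DataFrame(A @ A.T + 4 * np.eye(4), index=list("abcd"), columns=list("abcd"))
        fit = fit_ml(saturated_spec(list("abcd")), S, 100)
        assert fit.fml == pytest.approx(0.0, abs=1e-8)
        assert fit.chisq == pytest.approx(0.0, abs=1e-5)
        assert fit.df == 0
        np.testing.assert_allclose(fit.implied_cov, S.to_numpy(), atol=1e-5)

    def test_rejects_bad_input(self):
        spec = one_factor_spec(["a", "b", "c"])
        bad = pd.DataFrame(
            -np.eye(3), index=["a", "b", "c"], columns=["a", "b", "c"]
        )
        with pytest.raises(SemInputError):
            fit_ml(spec, bad, 100)
        good = pd.DataFrame(
            np.eye(3), index=["a", "b", "c"], columns=["a", "b", "c"]
        )
        with pytest.raises(SemInputError):
            fit_ml(spec, good, 3)  # N too small

    def test_exact_recovery_from_implied_covariance(self):
        """Fitting a model to its own implied covariance returns the truth."""
        spec = model1_spec()
        # walk the free-parameter order and assign plausible true values
        vals = []
        for p in spec.free_params:
            if p.op == "~":
                vals.append(0.9)
            elif p.lhs == p.rhs and p.lhs in spec.observed:
                vals.append(0.5)
            else:
                vals.append(0.6)
        vals = np.array(vals)
        sigma = implied_covariance(spec, vals)
        fit = fit_ml(spec, pd.DataFrame(sigma, index=spec.observed, columns=spec.observed), 1000)
        assert fit.converged
        assert fit.fml == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.theta, vals, atol=1e-4)

    def test_parameter_recovery_on_simulated_cfa_data(self, rng):
        """One-factor data, loadings 0.8: recovered within 0.03 at N=5000."""
        n, lam = 5000, 0.8
        f = rng.standard_normal(n)
        X = np.outer(f, np.full(4, lam)) + rng.standard_normal((n, 4)) * np.sqrt(1 - lam**2)
        names = ["x1", "x2", "x3", "x4"]
        S = pd.DataFrame(np.cov(X, rowvar=False), index=names, columns=names)
        fit = fit_ml(one_factor_spec(names), S, n)
        assert fit.converged
        tab = fit.estimates
        std_loadings = tab[(tab.op == "~") & (tab.rhs == "F")]["std"].to_numpy()
        np.testing.assert_allclose(std_loadings, lam, atol=0.03)

    def test_discrepancy_positive_off_saturation(self, one_iteration):
        assert one_iteration.fit1.fml > 0
        assert one_iteration.fit1.chisq == pytest.approx(
            999 * one_iteration.fit1.fml
        )


class TestFitIndices:
    def test_chisq_below_df_clamps(self, rng):
        # a wildly overparameterized fit: chisq ~ 0 < df is emulated via
        # the closed forms directly
        assert rmsea_point(20.0, 24, 1000) == 0.0
        lo, hi = rmsea_ci(24.0, 24, 1000)
        assert lo == 0.0

    def test_printed_rmsea_arithmetic(self):
        assert rmsea_point(26.47, 24, 1000) == pytest.approx(
            np.sqrt(2.47 / (24 * 999)), abs=1e-12
        )
        assert round(rmsea_point(26.47, 24, 1000), 2) == 0.01
        assert round(rmsea_point(144.59, 51, 1000), 2) == 0.04

    def test_confidence_interval_inversion(self):
        assert tuple(round(x, 2) for x in rmsea_ci(26.47, 24, 1000)) == (0.0, 0.03)
        assert tuple(round(x, 2) for x in rmsea_ci(144.59, 51, 1000)) == (0.03, 0.05)
        lo, hi = rmsea_ci(100.0, 51, 1000)
        assert lo <= rmsea_point(100.0, 51, 1000) <= hi

    def test_srmr_zero_when_model_reproduces_sample(self, rng):
        A = rng.standard_normal((3, 3))
        S = A @ A.T + 3 * np.eye(3)
        assert srmr(S, S) == 0.0

    def test_indices_on_fitted_models(self, one_iteration):
        for fit in (one_iteration.fit1, one_iteration.fit2):
            fi = fit_indices(fit)
            assert 0 <= fi.cfi <= 1
            assert fi.rmsea >= 0 and fi.srmr >= 0
            assert fi.rmsea_ci[0] <= fi.rmsea + 1e-9
            assert fi.rmsea + 1e-9 >= fi.rmsea_ci[0] and fi.rmsea <= fi.rmsea_ci[1] + 1e-9


class TestStandardizedSolution:
    def test_equal_correlation_one_factor(self):
        r = 0.49
        names = ["a", "b", "c", "d"]
        S = pd.DataFrame(
            np.full((4, 4), r) + (1 - r) * np.eye(4), index=names, columns=names
        )
        fit = fit_ml(one_factor_spec(names), S, 500)
        tab = fit.estimates
        std = tab[(tab.op == "~")]["std"].to_numpy()
        np.testing.assert_allclose(std, np.sqrt(r), atol=1e-6)

    def test_identification_invariance(self):
        """Marker-fixed and unit-variance identifications agree when fitted."""
        spec_marker = model1_spec()
        vals = []
        for p in spec_marker.free_params:
            if p.op == "~":
                vals.append(0.9)
            elif p.lhs in spec_marker.observed:
                vals.append(0.5)
            else:
                vals.append(0.6)
        sigma = implied_covariance(spec_marker, np.array(vals))
        S = pd.DataFrame(sigma, index=spec_marker.observed, columns=spec_marker.observed)

        # unit-variance identification: free all loadings, fix latent
        # (disturbance) variances to 1
        params = []
        for f, inds in zip(
            ("Fluid", "Verbal", "Spatial"),
            (spec_marker.observed[:3], spec_marker.observed[3:6], spec_marker.observed[6:]),
        ):
            for ind in inds:
                params.append(Param(ind, "~", f))
                params.append(Param(ind, "~~", ind))
            params.append(Param(f, "~", "g"))
            params.append(Param(f, "~~", f, 1.0))
        params.append(Param("g", "~~", "g", 1.0))
        spec_std = SemModelSpec(
            observed=spec_marker.observed,
            latent=("Fluid", "Verbal", "Spatial", "g"),
            params=tuple(params),
        )
        assert spec_std.df == spec_marker.df

        fit_a = fit_ml(spec_marker, S, 1000)
        fit_b = fit_ml(spec_std, S, 1000)
        assert fit_a.chisq == pytest.approx(fit_b.chisq, abs=1e-6)
        ta, tb = fit_a.estimates, fit_b.estimates
        for lhs, rhs in [(o, f) for o, f in zip(
            spec_marker.observed,
            ["Fluid"] * 3 + ["Verbal"] * 3 + ["Spatial"] * 3,
        )] + [("Fluid", "g"), ("Verbal", "g"), ("Spatial", "g")]:
            sa = ta[(ta.lhs == lhs) & (ta.op == "~") & (ta.rhs == rhs)]["std"].iloc[0]
            sb = tb[(tb.lhs == lhs) & (tb.op == "~") & (tb.rhs == rhs)]["std"].iloc[0]
            assert abs(abs(sa) - abs(sb)) < 1e-6


class TestFactorScores:
    def test_mean_zero_and_single_indicator_proportionality(self, rng):
        spec = SemModelSpec(
            observed=("x",),
            latent=("F",),
            params=(
                Param("x", "~", "F", 1.0),
                Param("x", "~~", "x", 0.1),
                Param("F", "~~", "F"),
            ),
        )
        S = pd.DataFrame([[1.0]], index=["x"], columns=["x"])
        fit = fit_ml(spec, S, 200)
        x = rng.standard_normal(200)
        scores = factor_scores(fit, x.reshape(-1, 1), latent="F")
        assert scores.mean() == pytest.approx(0.0, abs=1e-12)
        r = np.corrcoef(scores, x)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_g_scores_track_simulated_general_composite(self, one_iteration):
        """Model-1 g scores correlate strongly with the broad-test composite."""
        frame = one_iteration.scores
        composite = frame.iloc[:, :9].sum(axis=1).to_numpy(dtype=float)
        g = factor_scores(one_iteration.fit1, frame, latent="g")
        assert np.corrcoef(g, composite)[0, 1] > 0.9
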