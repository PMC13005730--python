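import numpy as np
import pytest

from jmncc.datamodel import CohortData, SubjectSurvival
from jmncc.estimation import (
    _fit_core,
    adjust_pvalues,
    fit_fjmncc,
    fit_wjmncc,
    fit_wjmncc_both,
    make_template,
    wald_test,
)
from jmncc.likelihood import LikelihoodData
from jmncc.model import ModelTemplate


class TestWald:
    def test_zero_estimate(self):
        z, p = wald_test(0.0, 1.0)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_nominal_boundary(self):
        _, p = wald_test(1.959963984540054, 1.0)
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_z(self):
        ps = [wald_test(z, 1.0)[1] for z in (0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)


class TestAdjustPvalues:
    def test_bonferroni_pair(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04], "bonferroni"), [0.02, 0.08]
        )

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            np.testing.assert_allclose(adjust_pvalues([0.03], method), [0.03])

    def test_bh_step_up_hand_computed(self):
        # min over j>=i of p_(j) m / j: all equal 0.04 for this ladder
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04] * 4
        )

    def test_order_preserved(self):
        p = np.array([0.2, 0.001, 0.04, 0.6])
        adj = adjust_pvalues(p, "bh")
        assert list(np.argsort(adj)) == list(np.argsort(p))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bh")
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "holm-sidak-nope")


class TestFitting:
    def test_exponential_mle_closed_form(self):
        """With beta=alpha=0, Q=1, K=1 the baseline MLE is events/time."""
        rng = np.random.default_rng(1)
        T = rng.exponential(5.0, 80)
        status = (rng.uniform(size=80) < 0.7).astype(int)
        surv = [
            SubjectSurvival(f"s{i}", float(T[i]), int(status[i]), {}) for i in range(80)
        ]
        from jmncc.datamodel import LongitudinalSeries

        series = {
            "s0": LongitudinalSeries("s0", (0.0,), (0.1,)),
        }
        cohort = CohortData(surv, series, {s.id: 1 if s.id == "s0" else 0 for s in surv}, [])
        template = ModelTemplate(K=1, knots=(np.inf,), surv_covariates=())
        layout = template.layout()
        from scipy.optimize import minimize_scalar

        from jmncc.likelihood import full_loglik
        from jmncc.model import ParamVector

        def neg_ll(log_xi):
            v = np.zeros(layout.size)
            v[layout.sl_xi] = log_xi
            return -full_loglik(ParamVector(layout, v), cohort, nodes=9)

        opt = minimize_scalar(neg_ll, bounds=(-8, 2), method="bounded",
                              options={"xatol": 1e-12})
        closed_form = status.sum() / T.sum()
        assert np.exp(opt.x) == pytest.approx(closed_form, rel=1e-6)

    def test_gradient_small_at_optimum(self, small_ncc_pipeline):
        from jmncc.estimation import _objective

        template = small_ncc_pipeline["template"]
        layout = template.layout()
        data = LikelihoodData.from_cohort(small_ncc_pipeline["full"], template)
        w = np.ones(data.n)
        res, converged, scaled_g = _fit_core(layout, data, w, 15)
        assert converged
        assert scaled_g < 1e-4

    def test_fit_result_structure(self, small_ncc_pipeline):
        template = small_ncc_pipeline["template"]
        fit = fit_fjmncc(small_ncc_pipeline["full"], template, nodes=9)
        assert fit.method == "fJM-NCC"
        assert fit.converged
        # covariance PSD and CI arithmetic
        eig = np.linalg.eigvalsh(0.5 * (fit.cov + fit.cov.T))
        assert eig.min() > -1e-8
        np.testing.assert_allclose(fit.ci_low, fit.estimates - 1.959963984540054 * fit.se)
        df = fit.to_frame()
        assert list(df.columns) == ["parameter", "estimate", "se", "ci_low", "ci_high", "z", "p"]

    def test_wjmncc_variants_share_point_estimates(self, small_ncc_pipeline):
        template = small_ncc_pipeline["template"]
        sandwich, fisher = fit_wjmncc_both(
            small_ncc_pipeline["sub"], small_ncc_pipeline["weights"], template, nodes=9
        )
        np.testing.assert_allclose(sandwich.estimates, fisher.estimates)
        assert sandwich.method == "wJM-NCC"
        assert fisher.method == "wJM-NCC-Fisher"
        # sandwich covariance PSD
        eig = np.linalg.eigvalsh(0.5 * (sandwich.cov + sandwich.cov.T))
        assert eig.min() > -1e-8

    def test_unit_weights_match_unweighted_fit(self, small_ncc_pipeline):
        """wJM-NCC with all weights 1 equals the full-likelihood fit on
        the same (sub-)cohort up to optimizer tolerance."""
        template = small_ncc_pipeline["template"]
        sub = small_ncc_pipeline["sub"]
        ones = {s.id: 1.0 for s in sub.survival}
        w_fit = fit_wjmncc(sub, ones, template, nodes=9)
        f_fit = fit_fjmncc(sub, template, nodes=9)
        np.testing.assert_allclose(w_fit.estimates, f_fit.estimates, atol=2e-3)

    def test_subject_order_invariance(self, small_ncc_pipeline):
        template = small_ncc_pipeline["template"]
        full = small_ncc_pipeline["full"]
        fit1 = fit_fjmncc(full, template, nodes=9)
        rng = np.random.default_rng(0)
        order = rng.permutation(len(full.survival))
        shuffled = CohortData(
            [full.survival[i] for i in order],
            full.longitudinal,
            full.subcohort_flags,
            full.selections,
        )
        fit2 = fit_fjmncc(shuffled, template, nodes=9)
        np.testing.assert_allclose(fit1.estimates, fit2.estimates, atol=2e-4)

    def test_missing_weight_raises(self, small_ncc_pipeline):
        template = small_ncc_pipeline["template"]
        with pytest.raises(KeyError):
            fit_wjmncc(small_ncc_pipeline["sub"], {}, template)

    def test_make_template_quantile_knots(self, small_ncc_pipeline):
        cohort = small_ncc_pipeline["full"]
        t = make_template(cohort, Q=4, surv_covariates=("x2",))
        assert t.Q == 4
        knots = np.array(t.knots)
        assert np.isinf(knots[-1])
        assert np.all(np.diff(knots[:-1]) > 0)
        t1 = make_template(cohort, Q=1, surv_covariates=("x2",))
        assert t1.knots == (np.inf,)


class TestStudy2Configuration:
    def test_random_slope_piecewise_fit(self):
        """The intercept+slope model with piecewise baselines fits a
        matching simulated dataset and recovers the trajectory scale."""
        from jmncc.experiments import Scenario
        from jmncc.scenarios import study2_scenario
        from jmncc.simulator import attach_longitudinal, sample_longitudinal, simulate_full_cohort

        sc = study2_scenario(m=1)
        sim = sc.sim
        from dataclasses import replace

        sim = replace(sim, N=400, n_cases_target=18)
        cohort, truth = simulate_full_cohort(sim, seed=31)
        series = sample_longitudinal(cohort, truth, sim, seed=32)
        full = attach_longitudinal(cohort, series)
        template = sc.template()
        fit = fit_fjmncc(full, template, nodes=9)
        assert fit.converged
        assert fit["sigma2"] == pytest.approx(1.0, abs=0.2)
        assert fit["theta_var_intercept"] == pytest.approx(1.0, abs=0.5)
        assert abs(fit["beta_1"]) < 1.0  # truth is 0
        assert all(fit[f"xi_1_{q}"] > 0 for q in (1, 2, 3))
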