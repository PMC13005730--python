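import math

import numpy as np
import pytest
from scipy import integrate, stats

from jmncc.datamodel import LongitudinalSeries
from jmncc.likelihood import (
    LikelihoodData,
    _eval,
    baseline_hazard,
    cumulative_cause_hazard,
    full_loglik,
    longitudinal_logdensity,
    pointwise_loglik,
    subject_marginal_loglik,
    survival_logdensity,
    trajectory_value,
    weighted_loglik,
)
from jmncc.model import LongSubmodelSpec, ModelTemplate, ParamVector, SurvSubmodelSpec


def long_spec(**kw):
    defaults = dict(gamma=np.array([1.0, 0.5]), tau=1.0, Sigma_theta=np.array([[1.0]]))
    defaults.update(kw)
    return LongSubmodelSpec(**defaults)


def surv_spec(**kw):
    defaults = dict(
        K=1,
        knots=np.array([np.inf]),
        xi=np.array([[0.2]]),
        beta=np.array([0.0]),
        alpha=np.zeros((1, 0)),
        covariate_names=(),
    )
    defaults.update(kw)
    return SurvSubmodelSpec(**defaults)


class TestTrajectoryAndDensity:
    def test_identity_link_value(self):
        assert trajectory_value(long_spec(), {}, [0.0], 2.0) == pytest.approx(2.0)

    def test_log_link_at_zero_predictor(self):
        spec = long_spec(family="poisson", link="log", gamma=np.array([0.0, 0.0]))
        assert trajectory_value(spec, {}, [0.0], 3.0) == pytest.approx(1.0)

    def test_random_intercept_shifts_value(self):
        base = trajectory_value(long_spec(), {}, [0.0], 1.5)
        assert trajectory_value(long_spec(), {}, [0.3], 1.5) == pytest.approx(base + 0.3)

    def test_normal_single_observation(self):
        spec = long_spec(gamma=np.array([0.0, 0.0]))
        series = LongitudinalSeries("s", (1.0,), (0.0,))
        assert longitudinal_logdensity(spec, series, {}, [0.0]) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_poisson_zero_count(self):
        spec = long_spec(family="poisson", link="log", gamma=np.array([0.0, 0.0]))
        series = LongitudinalSeries("s", (1.0,), (0.0,))
        assert longitudinal_logdensity(spec, series, {}, [0.0]) == pytest.approx(-1.0)

    def test_additivity_over_observations(self):
        spec = long_spec()
        s1 = LongitudinalSeries("s", (0.5,), (1.0,))
        s2 = LongitudinalSeries("s", (1.5,), (2.0,))
        s12 = LongitudinalSeries("s", (0.5, 1.5), (1.0, 2.0))
        total = longitudinal_logdensity(spec, s12, {}, [0.2])
        parts = longitudinal_logdensity(spec, s1, {}, [0.2]) + longitudinal_logdensity(
            spec, s2, {}, [0.2]
        )
        assert total == pytest.approx(parts)


class TestBaselineHazard:
    def test_constant(self):
        sp = surv_spec(xi=np.array([[0.1]]))
        assert baseline_hazard(sp, 1, 0.5) == pytest.approx(0.1)

    def test_left_open_right_closed_boundary(self):
        sp = surv_spec(knots=np.array([1.0, np.inf]), xi=np.array([[0.1, 0.4]]))
        assert baseline_hazard(sp, 1, 1.0) == pytest.approx(0.1)
        assert baseline_hazard(sp, 1, 1.0 + 1e-9) == pytest.approx(0.4)

    def test_extension_beyond_last_knot(self):
        sp = surv_spec(knots=np.array([1.0, 2.0]), xi=np.array([[0.1, 0.4]]))
        assert baseline_hazard(sp, 1, 7.0) == pytest.approx(0.4)


class TestCumulativeHazard:
    def test_null_association_is_rate_times_time(self):
        assert cumulative_cause_hazard(surv_spec(), long_spec(), {}, [0.0], 1, 3.0) == (
            pytest.approx(0.6)
        )

    def test_piecewise_rectangles(self):
        sp = surv_spec(knots=np.array([1.0, np.inf]), xi=np.array([[0.1, 0.3]]))
        assert cumulative_cause_hazard(sp, long_spec(gamma=np.zeros(2)), {}, [0.0], 1, 2.0) == (
            pytest.approx(0.4)
        )

    def test_closed_form_vs_riemann_sum(self):
        """Identity-link closed form against brute-force integration."""
        sp = surv_spec(beta=np.array([1.0]), xi=np.array([[0.2]]))
        ls = long_spec(gamma=np.array([0.4, 0.3]))
        b = [0.25]
        T = 2.5
        val = cumulative_cause_hazard(sp, ls, {}, b, 1, T)
        s = np.linspace(0, T, 10_001)
        integrand = 0.2 * np.exp(1.0 * (0.4 + 0.25 + 0.3 * s))
        riemann = np.trapezoid(integrand, s)
        assert val == pytest.approx(riemann, rel=1e-6)

    def test_log_link_quadrature_vs_riemann(self):
        sp = surv_spec(beta=np.array([0.4]), xi=np.array([[0.1]]))
        ls = long_spec(family="poisson", link="log", gamma=np.array([0.1, 0.2]))
        b = [0.2]
        T = 1.5
        val = cumulative_cause_hazard(sp, ls, {}, b, 1, T)
        s = np.linspace(0, T, 20_001)
        integrand = 0.1 * np.exp(0.4 * np.exp(0.1 + 0.2 + 0.2 * s))
        assert val == pytest.approx(np.trapezoid(integrand, s), rel=1e-6)


class TestSurvivalDensity:
    def test_exponential_event(self):
        val = survival_logdensity(surv_spec(), long_spec(), {}, [0.0], 2.0, 1)
        assert val == pytest.approx(math.log(0.2) - 0.2 * 2.0)

    def test_two_cause_censored(self):
        sp = surv_spec(K=2, xi=np.array([[0.2], [0.3]]), beta=np.zeros(2), alpha=np.zeros((2, 0)))
        val = survival_logdensity(sp, long_spec(), {}, [0.0], 2.0, 0)
        assert val == pytest.approx(-(0.2 + 0.3) * 2.0)

    def test_two_cause_event(self):
        sp = surv_spec(K=2, xi=np.array([[0.2], [0.3]]), beta=np.zeros(2), alpha=np.zeros((2, 0)))
        val = survival_logdensity(sp, long_spec(), {}, [0.0], 2.0, 1)
        assert val == pytest.approx(math.log(0.2) - 0.5 * 2.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            survival_logdensity(surv_spec(), long_spec(), {}, [0.0], -1.0, 0)
        with pytest.raises(ValueError):
            survival_logdensity(surv_spec(), long_spec(), {}, [0.0], 1.0, 5)


class TestMarginalLoglik:
    def test_degenerate_mixing_limit(self):
        """Sigma_theta -> 0 makes the marginal equal the b=0 plug-in."""
        ls = long_spec(Sigma_theta=np.array([[1e-12]]))
        sp = surv_spec()
        series = LongitudinalSeries("s", (0.5, 1.0), (1.1, 1.6))
        got = subject_marginal_loglik(ls, sp, {}, 2.0, 1, series=series, nodes=15)
        plug = survival_logdensity(sp, ls, {}, [0.0], 2.0, 1) + longitudinal_logdensity(
            ls, series, {}, [0.0]
        )
        assert got == pytest.approx(plug, abs=1e-5)

    def test_compound_symmetry_closed_form(self):
        """Random-intercept Gaussian marginal equals the MVN with
        covariance sigma^2 I + theta^2 11'."""
        theta2, sigma2 = 0.8, 0.5
        ls = long_spec(gamma=np.array([0.3, 0.2]), tau=sigma2, Sigma_theta=np.array([[theta2]]))
        sp = surv_spec(beta=np.array([0.0]))  # survival independent of b
        times = (0.0, 0.5, 1.0, 1.5)
        values = (0.5, 0.1, 1.2, 0.9)
        series = LongitudinalSeries("s", times, values)
        T, delta = 2.0, 0
        got = subject_marginal_loglik(ls, sp, {}, T, delta, series=series, nodes=15)
        surv_part = survival_logdensity(sp, ls, {}, [0.0], T, delta)
        mean = 0.3 + 0.2 * np.asarray(times)
        cov = sigma2 * np.eye(4) + theta2 * np.ones((4, 4))
        oracle = stats.multivariate_normal(mean, cov).logpdf(np.asarray(values))
        assert got - surv_part == pytest.approx(oracle, abs=1e-6)

    def test_quadrature_self_convergence(self):
        ls = long_spec()
        sp = surv_spec(beta=np.array([0.3]))
        series = LongitudinalSeries("s", (0.0, 0.5, 1.0), (0.2, 0.9, 1.4))
        v15 = subject_marginal_loglik(ls, sp, {}, 1.5, 1, series=series, nodes=15)
        v30 = subject_marginal_loglik(ls, sp, {}, 1.5, 1, series=series, nodes=30)
        assert abs(v15 - v30) < 1e-6

    def test_flag_false_drops_longitudinal(self):
        ls = long_spec()
        sp = surv_spec(beta=np.array([0.3]))
        series = LongitudinalSeries("s", (0.0, 0.5), (0.2, 0.9))
        with_flag = subject_marginal_loglik(
            ls, sp, {}, 1.0, 1, series=series, include_longitudinal=False
        )
        without_series = subject_marginal_loglik(ls, sp, {}, 1.0, 1, series=None)
        assert with_flag == pytest.approx(without_series)

    def test_adaptive_matches_nonadaptive(self):
        ls = long_spec()
        sp = surv_spec(beta=np.array([0.4]))
        series = LongitudinalSeries("s", (0.0, 0.5, 1.0), (0.4, 1.1, 1.2))
        plain = subject_marginal_loglik(ls, sp, {}, 1.4, 1, series=series, nodes=25)
        adap = subject_marginal_loglik(ls, sp, {}, 1.4, 1, series=series, nodes=15, adaptive=True)
        assert adap == pytest.approx(plain, abs=1e-5)

    def test_quad_oracle_single_cause(self):
        """K=1 marginal against independent 1-D numerical integration."""
        ls = long_spec()
        sp = surv_spec(beta=np.array([0.5]), xi=np.array([[0.15]]))
        rng = np.random.default_rng(5)
        for _ in range(5):
            T = float(rng.uniform(0.5, 3.0))
            delta = int(rng.integers(0, 2))
            times = tuple(np.sort(rng.uniform(0, T, 3)))
            values = tuple(rng.normal(0.5, 1.0, 3))
            series = LongitudinalSeries("s", times, values)

            def integrand(b):
                return math.exp(
                    survival_logdensity(sp, ls, {}, [b], T, delta)
                    + longitudinal_logdensity(ls, series, {}, [b])
                ) * stats.norm.pdf(b)

            oracle, _ = integrate.quad(integrand, -8, 8, limit=200)
            got = subject_marginal_loglik(ls, sp, {}, T, delta, series=series, nodes=30)
            assert got == pytest.approx(math.log(oracle), abs=1e-6)


class TestCohortLoglik:
    def _phi(self, template, sim):
        return ParamVector.from_specs(template, sim.long_spec(), sim.surv_spec())

    def test_full_loglik_single_censored_subject(self):
        from jmncc.datamodel import CohortData, SubjectSurvival

        cohort = CohortData(
            [SubjectSurvival("a", 2.0, 0, {})], {}, {"a": 0}, []
        )
        t = ModelTemplate(K=1, knots=(np.inf,), surv_covariates=())
        layout = t.layout()
        v = np.zeros(layout.size)
        v[layout.sl_xi] = math.log(0.2)
        phi = ParamVector(layout, v)
        # the small-|x| clamp in the segment integrals costs O(1e-8) relative
        assert full_loglik(phi, cohort) == pytest.approx(-0.2 * 2.0, abs=1e-7)

    def test_vectorized_matches_scalar(self, small_ncc_pipeline):
        full = small_ncc_pipeline["full"]
        sim = small_ncc_pipeline["sim"]
        template = small_ncc_pipeline["template"]
        phi = ParamVector.from_specs(template, sim.long_spec(), sim.surv_spec())
        data = LikelihoodData.from_cohort(full, template)
        ll, _ = pointwise_loglik(phi.layout, phi.values, data, 15)
        ls, sp = sim.long_spec(), sim.surv_spec()
        for i, s in enumerate(full.survival[:40]):
            expected = subject_marginal_loglik(
                ls, sp, s.covariates, s.time, s.status,
                series=full.longitudinal.get(s.id), nodes=15,
            )
            assert ll[i] == pytest.approx(expected, abs=1e-9)

    def test_fast_path_matches_numpy_path(self, small_ncc_pipeline):
        """JIT kernel and vectorized numpy evaluation agree exactly."""
        full = small_ncc_pipeline["full"]
        for re_, Q in [("intercept", 1), ("intercept", 3), ("intercept_slope", 2)]:
            knots = (np.inf,) if Q == 1 else tuple(np.linspace(1.0, 2.5, Q - 1)) + (np.inf,)
            t = ModelTemplate(K=2, knots=knots, random_effects=re_, surv_covariates=("x2",))
            layout = t.layout()
            rng = np.random.default_rng(Q)
            v = rng.normal(0, 0.3, layout.size)
            v[layout.sl_xi] = np.log(0.05)
            data = LikelihoodData.from_cohort(full, t)
            ll_f, sc_f = pointwise_loglik(layout, v, data, 9, compute_scores=True)
            ll_n, sc_n = _eval(layout, v, data, 9, True)
            np.testing.assert_allclose(ll_f, ll_n, atol=1e-10)
            np.testing.assert_allclose(sc_f, sc_n, atol=1e-9)

    @pytest.mark.parametrize("random_effects", ["intercept", "intercept_slope"])
    @pytest.mark.parametrize("at_null", [True, False])
    def test_analytic_scores_match_numeric_gradient(
        self, small_ncc_pipeline, random_effects, at_null
    ):
        """Analytic scores equal numeric gradients, including at beta = 0
        (where the segment-integral derivative switches to its series)."""
        full = small_ncc_pipeline["full"]
        template = ModelTemplate(
            K=2, knots=(1.2, np.inf), random_effects=random_effects,
            surv_covariates=("x2",),
        )
        layout = template.layout()
        rng = np.random.default_rng(0)
        v = rng.normal(0, 0.2, layout.size)
        v[layout.sl_xi] = np.log(0.03)
        if at_null:
            v[layout.sl_beta] = 0.0
        data = LikelihoodData.from_cohort(full, template)
        _, scores = pointwise_loglik(layout, v, data, 9, compute_scores=True)
        g = scores.sum(axis=0)
        for j in range(layout.size):
            h = 1e-6 * max(1, abs(v[j]))
            up, dn = v.copy(), v.copy()
            up[j] += h
            dn[j] -= h
            lu, _ = pointwise_loglik(layout, up, data, 9)
            ld, _ = pointwise_loglik(layout, dn, data, 9)
            num = (lu.sum() - ld.sum()) / (2 * h)
            assert g[j] == pytest.approx(num, rel=5e-4, abs=5e-4)

    def test_order_invariance(self, small_ncc_pipeline):
        from jmncc.datamodel import CohortData

        full = small_ncc_pipeline["full"]
        sim = small_ncc_pipeline["sim"]
        template = small_ncc_pipeline["template"]
        phi = ParamVector.from_specs(template, sim.long_spec(), sim.surv_spec())
        base = full_loglik(phi, full)
        rng = np.random.default_rng(1)
        order = rng.permutation(len(full.survival))
        shuffled = CohortData(
            [full.survival[i] for i in order],
            full.longitudinal,
            full.subcohort_flags,
            full.selections,
        )
        assert full_loglik(phi, shuffled) == pytest.approx(base, abs=1e-8)

    def test_weighted_loglik_identities(self, small_ncc_pipeline):
        sub = small_ncc_pipeline["sub"]
        sim = small_ncc_pipeline["sim"]
        template = small_ncc_pipeline["template"]
        phi = ParamVector.from_specs(template, sim.long_spec(), sim.surv_spec())
        ones = {s.id: 1.0 for s in sub.survival}
        assert weighted_loglik(phi, sub, ones) == pytest.approx(full_loglik(phi, sub), abs=1e-8)
        w2 = {sid: 2.0 * w for sid, w in ones.items()}
        assert weighted_loglik(phi, sub, w2) == pytest.approx(
            2.0 * weighted_loglik(phi, sub, ones), abs=1e-8
        )
        with pytest.raises(KeyError):
            weighted_loglik(phi, sub, {})

    def test_poisson_family_cohort(self):
        """Log-link Poisson path agrees with the scalar reference."""
        from jmncc.datamodel import CohortData, LongitudinalSeries, SubjectSurvival
        from jmncc.simulator import SimConfig, sample_longitudinal, simulate_full_cohort

        sim = SimConfig(
            N=30, n_cases_target=5, censor_hi=5.0, family="poisson", link="log",
            gamma=(0.5, 0.1), xi=((0.05,), (0.04,)),
        )
        cohort, truth = simulate_full_cohort(sim, seed=8)
        series = sample_longitudinal(cohort, truth, sim, seed=9)
        full = CohortData(
            cohort.survival, series, {s.id: 1 for s in cohort.survival}, []
        )
        t = ModelTemplate(
            family="poisson", link="log", K=2, knots=(np.inf,), surv_covariates=("x2",)
        )
        phi = ParamVector.from_specs(t, sim.long_spec(), sim.surv_spec())
        data = LikelihoodData.from_cohort(full, t)
        ll, _ = pointwise_loglik(phi.layout, phi.values, data, 15)
        ls, sp = sim.long_spec(), sim.surv_spec()
        for i, s in enumerate(full.survival[:10]):
            expected = subject_marginal_loglik(
                ls, sp, s.covariates, s.time, s.status,
                series=full.longitudinal[s.id], nodes=15,
            )
            assert ll[i] == pytest.approx(expected, abs=1e-6)
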