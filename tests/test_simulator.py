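import numpy as np
import pytest
from scipy import integrate, stats

from jmncc.simulator import (
    SimConfig,
    attach_longitudinal,
    sample_longitudinal,
    simulate_full_cohort,
    simulate_multifeature,
)


class TestEventGeneration:
    def test_competing_exponentials_distribution(self):
        """With beta=0 and equal constant hazards, T* ~ Exp(xi1+xi2) and
        the cause label is a fair coin (KS and binomial checks)."""
        cfg = SimConfig(
            N=5000, n_cases_target=None, xi=((0.25,), (0.25,)),
            alpha=((0.0,), (0.0,)), censor_lo=1e6 - 1, censor_hi=1e6,
        )
        cohort, truth = simulate_full_cohort(cfg, seed=5)
        T = np.array([s.time for s in cohort.survival])
        delta = np.array([s.status for s in cohort.survival])
        assert np.all(delta > 0)
        ks = stats.kstest(T, "expon", args=(0, 1.0 / 0.5))
        assert ks.pvalue > 0.01
        binom = stats.binomtest(int((delta == 1).sum()), delta.size, 0.5)
        assert binom.pvalue > 0.01

    def test_inverse_transform_with_association(self):
        """Cause-1 cumulative incidence under beta1 != 0 matches numerical
        integration of the true sub-density at a fixed horizon."""
        cfg = SimConfig(
            N=10_000, n_cases_target=None, xi=((0.3,), (0.2,)),
            alpha=((0.0,), (0.0,)), beta=(0.4, -0.2), gamma=(0.0, 0.5),
            censor_lo=1e6 - 1, censor_hi=1e6,
        )
        cohort, truth = simulate_full_cohort(cfg, seed=7)
        t0 = 1.5
        delta = np.array([s.status for s in cohort.survival])
        T = np.array([s.time for s in cohort.survival])
        p_hat = np.mean((delta == 1) & (T <= t0))

        def lam(k, s, b):
            xi = (0.3, 0.2)[k]
            beta = (0.4, -0.2)[k]
            return xi * np.exp(beta * (b + 0.5 * s))

        def cif_given_b(b):
            def surv(s):
                h1, _ = integrate.quad(lambda x: lam(0, x, b), 0, s)
                h2, _ = integrate.quad(lambda x: lam(1, x, b), 0, s)
                return np.exp(-h1 - h2)

            val, _ = integrate.quad(lambda s: lam(0, s, b) * surv(s), 0, t0, limit=100)
            return val

        nodes, w = np.polynomial.hermite_e.hermegauss(40)
        p_true = float(sum(wi * cif_given_b(x) for x, wi in zip(nodes, w)) / np.sqrt(2 * np.pi))
        mc_se = np.sqrt(p_true * (1 - p_true) / cfg.N)
        assert abs(p_hat - p_true) < 4 * mc_se

    def test_administrative_censoring_boundary(self):
        cfg = SimConfig(N=2000, n_cases_target=100, censor_hi=5.0)
        cohort, truth = simulate_full_cohort(cfg, seed=11)
        T = np.array([s.time for s in cohort.survival])
        delta = np.array([s.status for s in cohort.survival])
        assert (delta > 0).sum() == 100
        # the admin cut sits at the 100th case's event time, and no
        # observation extends beyond it
        assert truth.admin_time == pytest.approx(np.sort(T[delta > 0])[-1])
        assert T.max() == pytest.approx(truth.admin_time)

    def test_case_target_unreachable_raises(self):
        cfg = SimConfig(N=50, n_cases_target=45, censor_hi=4.0)
        with pytest.raises(RuntimeError, match="cases observed"):
            simulate_full_cohort(cfg, seed=0, strict=True)
        with pytest.warns(UserWarning):
            simulate_full_cohort(cfg, seed=0, strict=False)

    def test_default_calibration_case_yield(self):
        """Defaults target ~400 observed cases (+-10%) before the
        administrative cut at N=8000."""
        counts = [
            simulate_full_cohort(SimConfig(), seed=s, strict=False)[1].n_natural_cases
            for s in (0, 1, 2)
        ]
        assert 360 <= np.mean(counts) <= 440

    def test_censoring_monotonicity(self):
        """A wider step-1 censoring window weakly increases observed cases."""
        short = [
            simulate_full_cohort(
                SimConfig(N=2000, n_cases_target=None, censor_hi=2.0), seed=s
            )[1].n_natural_cases
            for s in range(3)
        ]
        long_ = [
            simulate_full_cohort(
                SimConfig(N=2000, n_cases_target=None, censor_hi=6.0), seed=s
            )[1].n_natural_cases
            for s in range(3)
        ]
        assert np.mean(long_) > np.mean(short)

    def test_truth_consistency(self):
        cfg = SimConfig(N=500, n_cases_target=30, censor_hi=5.0)
        cohort, truth = simulate_full_cohort(cfg, seed=3)
        assert truth.consistent_with(cohort)


class TestLongitudinalSampling:
    def test_grid_truncation(self):
        cfg = SimConfig(N=200, n_cases_target=15, censor_hi=5.0, grid=0.25, xi=((0.06,), (0.04,)))
        cohort, truth = simulate_full_cohort(cfg, seed=13)
        series = sample_longitudinal(cohort, truth, cfg, seed=14)
        for s in cohort.survival[:50]:
            times = np.array(series[s.id].times)
            assert times[0] == 0.0
            assert times.max() <= s.time + 1e-9
            np.testing.assert_allclose(np.diff(times), 0.25)

    def test_zero_noise_reproduces_trajectory(self):
        cfg = SimConfig(N=100, n_cases_target=8, censor_hi=5.0, sigma2=1e-18, xi=((0.06,), (0.04,)))
        cohort, truth = simulate_full_cohort(cfg, seed=15)
        series = sample_longitudinal(cohort, truth, cfg, seed=16)
        idx = {sid: i for i, sid in enumerate(truth.ids)}
        for s in cohort.survival[:20]:
            ser = series[s.id]
            i = idx[s.id]
            expected = truth.b[i, 0] + 0.5 * np.array(ser.times)
            np.testing.assert_allclose(ser.values, expected, atol=1e-6)

    def test_poisson_counts(self):
        cfg = SimConfig(
            N=100, n_cases_target=10, censor_hi=5.0, family="poisson", link="log",
            gamma=(0.5, 0.1), xi=((0.05,), (0.04,)),
        )
        cohort, truth = simulate_full_cohort(cfg, seed=17)
        series = sample_longitudinal(cohort, truth, cfg, seed=18)
        vals = np.concatenate([ser.values for ser in series.values()])
        assert np.all(vals >= 0)
        assert np.all(vals == np.round(vals))

    def test_subset_reveal_is_consistent(self):
        """Revealing a subset of subjects yields the same measurements as
        revealing everyone (per-subject noise streams)."""
        cfg = SimConfig(N=150, n_cases_target=12, censor_hi=5.0, xi=((0.06,), (0.04,)))
        cohort, truth = simulate_full_cohort(cfg, seed=19)
        all_series = sample_longitudinal(cohort, truth, cfg, seed=20)
        some = [s.id for s in cohort.survival[:10]]
        sub_series = sample_longitudinal(cohort, truth, cfg, ids=some, seed=20)
        for sid in some:
            np.testing.assert_array_equal(all_series[sid].values, sub_series[sid].values)

    def test_attach_longitudinal_sets_flags(self):
        cfg = SimConfig(N=60, n_cases_target=6, censor_hi=5.0, xi=((0.08,), (0.05,)))
        cohort, truth = simulate_full_cohort(cfg, seed=21)
        series = sample_longitudinal(cohort, truth, cfg, seed=22)
        full = attach_longitudinal(cohort, series)
        assert full.n_subcohort == cfg.N


class TestMultiFeature:
    def test_signal_count_and_determinism(self):
        cfg = SimConfig(N=150, n_cases_target=15, censor_hi=6.0, grid=1.0,
                        xi=((0.03,), (0.02,)))
        c1, t1, f1, m1 = simulate_multifeature(cfg, 20, 0.1, (0.5, -0.5), seed=23)
        c2, t2, f2, m2 = simulate_multifeature(cfg, 20, 0.1, (0.5, -0.5), seed=23)
        assert m1.sum() == 2
        np.testing.assert_array_equal(m1, m2)
        assert c1.equals(c2)
        sid = c1.survival[0].id
        np.testing.assert_array_equal(f1[3][sid].values, f2[3][sid].values)

    def test_null_signal_fraction_bounds(self):
        cfg = SimConfig(N=100, n_cases_target=10, censor_hi=6.0)
        with pytest.raises(ValueError):
            simulate_multifeature(cfg, 10, 0.0, (0.0, 0.0), seed=1)
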