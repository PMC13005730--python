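"""Cohort simulator for the joint model under NCC sampling.

Generates subject-specific biomarker trajectories from the longitudinal
GLMM, latent competing event times by inverting each cause-specific
cumulative hazard against an independent unit exponential, and applies
the two-step censoring scheme used throughout the simulation designs:

1. random right-censoring drawn from a uniform distribution, then
2. administrative censoring at the event time of the ``n_cases_target``-th
   observed case (so the case series is cut to exactly that many).

The default configuration mirrors the study design the package
reproduces at desk scale: a large cohort with ~5% of subjects observed
as cases of two competing events before the administrative cut, a linear
trajectory with subject-specific random intercept, a Bernoulli(0.5)
binary survival covariate, and constant cause-specific baseline hazards.
Baseline hazard values and the censoring window are calibrated jointly
to that case yield (see docs/methods.md).

One master seed spawns child streams per ingredient (covariates, random
effects, per-cause exponentials, censoring, measurement noise, features),
so partial re-runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .datamodel import CohortData, LongitudinalSeries, SubjectSurvival
from .likelihood import cumulative_cause_hazard, _segment_edges
from .model import LongSubmodelSpec, SurvSubmodelSpec

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_full_cohort",
    "sample_longitudinal",
    "attach_longitudinal",
    "simulate_multifeature",
]


@dataclass(frozen=True)
class SimConfig:
    """True data-generating parameters and design knobs.

    Defaults generate the constant-baseline, random-intercept design:
    cohort of ``N`` subjects with two competing events and about 5% of
    the cohort observed as cases before administrative censoring when
    ``N=8000`` and ``n_cases_target=400``.
    """

    N: int = 8000
    n_cases_target: int | None = 400  # None disables administrative censoring
    K: int = 2
    family: str = "normal"
    link: str = "identity"
    gamma: tuple[float, ...] = (0.0, 0.5)  # (intercept, slope)
    sigma2: float = 1.0
    random_effects: str = "intercept"
    theta_var: float = 1.0  # random-intercept variance
    theta_slope_var: float = 0.04  # used when random_effects='intercept_slope'
    theta_cov: float = 0.0
    knots: tuple[float, ...] = (np.inf,)  # constant baselines by default
    xi: tuple[tuple[float, ...], ...] = ((0.0161,), (0.0080,))
    beta: tuple[float, float] = (0.0, 0.0)
    alpha: tuple[tuple[float, ...], ...] = ((0.3,), (0.2,))
    censor_lo: float = 0.0
    censor_hi: float = 4.0
    grid: float = 0.25  # longitudinal measurement spacing
    m: int = 1  # controls per case (used by pipeline helpers)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases_target is not None and not (0 < self.n_cases_target < self.N):
            raise ValueError("require 0 < n_cases_target < N")
        if self.grid <= 0:
            raise ValueError("grid spacing must be positive")
        if self.censor_hi <= self.censor_lo or self.censor_hi <= 0:
            raise ValueError("invalid censoring bounds")

    @property
    def r(self) -> int:
        return 1 if self.random_effects == "intercept" else 2

    def Sigma_theta(self) -> np.ndarray:
        if self.r == 1:
            return np.array([[self.theta_var]])
        return np.array(
            [[self.theta_var, self.theta_cov], [self.theta_cov, self.theta_slope_var]]
        )

    def long_spec(self) -> LongSubmodelSpec:
        return LongSubmodelSpec(
            family=self.family,
            link=self.link,
            covariate_names=(),
            random_effects=self.random_effects,
            gamma=np.array(self.gamma),
            tau=self.sigma2 if self.family == "normal" else 1.0,
            Sigma_theta=self.Sigma_theta(),
        )

    def surv_spec(self) -> SurvSubmodelSpec:
        return SurvSubmodelSpec(
            K=self.K,
            knots=np.array(self.knots),
            xi=np.array(self.xi),
            beta=np.array(self.beta),
            alpha=np.array(self.alpha),
            covariate_names=("x2",),
        )


@dataclass
class TruthRecord:
    """Latent quantities realized by the simulator (testing only)."""

    ids: list[str]
    b: np.ndarray  # (N, r)
    T_star: np.ndarray  # (N, K) latent event times (inf = never)
    C: np.ndarray  # (N,) step-1 censoring times
    admin_time: float
    n_natural_cases: int  # observed cases before the administrative cut

    def consistent_with(self, cohort: CohortData) -> bool:
        for i, s in enumerate(cohort.survival):
            t_min = min(float(np.min(self.T_star[i])), float(self.C[i]), self.admin_time)
            if not np.isclose(s.time, t_min):
                return False
            if s.status == 0:
                if float(np.min(self.T_star[i])) < s.time - 1e-12:
                    return False
            else:
                if not np.isclose(self.T_star[i, s.status - 1], s.time):
                    return False
        return True


def _expint_vec(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """``int_lo^hi e^{x s} ds`` elementwise in x; hi may be +inf."""
    out = np.empty_like(x)
    small = np.abs(x) < 1e-12
    if np.isinf(hi):
        pos = x >= 0
        out[pos | small] = np.inf
        neg = ~(pos | small)
        out[neg] = -np.exp(x[neg] * lo) / x[neg]
        return out
    with np.errstate(over="ignore"):
        out = np.where(small, hi - lo, (np.exp(x * hi) - np.exp(x * lo)) / np.where(small, 1.0, x))
    return out


def _invert_piecewise(E: np.ndarray, pref: np.ndarray, x: np.ndarray, edges: np.ndarray):
    """Solve ``Lambda(t) = E`` for piecewise integrands ``pref_q e^{x s}``.

    ``pref`` has shape (N, Q) (baseline level times the subject's fixed
    hazard multiplier), ``x`` (N,) the exponential tilt from the
    trajectory slope. Returns event times (inf where the total hazard
    never reaches E).
    """
    N, Q = pref.shape
    T = np.full(N, np.inf)
    remaining = E.copy()
    unresolved = np.ones(N, dtype=bool)
    for q in range(Q):
        lo, hi = edges[q], edges[q + 1]
        inc = pref[:, q] * _expint_vec(x, lo, hi)
        hit = unresolved & (remaining <= inc)
        if np.any(hit):
            xq = x[hit]
            pq = pref[hit, q]
            rq = remaining[hit]
            small = np.abs(xq) < 1e-12
            sol = np.empty(xq.size)
            sol[small] = lo + rq[small] / pq[small]
            ns = ~small
            with np.errstate(over="ignore"):
                arg = np.exp(xq[ns] * lo) + xq[ns] * rq[ns] / pq[ns]
            sol[ns] = np.log(arg) / xq[ns]
            T[hit] = sol
            unresolved[hit] = False
        still = unresolved & np.isfinite(inc)
        remaining[still] -= inc[still]
        # if inc is inf and not hit, remaining <= inc must have held; nothing to do
    return T


def _draw_event_times(
    config: SimConfig, b: np.ndarray, X2: np.ndarray, rng_exp: np.random.Generator
) -> np.ndarray:
    """Latent cause-specific event times by cumulative-hazard inversion."""
    N = config.N
    long_spec = config.long_spec()
    surv_spec = config.surv_spec()
    edges = _segment_edges(surv_spec.knots)
    T_star = np.empty((N, config.K))
    E = rng_exp.exponential(size=(N, config.K))
    if config.link == "identity":
        a = long_spec.gamma[0] + b[:, 0]
        c = np.full(N, long_spec.gamma[1]) + (b[:, 1] if config.r == 2 else 0.0)
        for k in range(config.K):
            beta_k = surv_spec.beta[k]
            mult = np.exp(surv_spec.alpha[k, 0] * X2 + beta_k * a)
            pref = surv_spec.xi[k][None, :] * mult[:, None]
            T_star[:, k] = _invert_piecewise(E[:, k], pref, beta_k * c, edges)
    else:
        for i in range(N):
            covs = {"x2": float(X2[i])}
            for k in range(config.K):
                T_star[i, k] = _invert_scalar(
                    surv_spec, long_spec, covs, b[i], k + 1, E[i, k]
                )
    return T_star


def _invert_scalar(surv_spec, long_spec, covs, b, k, target) -> float:
    """Root-find Lambda_k(t | b) = target with bracket expansion."""

    def f(t):
        return cumulative_cause_hazard(surv_spec, long_spec, covs, b, k, t) - target

    hi = 1.0
    for _ in range(60):
        if f(hi) > 0:
            return float(brentq(f, 1e-12, hi, xtol=1e-10))
        hi *= 2.0
        if hi > 1e8:
            return np.inf
    return np.inf


def simulate_full_cohort(
    config: SimConfig, seed: int | np.random.SeedSequence | None = None, strict: bool = True
) -> tuple[CohortData, TruthRecord]:
    """Simulate survival outcomes for the full cohort.

    Longitudinal measurements are withheld until :func:`sample_longitudinal`
    so that the same latent trajectories can be revealed for whichever
    subjects the NCC sample (or an oracle analysis) requires.

    Raises when fewer than ``n_cases_target`` cases are observed under
    step-1 censoring (``strict=True``); with ``strict=False`` a warning is
    issued and the administrative cut falls at the last observed case.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cov, s_b, s_exp, s_cens = ss.spawn(4)
    N = config.N
    rng_cov = np.random.default_rng(s_cov)
    X2 = rng_cov.binomial(1, 0.5, size=N).astype(float)
    L = np.linalg.cholesky(config.Sigma_theta())
    b = np.random.default_rng(s_b).standard_normal((N, config.r)) @ L.T
    T_star = _draw_event_times(config, b, X2, np.random.default_rng(s_exp))
    C = np.random.default_rng(s_cens).uniform(config.censor_lo, config.censor_hi, size=N)
    C = np.maximum(C, 1e-6)

    T_min = T_star.min(axis=1)
    cause = T_star.argmin(axis=1) + 1
    T_pre = np.minimum(T_min, C)
    delta_pre = np.where(T_min <= C, cause, 0)

    ev_times = np.sort(T_pre[delta_pre > 0])
    n_nat = ev_times.size
    if config.n_cases_target is None:
        admin = np.inf
    elif n_nat < config.n_cases_target:
        msg = (
            f"only {n_nat} cases observed before administrative censoring "
            f"(target {config.n_cases_target})"
        )
        if strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
        admin = float(ev_times[-1]) if n_nat else config.censor_hi
    else:
        admin = float(ev_times[config.n_cases_target - 1])

    T_obs = np.minimum(T_pre, admin)
    delta = np.where(T_pre <= admin, delta_pre, 0)

    width = len(str(N - 1))
    ids = [f"s{i:0{width}d}" for i in range(N)]
    survival = [
        SubjectSurvival(
            id=ids[i], time=float(T_obs[i]), status=int(delta[i]), covariates={"x2": float(X2[i])}
        )
        for i in range(N)
    ]
    cohort = CohortData(
        survival=survival,
        longitudinal={},
        subcohort_flags={sid: 0 for sid in ids},
        selections=[],
    )
    truth = TruthRecord(
        ids=ids, b=b, T_star=T_star, C=C, admin_time=admin, n_natural_cases=int(n_nat)
    )
    return cohort, truth


def sample_longitudinal(
    cohort: CohortData,
    truth: TruthRecord,
    config: SimConfig,
    ids: list[str] | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> dict[str, LongitudinalSeries]:
    """Reveal biomarker measurements for the chosen subjects.

    Times sit on the configured grid ``0, g, 2g, ...`` truncated at each
    subject's observed time; values follow the family (Gaussian noise
    around the latent trajectory, or Poisson counts under the log link).
    Measurement noise streams are child seeds per subject, so revealing a
    subset of subjects yields the same values as revealing everyone.
    """
    if seed is None:
        raise ValueError("a seed is required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(truth.ids))
    idx_of = {sid: i for i, sid in enumerate(truth.ids)}
    if ids is None:
        ids = [s.id for s in cohort.survival]
    time_of = {s.id: s.time for s in cohort.survival}
    out: dict[str, LongitudinalSeries] = {}
    gamma = np.array(config.gamma)
    sd = np.sqrt(config.sigma2)
    for sid in ids:
        i = idx_of[sid]
        rng = np.random.default_rng(children[i])
        T_i = time_of[sid]
        times = np.arange(0.0, T_i + 1e-9, config.grid)
        if times.size == 0:
            times = np.array([0.0])
        b0 = truth.b[i, 0]
        b1 = truth.b[i, 1] if config.r == 2 else 0.0
        eta = gamma[0] + b0 + (gamma[1] + b1) * times
        if config.family == "normal":
            values = eta + rng.normal(0.0, sd, size=times.size)
        else:
            values = rng.poisson(np.exp(eta)).astype(float)
        out[sid] = LongitudinalSeries(id=sid, times=tuple(times), values=tuple(values))
    return out


def attach_longitudinal(
    cohort: CohortData,
    series_map: dict[str, LongitudinalSeries],
    subcohort_flags: dict[str, int] | None = None,
    selections=None,
) -> CohortData:
    """New CohortData with the given longitudinal series (and, optionally,
    NCC flags/selections) attached."""
    flags = dict(subcohort_flags) if subcohort_flags is not None else {
        s.id: 0 for s in cohort.survival
    }
    for sid in series_map:
        flags[sid] = 1
    return CohortData(
        survival=list(cohort.survival),
        longitudinal=dict(series_map),
        subcohort_flags=flags,
        selections=list(selections) if selections is not None else list(cohort.selections),
    )


def simulate_multifeature(
    config: SimConfig,
    n_features: int = 100,
    signal_fraction: float = 0.1,
    beta_signal: tuple[float, float] = (0.5, -0.5),
    seed: int | np.random.SeedSequence | None = None,
    strict: bool = True,
):
    """Many independent biomarker features, a fraction of them signals.

    Each feature evolves as an independent random-intercept trajectory on
    the log-abundance scale. Signal features enter both cause-specific
    hazards with coefficients ``beta_signal``; null features are
    independent of the event process. Returned feature series are already
    log-scale (analysis-ready). Returns
    ``(cohort, truth, feature_series, signal_mask)`` where
    ``feature_series[f]`` maps subject id -> series for feature ``f``.
    """
    if not 0 < signal_fraction < 1:
        raise ValueError("signal_fraction must be in (0, 1)")
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pick, s_cov, s_b, s_exp, s_cens, *s_feat = ss.spawn(5 + n_features)
    n_signal = int(round(signal_fraction * n_features))
    rng_pick = np.random.default_rng(s_pick)
    signal_idx = np.sort(rng_pick.choice(n_features, size=n_signal, replace=False))
    signal_mask = np.zeros(n_features, dtype=bool)
    signal_mask[signal_idx] = True

    N = config.N
    rng_cov = np.random.default_rng(s_cov)
    X2 = rng_cov.binomial(1, 0.5, size=N).astype(float)
    theta_sd = np.sqrt(config.theta_var)
    b_all = np.random.default_rng(s_b).standard_normal((n_features, N)) * theta_sd

    # hazard exponent is linear in t: sum of signal trajectories
    gamma = np.array(config.gamma)
    surv = config.surv_spec()
    edges = _segment_edges(surv.knots)
    a_sig = (gamma[0] + b_all[signal_mask]).sum(axis=0)  # (N,)
    c_sig = float(n_signal * gamma[1])
    E = np.random.default_rng(s_exp).exponential(size=(N, config.K))
    T_star = np.empty((N, config.K))
    for k in range(config.K):
        bk = beta_signal[k]
        mult = np.exp(surv.alpha[k, 0] * X2 + bk * a_sig)
        pref = surv.xi[k][None, :] * mult[:, None]
        T_star[:, k] = _invert_piecewise(E[:, k], pref, np.full(N, bk * c_sig), edges)
    C = np.random.default_rng(s_cens).uniform(config.censor_lo, config.censor_hi, size=N)
    C = np.maximum(C, 1e-6)
    T_min = T_star.min(axis=1)
    cause = T_star.argmin(axis=1) + 1
    T_pre = np.minimum(T_min, C)
    delta_pre = np.where(T_min <= C, cause, 0)
    ev_times = np.sort(T_pre[delta_pre > 0])
    n_nat = ev_times.size
    if n_nat < config.n_cases_target:
        msg = f"only {n_nat} cases observed (target {config.n_cases_target})"
        if strict:
            raise RuntimeError(msg)
        warnings.warn(msg)
        admin = float(ev_times[-1]) if n_nat else config.censor_hi
    else:
        admin = float(ev_times[config.n_cases_target - 1])
    T_obs = np.minimum(T_pre, admin)
    delta = np.where(T_pre <= admin, delta_pre, 0)

    width = len(str(N - 1))
    ids = [f"s{i:0{width}d}" for i in range(N)]
    survival = [
        SubjectSurvival(
            id=ids[i], time=float(T_obs[i]), status=int(delta[i]), covariates={"x2": float(X2[i])}
        )
        for i in range(N)
    ]
    cohort = CohortData(survival, {}, {sid: 0 for sid in ids}, [])
    truth = TruthRecord(
        ids=ids,
        b=b_all.T,  # (N, n_features): one random intercept per feature
        T_star=T_star,
        C=C,
        admin_time=admin,
        n_natural_cases=int(n_nat),
    )

    feature_series: list[dict[str, LongitudinalSeries]] = []
    sd = np.sqrt(config.sigma2)
    for f in range(n_features):
        rng_f = np.random.default_rng(s_feat[f])
        series: dict[str, LongitudinalSeries] = {}
        for i, sid in enumerate(ids):
            times = np.arange(0.0, T_obs[i] + 1e-9, config.grid)
            if times.size == 0:
                times = np.array([0.0])
            eta = gamma[0] + b_all[f, i] + gamma[1] * times
            values = eta + rng_f.normal(0.0, sd, size=times.size)
            series[sid] = LongitudinalSeries(id=sid, times=tuple(times), values=tuple(values))
        feature_series.append(series)
    return cohort, truth, feature_series, signal_mask
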