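"""Maximum-likelihood fitting, covariance estimation and Wald inference.

Two estimators share one quasi-Newton machinery:

* fJM-NCC maximizes the full likelihood (survival terms for every cohort
  subject; joint survival x longitudinal terms for the NCC sub-cohort) and
  reports covariance from the inverse empirical Fisher information (outer
  product of per-subject scores).
* wJM-NCC maximizes the inverse-probability-weighted likelihood over the
  sub-cohort alone and reports either the robust sandwich covariance
  ``I^{-1} Sigma I^{-1}`` (``I`` = negative Hessian of the weighted
  log-likelihood, ``Sigma`` = outer product of per-subject weighted
  scores) or, for comparison, the anti-conservative naive inverse
  information ("Fisher" variant).

All covariances are mapped to the natural parameter scale by the delta
method; confidence intervals are Wald intervals at the 0.95 level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import CohortData, WeightTable
from .likelihood import LikelihoodData, NumericError, pointwise_loglik
from .model import ModelTemplate, ParamLayout, ParamVector

__all__ = [
    "FitResult",
    "make_template",
    "fit_fjmncc",
    "fit_wjmncc",
    "wald_test",
    "adjust_pvalues",
]

_Z975 = 1.959963984540054


@dataclass
class FitResult:
    """Estimates, covariance and Wald inference for one fitted model."""

    method: str
    names: list[str]
    estimates: np.ndarray  # natural scale
    cov: np.ndarray  # natural scale
    loglik: float
    converged: bool
    n_iter: int
    phi: ParamVector
    message: str = ""
    n_subjects: int = 0

    se: np.ndarray = field(init=False)
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    z: np.ndarray = field(init=False)
    p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        var = np.clip(np.diag(self.cov), 0.0, None)
        self.se = np.sqrt(var)
        self.ci_low = self.estimates - _Z975 * self.se
        self.ci_high = self.estimates + _Z975 * self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            self.z = np.where(self.se > 0, self.estimates / self.se, np.nan)
        self.p = 2.0 * stats.norm.sf(np.abs(self.z))

    def __getitem__(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def ci_of(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.ci_low[i]), float(self.ci_high[i])

    def p_of(self, name: str) -> float:
        return float(self.p[self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "estimate": self.estimates,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "z": self.z,
                "p": self.p,
            }
        )


# ---------------------------------------------------------------------------
# template and initialization helpers


def make_template(
    cohort: CohortData,
    family: str = "normal",
    link: str | None = None,
    long_covariates: tuple[str, ...] = (),
    random_effects: str = "intercept",
    K: int = 2,
    Q: int = 5,
    surv_covariates: tuple[str, ...] = (),
) -> ModelTemplate:
    """Model template with baseline-hazard knots at pooled event-time
    quantiles (``Q`` pieces; the last piece extends beyond its knot)."""
    if link is None:
        link = "identity" if family == "normal" else "log"
    ev_times = np.array([s.time for s in cohort.survival if s.status != 0])
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if Q == 1 or ev_times.size < Q:
        knots = (np.inf,)
    else:
        qs = np.quantile(ev_times, np.arange(1, Q) / Q)
        qs = np.unique(qs)
        knots = tuple(qs) + (np.inf,)
    return ModelTemplate(
        family=family,
        link=link,
        long_covariates=tuple(long_covariates),
        random_effects=random_effects,
        K=K,
        knots=knots,
        surv_covariates=tuple(surv_covariates),
    )


def _initial_values(
    layout: ParamLayout, data: LikelihoodData, w: np.ndarray | None = None
) -> np.ndarray:
    """Documented initialization: longitudinal parameters from a
    longitudinal-only fit, beta = 0, baseline hazards from per-interval
    occurrence/exposure rates, covariate effects from a cause-specific
    exponential-rate regression. ``w`` (inclusion weights) keeps the
    hazard-rate initializations roughly design-unbiased for the weighted
    estimator."""
    t = layout.template
    if w is None:
        w = np.ones(data.n)
    values = np.zeros(layout.size)

    # longitudinal part
    M = data.obs_sub.size
    gamma0 = np.zeros(t.p_gamma)
    sigma2_0, theta_var0 = 1.0, 1.0
    if M:
        X1obs = np.column_stack(
            [np.ones(M), data.obs_t]
            + [data.X1c[data.obs_sub, j] for j in range(data.X1c.shape[1])]
        )
        y = data.obs_y if t.family == "normal" else np.log1p(data.obs_y)
        gamma0, *_ = np.linalg.lstsq(X1obs, y, rcond=None)
        resid = y - X1obs @ gamma0
        Sr = np.bincount(data.obs_sub, weights=resid, minlength=data.n)
        Sr2 = np.bincount(data.obs_sub, weights=resid**2, minlength=data.n)
        n_i = data.n_obs
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(n_i > 0, Sr / np.maximum(n_i, 1), np.nan)
            within_ss = Sr2 - np.where(n_i > 0, Sr**2 / np.maximum(n_i, 1), 0.0)
        multi = n_i >= 2
        total_var = max(float(np.var(resid)), 1e-3)
        sigma2_0 = (
            float(within_ss[multi].sum() / np.maximum((n_i[multi] - 1).sum(), 1))
            if multi.any()
            else 0.5 * total_var
        )
        sigma2_0 = max(sigma2_0, 1e-3)
        have = n_i > 0
        between = float(np.var(means[have])) if have.sum() > 1 else total_var
        theta_var0 = max(between - sigma2_0 / max(float(n_i[have].mean()), 1.0), 0.05 * total_var, 1e-3)
    values[layout.sl_gamma] = gamma0
    if t.has_dispersion:
        values[layout.sl_tau] = np.log(sigma2_0)
    chol0 = np.zeros(t.r * (t.r + 1) // 2)
    chol0[0] = 0.5 * np.log(theta_var0)
    if t.r == 2:
        chol0[2] = 0.5 * np.log(max(0.05 * theta_var0, 1e-3))
    values[layout.sl_chol] = chol0

    # baseline hazards from (weighted) occurrence/exposure per interval
    exposure = np.maximum((w[:, None] * (data.hi - data.lo)).sum(axis=0), 1e-8)  # (Q,)
    log_xi0 = np.empty((t.K, t.Q))
    for k in range(t.K):
        for q in range(t.Q):
            ev = float(np.sum((data.delta == k + 1) & (data.qT == q)))
            log_xi0[k, q] = np.log(max(ev, 0.5) / exposure[q])
    values[layout.sl_xi] = log_xi0.ravel()

    # alpha from a cause-specific exponential-rate (Poisson) regression
    if t.p2:
        alpha0 = np.zeros((t.K, t.p2))
        exog = np.column_stack([np.ones(data.n), data.X2])
        offset = np.log(data.T)
        for k in range(t.K):
            endog = (data.delta == k + 1).astype(float)
            coefs = _poisson_irls(endog, exog, offset, w)
            if coefs is not None:
                alpha0[k] = np.clip(coefs[1:], -3.0, 3.0)
        values[layout.sl_alpha] = alpha0.ravel()
    return values


def _poisson_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, w: np.ndarray, n_iter: int = 20
) -> np.ndarray | None:
    """Weighted Poisson regression with offset (IRLS); initialization only."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(n_iter):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        W = w * mu
        score = X.T @ (w * (y - mu))
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(p), score)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            return None
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


# ---------------------------------------------------------------------------
# core optimizer


_PENALTY = 1e10  # finite "infeasible" objective: L-BFGS-B backtracks reliably


def _objective(layout, data, w, nodes):
    """Negative (weighted) log-likelihood and gradient closure."""

    def fun(values):
        try:
            ll, scores = pointwise_loglik(layout, values, data, nodes, compute_scores=True)
        except (NumericError, FloatingPointError):
            return _PENALTY, np.zeros(layout.size)
        if not np.all(np.isfinite(ll)):
            return _PENALTY, np.zeros(layout.size)
        f = -float(w @ ll)
        grad = -(scores.T @ w)
        if not np.all(np.isfinite(grad)):
            return _PENALTY, np.zeros(layout.size)
        return f, grad

    return fun


def _total_grad(layout, data, w, nodes, values):
    ll, scores = pointwise_loglik(layout, values, data, nodes, compute_scores=True)
    return scores.T @ w


def _numeric_hessian(layout, data, w, nodes, values, step=1e-5):
    """Hessian of the (weighted) log-likelihood by central differences of
    the gradient."""
    p = layout.size
    H = np.empty((p, p))
    for j in range(p):
        h = step * max(1.0, abs(values[j]))
        up, dn = values.copy(), values.copy()
        up[j] += h
        dn[j] -= h
        gu = _total_grad(layout, data, w, nodes, up)
        gd = _total_grad(layout, data, w, nodes, dn)
        H[:, j] = (gu - gd) / (2 * h)
    return 0.5 * (H + H.T)


def _pinv_psd(A: np.ndarray) -> np.ndarray:
    Ainv = np.linalg.pinv(0.5 * (A + A.T))
    return 0.5 * (Ainv + Ainv.T)


def _fit_core(
    layout: ParamLayout,
    data: LikelihoodData,
    w: np.ndarray,
    nodes: int,
    x0: np.ndarray | None = None,
    maxiter: int = 500,
):
    if x0 is None:
        x0 = _initial_values(layout, data, w)
    bounds = [(-50.0, 50.0)] * layout.size
    for j in range(*layout.sl_xi.indices(layout.size)):
        bounds[j] = (-20.0, 5.0)
    # variance parameters: keep the optimizer out of degenerate regions
    for sl in (layout.sl_tau, layout.sl_chol):
        for j in range(*sl.indices(layout.size)):
            bounds[j] = (-12.0, 12.0)
    fun = _objective(layout, data, w, nodes)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-6},
        )
    f, grad = fun(res.x)
    scaled_g = np.max(np.abs(grad)) / max(1.0, abs(f))
    converged = bool(res.success) and np.isfinite(f) and scaled_g < 1e-4
    return res, converged, scaled_g


def _finalize(layout, data, w, nodes, res, converged, method, variance) -> FitResult:
    values = res.x
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        ll, scores = pointwise_loglik(layout, values, data, nodes, compute_scores=True)
        if variance == "opg":
            # empirical Fisher information: outer product of scores
            info = scores.T @ scores
            cov_u = _pinv_psd(info)
        elif variance == "fisher":
            info = -_numeric_hessian(layout, data, w, nodes, values)
            cov_u = _pinv_psd(info)
        elif variance == "sandwich":
            info = -_numeric_hessian(layout, data, w, nodes, values)
            ws = scores * w[:, None]
            meat = ws.T @ ws
            bread = _pinv_psd(info)
            cov_u = bread @ meat @ bread
        else:
            raise ValueError(f"unknown variance estimator {variance!r}")
        J = layout.natural_jacobian(values)
        cov_nat = J @ cov_u @ J.T
    phi = ParamVector(layout, values)
    return FitResult(
        method=method,
        names=layout.natural_names(),
        estimates=layout.natural_values(values),
        cov=cov_nat,
        loglik=float(w @ ll),
        converged=converged,
        n_iter=int(res.nit),
        phi=phi,
        message=str(res.message),
        n_subjects=data.n,
    )


# ---------------------------------------------------------------------------
# public fitting API


def fit_fjmncc(
    cohort: CohortData,
    template: ModelTemplate,
    nodes: int = 15,
    maxiter: int = 500,
    x0: np.ndarray | None = None,
    method_label: str = "fJM-NCC",
) -> FitResult:
    """Full-likelihood estimator: uses every cohort subject's survival
    record plus the sub-cohort's longitudinal data. Covariance is the
    inverse empirical Fisher information (score outer products)."""
    layout = template.layout()
    data = LikelihoodData.from_cohort(cohort, template)
    if not data.has_long.any():
        raise ValueError("no longitudinal data present in the cohort")
    w = np.ones(data.n)
    res, converged, _ = _fit_core(layout, data, w, nodes, x0=x0, maxiter=maxiter)
    return _finalize(layout, data, w, nodes, res, converged, method_label, "opg")


def fit_wjmncc(
    subcohort: CohortData,
    weights: WeightTable | dict,
    template: ModelTemplate,
    nodes: int = 15,
    variance: str = "sandwich",
    maxiter: int = 500,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Weighted estimator on the NCC sub-cohort only.

    ``variance='sandwich'`` gives the robust covariance; ``'fisher'`` the
    naive inverse information of the weighted likelihood, known to
    understate uncertainty when control-to-case ratios are small.
    """
    if variance not in ("sandwich", "fisher"):
        raise ValueError("variance must be 'sandwich' or 'fisher'")
    layout = template.layout()
    data = LikelihoodData.from_cohort(subcohort, template)
    try:
        w = np.array([weights[sid] for sid in data.ids], dtype=float)
    except KeyError as e:
        raise KeyError(f"missing weight for sub-cohort subject {e.args[0]}") from None
    res, converged, _ = _fit_core(layout, data, w, nodes, x0=x0, maxiter=maxiter)
    label = "wJM-NCC" if variance == "sandwich" else "wJM-NCC-Fisher"
    return _finalize(layout, data, w, nodes, res, converged, label, variance)


def fit_wjmncc_both(
    subcohort: CohortData,
    weights: WeightTable | dict,
    template: ModelTemplate,
    nodes: int = 15,
    maxiter: int = 500,
    x0: np.ndarray | None = None,
) -> tuple[FitResult, FitResult]:
    """One weighted maximization, both covariance estimators (sandwich and
    naive Fisher) — the two share the same point estimates."""
    layout = template.layout()
    data = LikelihoodData.from_cohort(subcohort, template)
    w = np.array([weights[sid] for sid in data.ids], dtype=float)
    res, converged, _ = _fit_core(layout, data, w, nodes, x0=x0, maxiter=maxiter)
    sandwich = _finalize(layout, data, w, nodes, res, converged, "wJM-NCC", "sandwich")
    fisher = _finalize(layout, data, w, nodes, res, converged, "wJM-NCC-Fisher", "fisher")
    return sandwich, fisher


# ---------------------------------------------------------------------------
# tests and multiplicity


def wald_test(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided Wald z test: ``z = estimate / se``, p from N(0, 1)."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = estimate / se
    return z, 2.0 * float(stats.norm.sf(abs(z)))


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: 'bonferroni' or 'bh' (Benjamini-Hochberg
    step-up adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")
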