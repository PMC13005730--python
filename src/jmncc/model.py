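"""Sub-model specifications and the unconstrained parameter vector.

The joint model couples

* a longitudinal GLMM: ``g(E[Y_ij | b_i]) = gamma' x_i(t_ij) + b_i' z(t_ij)``
  with ``b_i ~ N(0, Sigma_theta)`` (random intercept, or intercept+slope),
  Gaussian (identity link, dispersion sigma^2) or Poisson (log link); and
* cause-specific proportional hazards for K competing events:
  ``lambda_k(t | b_i) = lambda_0k(t) exp(beta_k m_i(t) + alpha_k' x2_i)``
  where ``m_i(t) = g^{-1}(gamma' x_i(t) + b_i' z(t))`` is the current
  model-implied biomarker value and ``lambda_0k`` is piecewise constant on
  ``(nu_{q-1}, nu_q]`` with values ``xi_kq`` (last piece extended beyond
  ``nu_Q``).

All parameters pack bijectively into one unconstrained real vector for
optimization: log transforms for the dispersion and baseline hazards, and a
log-Cholesky factor for ``Sigma_theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "LongSubmodelSpec",
    "SurvSubmodelSpec",
    "ModelTemplate",
    "ParamLayout",
    "ParamVector",
]


@dataclass(frozen=True)
class LongSubmodelSpec:
    """Longitudinal GLMM: family, link, designs and parameters.

    The fixed design row is ``[1, t, covariates...]`` (covariates named by
    ``covariate_names``, read from the subject's baseline record); the
    random design row is ``[1]`` or ``[1, t]``.
    """

    family: str = "normal"  # {normal, poisson}
    link: str = "identity"  # {identity, log}
    covariate_names: tuple[str, ...] = ()
    random_effects: str = "intercept"  # {intercept, intercept_slope}
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(2))
    tau: float = 1.0  # sigma^2 for normal; fixed 1 for Poisson
    Sigma_theta: np.ndarray = field(default_factory=lambda: np.eye(1))

    def __post_init__(self) -> None:
        if self.family not in ("normal", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in ("identity", "log"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.family == "poisson" and self.link != "log":
            raise ValueError("poisson family requires log link")
        if self.random_effects not in ("intercept", "intercept_slope"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        object.__setattr__(self, "gamma", g)
        if g.size != self.p_gamma:
            raise ValueError(f"gamma must have length {self.p_gamma}, got {g.size}")
        S = np.atleast_2d(np.asarray(self.Sigma_theta, dtype=float))
        object.__setattr__(self, "Sigma_theta", S)
        if S.shape != (self.r, self.r):
            raise ValueError(f"Sigma_theta must be {self.r}x{self.r}")
        if not np.allclose(S, S.T):
            raise ValueError("Sigma_theta must be symmetric")
        if np.any(np.linalg.eigvalsh(S) <= 0):
            raise ValueError("Sigma_theta must be positive definite")
        if self.family == "normal" and self.tau <= 0:
            raise ValueError("dispersion sigma^2 must be positive")

    @property
    def r(self) -> int:
        return 1 if self.random_effects == "intercept" else 2

    @property
    def p_gamma(self) -> int:
        return 2 + len(self.covariate_names)

    def fixed_row(self, covariates: dict, t: float) -> np.ndarray:
        return np.array([1.0, t] + [covariates[c] for c in self.covariate_names])

    def random_row(self, t: float) -> np.ndarray:
        return np.array([1.0]) if self.r == 1 else np.array([1.0, t])

    def inverse_link(self, eta):
        return eta if self.link == "identity" else np.exp(eta)


@dataclass(frozen=True)
class SurvSubmodelSpec:
    """Cause-specific hazards: piecewise-constant baselines and effects.

    ``knots`` holds the upper cutpoints ``nu_1 < ... < nu_Q`` (with
    ``nu_0 = 0`` implicit); ``xi`` is the K x Q matrix of baseline hazard
    levels; ``beta`` the K association coefficients on the current
    biomarker value; ``alpha`` the K x p2 baseline covariate effects on
    the covariates named by ``covariate_names``.
    """

    K: int = 2
    knots: np.ndarray = field(default_factory=lambda: np.array([np.inf]))
    xi: np.ndarray = field(default_factory=lambda: 0.01 * np.ones((2, 1)))
    beta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    alpha: np.ndarray = field(default_factory=lambda: np.zeros((2, 0)))
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        kn = np.atleast_1d(np.asarray(self.knots, dtype=float))
        object.__setattr__(self, "knots", kn)
        if kn.size < 1 or kn[0] <= 0 or np.any(np.diff(kn) <= 0):
            raise ValueError("knots must be strictly increasing and positive")
        xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        object.__setattr__(self, "xi", xi)
        if xi.shape != (self.K, self.Q):
            raise ValueError(f"xi must be {self.K}x{self.Q}")
        if np.any(xi <= 0):
            raise ValueError("baseline hazard values xi must be positive")
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", b)
        if b.size != self.K:
            raise ValueError(f"beta must have length {self.K}")
        a = np.asarray(self.alpha, dtype=float).reshape(self.K, -1)
        object.__setattr__(self, "alpha", a)
        if a.shape[1] != len(self.covariate_names):
            raise ValueError("alpha columns must match covariate_names")

    @property
    def Q(self) -> int:
        return self.knots.size

    @property
    def p2(self) -> int:
        return len(self.covariate_names)

    def surv_row(self, covariates: dict) -> np.ndarray:
        return np.array([covariates[c] for c in self.covariate_names])


@dataclass(frozen=True)
class ModelTemplate:
    """Structural description of the joint model (everything but numbers).

    A template plus an unconstrained vector determines the full model; the
    template fixes family, link, design columns, random-effect structure,
    number of causes and baseline-hazard knots.
    """

    family: str = "normal"
    link: str = "identity"
    long_covariates: tuple[str, ...] = ()
    random_effects: str = "intercept"
    K: int = 2
    knots: tuple[float, ...] = (np.inf,)
    surv_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "long_covariates", tuple(self.long_covariates))
        object.__setattr__(self, "surv_covariates", tuple(self.surv_covariates))
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))

    @property
    def r(self) -> int:
        return 1 if self.random_effects == "intercept" else 2

    @property
    def p_gamma(self) -> int:
        return 2 + len(self.long_covariates)

    @property
    def Q(self) -> int:
        return len(self.knots)

    @property
    def p2(self) -> int:
        return len(self.surv_covariates)

    @property
    def has_dispersion(self) -> bool:
        return self.family == "normal"

    def layout(self) -> "ParamLayout":
        return ParamLayout(self)


def _chol_to_free(S: np.ndarray) -> np.ndarray:
    """Log-Cholesky parameterization: log diagonal, raw sub-diagonal."""
    L = np.linalg.cholesky(S)
    r = S.shape[0]
    free = []
    for i in range(r):
        for j in range(i + 1):
            free.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(free)


def _free_to_chol(free: np.ndarray, r: int) -> np.ndarray:
    L = np.zeros((r, r))
    k = 0
    for i in range(r):
        for j in range(i + 1):
            L[i, j] = np.exp(free[k]) if i == j else free[k]
            k += 1
    return L


class ParamLayout:
    """Named slices of the unconstrained parameter vector phi.

    Order: gamma, log dispersion (normal family only), log-Cholesky of
    Sigma_theta, log xi (row-major K x Q), beta, alpha (row-major K x p2).
    """

    def __init__(self, template: ModelTemplate):
        self.template = template
        t = template
        names: list[str] = []
        names.append("gamma_intercept")
        names.append("gamma_time")
        names += [f"gamma_{c}" for c in t.long_covariates]
        self.sl_gamma = slice(0, t.p_gamma)
        pos = t.p_gamma
        if t.has_dispersion:
            names.append("log_sigma2")
            self.sl_tau = slice(pos, pos + 1)
            pos += 1
        else:
            self.sl_tau = slice(pos, pos)
        n_chol = t.r * (t.r + 1) // 2
        names += [f"chol_theta_{i}" for i in range(n_chol)]
        self.sl_chol = slice(pos, pos + n_chol)
        pos += n_chol
        names += [f"log_xi_{k + 1}_{q + 1}" for k in range(t.K) for q in range(t.Q)]
        self.sl_xi = slice(pos, pos + t.K * t.Q)
        pos += t.K * t.Q
        names += [f"beta_{k + 1}" for k in range(t.K)]
        self.sl_beta = slice(pos, pos + t.K)
        pos += t.K
        names += [f"alpha_{k + 1}_{c}" for k in range(t.K) for c in t.surv_covariates]
        self.sl_alpha = slice(pos, pos + t.K * t.p2)
        pos += t.K * t.p2
        self.size = pos
        self.names = names

    # -- packing -----------------------------------------------------------

    def pack(self, long_spec: LongSubmodelSpec, surv_spec: SurvSubmodelSpec) -> np.ndarray:
        t = self.template
        parts = [np.asarray(long_spec.gamma, dtype=float)]
        if t.has_dispersion:
            parts.append(np.array([np.log(long_spec.tau)]))
        parts.append(_chol_to_free(long_spec.Sigma_theta))
        parts.append(np.log(surv_spec.xi).ravel())
        parts.append(np.asarray(surv_spec.beta, dtype=float))
        parts.append(np.asarray(surv_spec.alpha, dtype=float).ravel())
        return np.concatenate(parts)

    def unpack(self, values: np.ndarray) -> tuple[LongSubmodelSpec, SurvSubmodelSpec]:
        t = self.template
        values = np.asarray(values, dtype=float)
        if values.size != self.size:
            raise ValueError(f"expected vector of length {self.size}, got {values.size}")
        gamma = values[self.sl_gamma]
        tau = float(np.exp(values[self.sl_tau][0])) if t.has_dispersion else 1.0
        L = _free_to_chol(values[self.sl_chol], t.r)
        Sigma = L @ L.T
        long_spec = LongSubmodelSpec(
            family=t.family,
            link=t.link,
            covariate_names=t.long_covariates,
            random_effects=t.random_effects,
            gamma=gamma,
            tau=tau,
            Sigma_theta=Sigma,
        )
        xi = np.exp(values[self.sl_xi]).reshape(t.K, t.Q)
        surv_spec = SurvSubmodelSpec(
            K=t.K,
            knots=np.array(t.knots),
            xi=xi,
            beta=values[self.sl_beta].copy(),
            alpha=values[self.sl_alpha].reshape(t.K, t.p2),
            covariate_names=t.surv_covariates,
        )
        return long_spec, surv_spec

    # -- natural-scale views ----------------------------------------------

    def natural_names(self) -> list[str]:
        t = self.template
        names = [n for n in self.names if n.startswith("gamma_")]
        if t.has_dispersion:
            names.append("sigma2")
        if t.r == 1:
            names.append("theta_var")
        else:
            names += ["theta_var_intercept", "theta_cov", "theta_var_slope"]
        names += [f"xi_{k + 1}_{q + 1}" for k in range(t.K) for q in range(t.Q)]
        names += [f"beta_{k + 1}" for k in range(t.K)]
        names += [f"alpha_{k + 1}_{c}" for k in range(t.K) for c in t.surv_covariates]
        return names

    def natural_values(self, values: np.ndarray) -> np.ndarray:
        long_spec, surv_spec = self.unpack(values)
        parts = [long_spec.gamma]
        if self.template.has_dispersion:
            parts.append([long_spec.tau])
        S = long_spec.Sigma_theta
        if self.template.r == 1:
            parts.append([S[0, 0]])
        else:
            parts.append([S[0, 0], S[1, 0], S[1, 1]])
        parts.append(surv_spec.xi.ravel())
        parts.append(surv_spec.beta)
        parts.append(surv_spec.alpha.ravel())
        return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])

    def natural_jacobian(self, values: np.ndarray) -> np.ndarray:
        """d(natural)/d(unconstrained), for the delta-method covariance on
        the natural scale. The map is elementwise (identity or exp) except
        for the Cholesky block of Sigma_theta."""
        t = self.template
        values = np.asarray(values, dtype=float)
        n_nat = len(self.natural_names())
        J = np.zeros((n_nat, self.size))
        row = 0
        for j in range(*self.sl_gamma.indices(self.size)):
            J[row, j] = 1.0
            row += 1
        if t.has_dispersion:
            j = self.sl_tau.start
            J[row, j] = np.exp(values[j])  # sigma2 = e^x
            row += 1
        c = values[self.sl_chol]
        j0 = self.sl_chol.start
        if t.r == 1:
            J[row, j0] = 2.0 * np.exp(2.0 * c[0])  # theta_var = L00^2
            row += 1
        else:
            L00, L10, L11 = np.exp(c[0]), c[1], np.exp(c[2])
            # S00 = L00^2 ; S10 = L10 L00 ; S11 = L10^2 + L11^2
            J[row, j0] = 2.0 * L00**2
            row += 1
            J[row, j0] = L10 * L00
            J[row, j0 + 1] = L00
            row += 1
            J[row, j0 + 1] = 2.0 * L10
            J[row, j0 + 2] = 2.0 * L11**2
            row += 1
        for j in range(*self.sl_xi.indices(self.size)):
            J[row, j] = np.exp(values[j])  # xi = e^x
            row += 1
        for j in range(*self.sl_beta.indices(self.size)):
            J[row, j] = 1.0
            row += 1
        for j in range(*self.sl_alpha.indices(self.size)):
            J[row, j] = 1.0
            row += 1
        return J


@dataclass(frozen=True)
class ParamVector:
    """Unconstrained parameter vector bound to its layout."""

    layout: ParamLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size != self.layout.size:
            raise ValueError("values length does not match layout")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_specs(
        cls, template: ModelTemplate, long_spec: LongSubmodelSpec, surv_spec: SurvSubmodelSpec
    ) -> "ParamVector":
        layout = template.layout()
        return cls(layout, layout.pack(long_spec, surv_spec))

    def unpack(self) -> tuple[LongSubmodelSpec, SurvSubmodelSpec]:
        return self.layout.unpack(self.values)

    @property
    def names(self) -> list[str]:
        return self.layout.names
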