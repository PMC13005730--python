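"""Replicate simulation experiments and their evaluation metrics.

A scenario couples a data-generating configuration with an NCC design
(control-to-case ratio m, matching factors) and a fitting configuration.
:func:`run_replicates` simulates cohort -> NCC sample -> fits per method,
and :func:`aggregate_metrics` reduces the per-replicate estimates to the
standard simulation metrics: Bias, mean estimated SE, empirical SE (SD of
estimates), MSE, mean CI length, empirical coverage probability, and the
Wald rejection rate at alpha = 0.05 (type-I error under the null; power
under the alternative).

Methods
-------
``oracle``
    full-likelihood joint model with longitudinal data retained for the
    whole cohort (the benchmark unattainable in a real NCC study);
``fjmncc``
    full likelihood using full-cohort survival + sub-cohort biomarkers;
``wjmncc`` / ``wjmncc-fisher``
    weighted likelihood on the sub-cohort with sandwich / naive Fisher
    SEs (one maximization, two covariances);
``jm``
    naive joint model treating the sub-cohort as a cohort;
``clr``
    conditional logistic regression per cause with mean-biomarker
    covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import build_matched_sets, fit_clr, fit_naive_jm
from .datamodel import CohortData
from .estimation import FitResult, adjust_pvalues, fit_fjmncc, fit_wjmncc_both
from .model import ModelTemplate
from .ncc import MatchingSpec, compute_inclusion_weights, sample_ncc
from .simulator import SimConfig, attach_longitudinal, sample_longitudinal, simulate_full_cohort, simulate_multifeature

logger = logging.getLogger("jmncc")

__all__ = [
    "Scenario",
    "run_replicates",
    "aggregate_metrics",
    "power_curve",
    "fdr_tpr_experiment",
    "true_parameter_values",
]

ALL_METHODS = ("oracle", "fjmncc", "wjmncc", "wjmncc-fisher", "jm", "clr")
_ALPHA = 0.05


@dataclass(frozen=True)
class Scenario:
    """Simulation scenario: generator config + NCC design + fit config."""

    sim: SimConfig
    m: int = 1
    matching: tuple[str, ...] = ("x2",)
    nodes: int = 15
    fit_knots: tuple[float, ...] | None = None  # default: the generator's knots

    def template(self) -> ModelTemplate:
        knots = self.fit_knots if self.fit_knots is not None else self.sim.knots
        return ModelTemplate(
            family=self.sim.family,
            link=self.sim.link,
            long_covariates=(),
            random_effects=self.sim.random_effects,
            K=self.sim.K,
            knots=knots,
            surv_covariates=("x2",),
        )


def true_parameter_values(sim: SimConfig, fit_knots=None) -> dict[str, float]:
    """Natural-scale true values keyed by fitted parameter name.

    Baseline-hazard truths are only included when the fitted knots match
    the generating knots (otherwise the piecewise fit approximates a
    different shape and elementwise comparison is meaningless).
    """
    truth = {
        "gamma_intercept": sim.gamma[0],
        "gamma_time": sim.gamma[1],
        "sigma2": sim.sigma2,
        "theta_var": sim.theta_var,
    }
    if sim.r == 2:
        truth.update(
            theta_var_intercept=sim.theta_var,
            theta_cov=sim.theta_cov,
            theta_var_slope=sim.theta_slope_var,
        )
        del truth["theta_var"]
    for k in range(sim.K):
        truth[f"beta_{k + 1}"] = sim.beta[k]
        truth[f"alpha_{k + 1}_x2"] = sim.alpha[k][0]
    if fit_knots is None or tuple(fit_knots) == tuple(sim.knots):
        for k in range(sim.K):
            for q in range(len(sim.knots)):
                truth[f"xi_{k + 1}_{q + 1}"] = sim.xi[k][q]
    return truth


def _result_rows(rep: int, method: str, fit: FitResult) -> list[dict]:
    return [
        {
            "rep": rep,
            "method": method,
            "parameter": name,
            "estimate": fit.estimates[j],
            "se": fit.se[j],
            "ci_low": fit.ci_low[j],
            "ci_high": fit.ci_high[j],
            "p": fit.p[j],
            "converged": fit.converged,
        }
        for j, name in enumerate(fit.names)
    ]


def _simulate_replicate(scenario: Scenario, rep_seed: np.random.SeedSequence, need_oracle: bool):
    """One cohort + NCC sample + revealed longitudinal data."""
    s_sim, s_long, s_ncc = rep_seed.spawn(3)
    cohort, truth = simulate_full_cohort(scenario.sim, seed=s_sim, strict=True)
    matching = MatchingSpec(scenario.matching)
    flags, selections = sample_ncc(cohort.survival, scenario.m, matching, seed=s_ncc)
    weights = compute_inclusion_weights(selections, flags, cohort.survival, matching)
    sub_ids = [s.id for s in cohort.survival if flags[s.id] == 1]
    reveal = None if need_oracle else sub_ids
    series = sample_longitudinal(cohort, truth, scenario.sim, ids=reveal, seed=s_long)
    sub_series = {sid: series[sid] for sid in sub_ids}
    ncc_cohort = attach_longitudinal(cohort, sub_series, flags, selections)
    subcohort = ncc_cohort.restrict_to_subcohort()
    oracle_cohort = (
        attach_longitudinal(cohort, series, {sid: 1 for sid in series}, selections)
        if need_oracle
        else None
    )
    return ncc_cohort, subcohort, oracle_cohort, weights, selections, truth


def _fit_methods(
    scenario: Scenario,
    methods,
    ncc_cohort: CohortData,
    subcohort: CohortData,
    oracle_cohort,
    weights,
    selections,
    rep: int,
) -> list[dict]:
    template = scenario.template()
    nodes = scenario.nodes
    rows: list[dict] = []
    if "oracle" in methods:
        rows += _result_rows(rep, "oracle", fit_fjmncc(oracle_cohort, template, nodes=nodes))
    if "fjmncc" in methods:
        rows += _result_rows(rep, "fjmncc", fit_fjmncc(ncc_cohort, template, nodes=nodes))
    if "wjmncc" in methods or "wjmncc-fisher" in methods:
        sandwich, fisher = fit_wjmncc_both(subcohort, weights, template, nodes=nodes)
        if "wjmncc" in methods:
            rows += _result_rows(rep, "wjmncc", sandwich)
        if "wjmncc-fisher" in methods:
            rows += _result_rows(rep, "wjmncc-fisher", fisher)
    if "jm" in methods:
        rows += _result_rows(rep, "jm", fit_naive_jm(subcohort, template, nodes=nodes))
    if "clr" in methods:
        for k in range(1, scenario.sim.K + 1):
            sets = build_matched_sets(subcohort, selections, event_of_interest=k)
            if not sets:
                continue
            res = fit_clr(sets)
            est, se = res.estimates[0], res.se[0]
            rows.append(
                {
                    "rep": rep,
                    "method": "clr",
                    "parameter": f"beta_{k}",
                    "estimate": est,
                    "se": se,
                    "ci_low": est - 1.959963984540054 * se,
                    "ci_high": est + 1.959963984540054 * se,
                    "p": res.p[0],
                    "converged": res.converged,
                }
            )
    return rows


def run_replicates(
    scenario: Scenario,
    methods=("fjmncc", "wjmncc"),
    n_reps: int = 200,
    seed: int | np.random.SeedSequence = 0,
    max_failure_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-replicate estimates for every method (long format).

    Replicates whose simulation or fit raises are logged and excluded;
    more than ``max_failure_fraction`` failures aborts with a diagnostic.
    Non-converged fits are kept in the output flagged ``converged=False``
    (and excluded by :func:`aggregate_metrics`).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_reps)
    need_oracle = "oracle" in methods
    rows: list[dict] = []
    failures = 0
    for rep in range(n_reps):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                parts = _simulate_replicate(scenario, rep_seeds[rep], need_oracle)
                ncc_cohort, subcohort, oracle_cohort, weights, selections, _ = parts
                rows += _fit_methods(
                    scenario, methods, ncc_cohort, subcohort, oracle_cohort,
                    weights, selections, rep,
                )
        except Exception as e:  # noqa: BLE001 - replicate-level robustness
            failures += 1
            logger.warning("replicate %d failed: %s", rep, e)
        if failures > max_failure_fraction * n_reps:
            raise RuntimeError(
                f"{failures} of {rep + 1} replicates failed (> {max_failure_fraction:.0%}); "
                "check the scenario configuration"
            )
    df = pd.DataFrame(rows)
    df.attrs["n_failures"] = failures
    df.attrs["n_reps"] = n_reps
    return df


def aggregate_metrics(
    raw: pd.DataFrame,
    truth: dict[str, float],
    alpha: float = _ALPHA,
) -> pd.DataFrame:
    """Reduce per-replicate estimates to the simulation metrics.

    Only parameters with a known true value are scored; non-converged
    replicates are excluded and counted in ``n_excluded``.
    """
    out = []
    for (method, param), grp in raw.groupby(["method", "parameter"], sort=True):
        if param not in truth:
            continue
        ok = grp[grp["converged"]]
        n = len(ok)
        if n < 2:
            continue
        tv = truth[param]
        est = ok["estimate"].to_numpy()
        se = ok["se"].to_numpy()
        bias = float(est.mean() - tv)
        ese = float(est.std(ddof=1))
        mse = float(np.mean((est - tv) ** 2))
        cover = (ok["ci_low"].to_numpy() <= tv) & (tv <= ok["ci_high"].to_numpy())
        ecp = float(cover.mean())
        reject = float((ok["p"].to_numpy() < alpha).mean())
        out.append(
            {
                "method": method,
                "parameter": param,
                "truth": tv,
                "bias": bias,
                "se_mean": float(se.mean()),
                "ese": ese,
                "mse": mse,
                "ci_length_mean": float((ok["ci_high"] - ok["ci_low"]).mean()),
                "ecp": ecp,
                "reject_rate": reject,
                "n_replicates": n,
                "n_excluded": int(len(grp) - n),
                "bias_mc_se": ese / np.sqrt(n),
                "ecp_mc_se": float(np.sqrt(max(ecp * (1 - ecp), 1e-12) / n)),
                "reject_mc_se": float(np.sqrt(max(reject * (1 - reject), 1e-12) / n)),
            }
        )
    return pd.DataFrame(out)


def power_curve(
    scenario: Scenario,
    beta1_grid,
    methods=("fjmncc", "wjmncc"),
    n_reps: int = 100,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = _ALPHA,
) -> pd.DataFrame:
    """Wald rejection rate of H0: beta_1 = 0 along a grid of true beta_1.

    The grid point 0 reproduces type-I error; elsewhere the rate is power.
    """
    if len(list(beta1_grid)) == 0:
        raise ValueError("beta1_grid must be non-empty")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for b1, child in zip(beta1_grid, ss.spawn(len(list(beta1_grid)))):
        sim = replace(scenario.sim, beta=(float(b1), scenario.sim.beta[1]))
        raw = run_replicates(replace(scenario, sim=sim), methods, n_reps, child)
        sub = raw[raw["parameter"] == "beta_1"]
        for method, grp in sub.groupby("method"):
            ok = grp[grp["converged"]]
            rows.append(
                {
                    "beta1": float(b1),
                    "method": method,
                    "reject_rate": float((ok["p"] < alpha).mean()),
                    "n_replicates": len(ok),
                }
            )
    return pd.DataFrame(rows)


def _overall_pvalue(fit: FitResult) -> float:
    """Wald chi-square test of no association with either event
    (H0: beta_1 = beta_2 = 0, 2 df)."""
    i1 = fit.names.index("beta_1")
    i2 = fit.names.index("beta_2")
    beta = fit.estimates[[i1, i2]]
    V = fit.cov[np.ix_([i1, i2], [i1, i2])]
    try:
        stat = float(beta @ np.linalg.solve(V, beta))
    except np.linalg.LinAlgError:
        return np.nan
    return float(stats.chi2.sf(stat, df=2))


def fdr_tpr_experiment(
    scenario: Scenario,
    n_features: int = 50,
    signal_fraction: float = 0.1,
    beta_signal: tuple[float, float] = (0.5, -0.5),
    methods=("oracle", "fjmncc", "wjmncc"),
    n_reps: int = 50,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = _ALPHA,
) -> pd.DataFrame:
    """Multi-feature discovery experiment: empirical FDR and TPR.

    Per replicate, every feature is fitted separately per method; the
    overall association test (either event) is BH-adjusted across
    features and discoveries at ``alpha`` are scored against the known
    signal labels. With an all-null configuration TPR is reported as NaN
    and FDR degenerates to a familywise false-positive rate.
    """
    from .likelihood import LikelihoodData
    from .estimation import _finalize, _fit_core

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_reps)
    template = scenario.template()
    layout = template.layout()
    matching = MatchingSpec(scenario.matching)
    per_rep: list[dict] = []
    failures = 0

    warm: dict[str, np.ndarray] = {}  # warm starts per analysis view

    def _core(view, data, w, obs_y):
        data.obs_y = obs_y
        res, conv, _ = _fit_core(layout, data, w, scenario.nodes, x0=warm.get(view))
        if not conv and view in warm:  # retry from scratch if warm start misleads
            res, conv, _ = _fit_core(layout, data, w, scenario.nodes)
        if conv:
            warm[view] = res.x.copy()
        return res, conv

    def _refit(view, data, w, obs_y, variance, label):
        res, conv = _core(view, data, w, obs_y)
        fit = _finalize(layout, data, w, scenario.nodes, res, conv, label, variance)
        return fit

    for rep in range(n_reps):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s_sim, s_ncc = rep_seeds[rep].spawn(2)
                cohort, truth, feats, signal_mask = simulate_multifeature(
                    scenario.sim, n_features, signal_fraction, beta_signal, seed=s_sim
                )
                flags, selections = sample_ncc(cohort.survival, scenario.m, matching, seed=s_ncc)
                weights = compute_inclusion_weights(selections, flags, cohort.survival, matching)
                sub_ids = {s.id for s in cohort.survival if flags[s.id] == 1}
                # one LikelihoodData per analysis view; feature loop swaps obs_y
                series0 = feats[0]
                sub_series0 = {sid: series0[sid] for sid in sub_ids}
                views: dict[str, tuple] = {}
                if "oracle" in methods:
                    oc = attach_longitudinal(cohort, series0, {sid: 1 for sid in series0})
                    d = LikelihoodData.from_cohort(oc, template)
                    views["oracle"] = (d, np.ones(d.n), [s.id for s in oc.survival])
                if "fjmncc" in methods:
                    nc = attach_longitudinal(cohort, sub_series0, flags, selections)
                    d = LikelihoodData.from_cohort(nc, template)
                    order = [s.id for s in nc.survival if s.id in sub_ids]
                    views["fjmncc"] = (d, np.ones(d.n), order)
                if "wjmncc" in methods or "wjmncc-fisher" in methods:
                    nc = attach_longitudinal(cohort, sub_series0, flags, selections)
                    sub = nc.restrict_to_subcohort()
                    d = LikelihoodData.from_cohort(sub, template)
                    wv = np.array([weights[sid] for sid in d.ids])
                    views["wjmncc"] = (d, wv, list(d.ids))
                pvals = {m: np.empty(n_features) for m in methods}
                for f in range(n_features):
                    series_all = feats[f]
                    if "oracle" in methods:
                        d, wv, order = views["oracle"]
                        y = np.concatenate([series_all[sid].values for sid in order])
                        fit = _refit("oracle", d, wv, y, "opg", "oracle")
                        pvals["oracle"][f] = _overall_pvalue(fit) if fit.converged else np.nan
                    if "fjmncc" in methods:
                        d, wv, order = views["fjmncc"]
                        y = np.concatenate([series_all[sid].values for sid in order])
                        fit = _refit("fjmncc", d, wv, y, "opg", "fJM-NCC")
                        pvals["fjmncc"][f] = _overall_pvalue(fit) if fit.converged else np.nan
                    if "wjmncc" in methods or "wjmncc-fisher" in methods:
                        d, wv, order = views["wjmncc"]
                        y = np.concatenate([series_all[sid].values for sid in order])
                        res, conv = _core("wjmncc", d, wv, y)
                        if "wjmncc" in methods:
                            sw = _finalize(layout, d, wv, scenario.nodes, res, conv,
                                           "wJM-NCC", "sandwich")
                            pvals["wjmncc"][f] = _overall_pvalue(sw) if conv else np.nan
                        if "wjmncc-fisher" in methods:
                            fis = _finalize(layout, d, wv, scenario.nodes, res, conv,
                                            "wJM-NCC-Fisher", "fisher")
                            pvals["wjmncc-fisher"][f] = _overall_pvalue(fis) if conv else np.nan
                n_sig = int(signal_mask.sum())
                for m in methods:
                    p = np.where(np.isnan(pvals[m]), 1.0, pvals[m])
                    disc = adjust_pvalues(p, "bh") <= alpha
                    tp = int(np.sum(disc & signal_mask))
                    fp = int(np.sum(disc & ~signal_mask))
                    per_rep.append(
                        {
                            "rep": rep,
                            "method": m,
                            "fdr": fp / max(1, int(disc.sum())),
                            "tpr": tp / n_sig if n_sig else np.nan,
                            "discoveries": int(disc.sum()),
                        }
                    )
        except Exception as e:  # noqa: BLE001
            failures += 1
            logger.warning("multifeature replicate %d failed: %s", rep, e)
        if failures > 0.2 * n_reps:
            raise RuntimeError(f"{failures} multifeature replicates failed")
    df = pd.DataFrame(per_rep)
    out = df.groupby("method", sort=True).agg(
        fdr=("fdr", "mean"), tpr=("tpr", "mean"), n_replicates=("rep", "nunique")
    ).reset_index()
    out.attrs["per_replicate"] = df
    return out
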