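"""Analysis models fitted to each simulated trial.

The crossover estimator mirrors the cluster-level analysis used for
within-cluster designs: a fixed-effects GLM on the K×J cluster-period
aggregates with one nuisance parameter per cluster, optionally J−1 fixed
period indicators, and — for counts — the log total at-risk time as an
offset.  The single-period (parallel CRT) estimators are a pooled logistic
regression for binary outcomes and cluster-summary t-comparisons for
continuous and count outcomes.

Every estimator returns an :class:`EffectEstimate`; degenerate data
(zero-event clusters, separation, singular fits) yield
``converged=False`` rather than an exception, so the power engine can tally
failure rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, t as t_dist

from .datagen import ClusterPeriodSummary, SimulatedTrial, aggregate

__all__ = [
    "EffectEstimate",
    "fit_cluster_fixed",
    "fit_single_period",
    "reject_null",
    "register_estimator",
    "get_estimator",
    "available_estimators",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Treatment-effect estimate on the link scale, with a Wald interval."""

    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool
    model_label: str

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.ci_low <= self.theta_hat <= self.ci_high):
                raise ValueError("confidence interval must bracket the estimate")
            if not self.se > 0:
                raise ValueError("standard error must be positive for a converged fit")


def _failed(label: str) -> EffectEstimate:
    nan = float("nan")
    return EffectEstimate(nan, nan, nan, nan, converged=False, model_label=label)


def _estimate_from_fit(theta: float, se: float, crit: float, label: str) -> EffectEstimate:
    if not (np.isfinite(theta) and np.isfinite(se) and se > 0):
        return _failed(label)
    return EffectEstimate(
        float(theta), float(se), float(theta - crit * se), float(theta + crit * se),
        converged=True, model_label=label,
    )


def reject_null(estimate: EffectEstimate, alpha: float = 0.05) -> bool:
    """CI-covers-zero rejection rule.

    True iff zero lies strictly outside [ci_low, ci_high]; an endpoint
    exactly at zero counts as covering (fail to reject).  Raises on a
    non-converged estimate — a failed fit yields no test decision.
    """
    if not estimate.converged:
        raise ValueError("cannot apply the rejection rule to a non-converged fit")
    return not (estimate.ci_low <= 0.0 <= estimate.ci_high)


# ---------------------------------------------------------------------------
# crossover (J >= 2): cluster fixed-effects GLM on cluster-period aggregates
# ---------------------------------------------------------------------------


def _cells(summaries: Sequence[ClusterPeriodSummary]):
    clusters = sorted({s.cluster for s in summaries})
    periods = sorted({s.period for s in summaries})
    cmap = {c: i for i, c in enumerate(clusters)}
    pmap = {p: i for i, p in enumerate(periods)}
    return clusters, periods, cmap, pmap


def fit_cluster_fixed(
    summaries: Sequence[ClusterPeriodSummary],
    family: str | None = None,
    include_period_effect: bool = False,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Cluster fixed-effects GLM on the K×J cluster-period aggregates.

    Count family: log E[events] = log(exposure) + gamma_k [+ delta_j] + theta*X,
    a Poisson regression with one parameter per cluster and the log total
    at-risk time as offset.  Binary family: the analogous logistic model on
    (successes, n).  Continuous family: a weighted linear model on the
    cluster-period means (weights n).  Wald z intervals for the Poisson and
    logistic fits; the linear fit uses t quantiles on its residual degrees
    of freedom.

    Requires J ≥ 2: with a single period the treatment indicator is
    confounded with the cluster effects and the model is not identifiable.
    """
    summaries = list(summaries)
    family = family or summaries[0].family
    label = "cluster_fixed_period" if include_period_effect else "cluster_fixed"
    clusters, periods, cmap, pmap = _cells(summaries)
    K, J, n_obs = len(clusters), len(periods), len(summaries)
    if J < 2:
        raise ValueError(
            "cluster fixed-effects analysis needs J >= 2 periods "
            "(use fit_single_period for parallel designs)"
        )
    if K < 2:
        raise ValueError("need at least 2 clusters")

    n_par = K + (J - 1 if include_period_effect else 0) + 1
    X = np.zeros((n_obs, n_par))
    treat = np.zeros(n_obs)
    for r, s in enumerate(summaries):
        X[r, cmap[s.cluster]] = 1.0
        if include_period_effect and pmap[s.period] > 0:
            X[r, K + pmap[s.period] - 1] = 1.0
        X[r, -1] = treat[r] = s.treatment

    if family == "poisson":
        y = np.array([s.events for s in summaries], dtype=float)
        exposure = np.array([s.exposure for s in summaries], dtype=float)
        # divergence guards: a zero-event cluster sends gamma_k to -inf
        # (likewise a zero-event period or arm for their coefficients)
        cl_tot = np.zeros(K)
        np.add.at(cl_tot, [cmap[s.cluster] for s in summaries], y)
        if np.any(cl_tot == 0) or y[treat == 1].sum() == 0 or y[treat == 0].sum() == 0:
            return _failed(label)
        if include_period_effect:
            per_tot = np.zeros(J)
            np.add.at(per_tot, [pmap[s.period] for s in summaries], y)
            if np.any(per_tot == 0):
                return _failed(label)
        try:
            res = sm.GLM(
                y, X, family=sm.families.Poisson(), offset=np.log(exposure)
            ).fit(maxiter=200)
        except Exception:
            return _failed(label)
        if not res.converged:
            return _failed(label)
        crit = norm.ppf(1 - alpha / 2)
        return _estimate_from_fit(res.params[-1], res.bse[-1], crit, label)

    if family == "binomial":
        succ = np.array([s.events for s in summaries], dtype=float)
        tot = np.array([float(s.n) for s in summaries])
        cl_s = np.zeros(K)
        cl_n = np.zeros(K)
        idx = [cmap[s.cluster] for s in summaries]
        np.add.at(cl_s, idx, succ)
        np.add.at(cl_n, idx, tot)
        # all-success or all-failure clusters (or arms) separate the fit
        if np.any(cl_s == 0) or np.any(cl_s == cl_n):
            return _failed(label)
        for arm in (0, 1):
            m = treat == arm
            if succ[m].sum() == 0 or succ[m].sum() == tot[m].sum():
                return _failed(label)
        try:
            res = sm.GLM(
                np.column_stack([succ, tot - succ]), X, family=sm.families.Binomial()
            ).fit(maxiter=200)
        except Exception:
            return _failed(label)
        if not res.converged:
            return _failed(label)
        crit = norm.ppf(1 - alpha / 2)
        return _estimate_from_fit(res.params[-1], res.bse[-1], crit, label)

    if family == "gaussian":
        means = np.array([s.mean for s in summaries], dtype=float)
        weights = np.array([float(s.n) for s in summaries])
        df = n_obs - n_par
        if df < 1:
            return _failed(label)
        try:
            res = sm.WLS(means, X, weights=weights).fit()
        except Exception:
            return _failed(label)
        crit = t_dist.ppf(1 - alpha / 2, df)
        return _estimate_from_fit(res.params[-1], res.bse[-1], crit, label)

    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# single period (parallel CRT)
# ---------------------------------------------------------------------------


def fit_single_period(
    summaries: Sequence[ClusterPeriodSummary],
    family: str | None = None,
    alpha: float = 0.05,
) -> EffectEstimate:
    """Parallel-arm (J = 1) analysis.

    Binary: pooled fixed-effects logistic regression of outcome on
    treatment only — the pooled log odds ratio with a Wald z interval
    (clustering is ignored by this model by construction; it is intended
    for settings with negligible between-cluster variation).

    Continuous and count: two-sample comparisons of cluster-level summaries
    with t intervals on K−2 degrees of freedom — cluster means (continuous)
    or exposure-weighted cluster log incidence rates (count), which respect
    the clustering.
    """
    summaries = list(summaries)
    family = family or summaries[0].family
    label = "single_period"
    periods = {s.period for s in summaries}
    if len(periods) != 1:
        raise ValueError("single-period analysis requires exactly one period")
    treat = np.array([s.treatment for s in summaries])
    if treat.min() == treat.max():
        raise ValueError("need both arms represented")

    if family == "binomial":
        succ = np.array([s.events for s in summaries], dtype=float)
        tot = np.array([float(s.n) for s in summaries])
        s1, n1 = succ[treat == 1].sum(), tot[treat == 1].sum()
        s0, n0 = succ[treat == 0].sum(), tot[treat == 0].sum()
        cells = np.array([s1, n1 - s1, s0, n0 - s0])
        if np.any(cells == 0):
            return _failed(label)
        theta = math.log(s1 / (n1 - s1)) - math.log(s0 / (n0 - s0))
        se = math.sqrt(np.sum(1.0 / cells))
        crit = norm.ppf(1 - alpha / 2)
        return _estimate_from_fit(theta, se, crit, label)

    K = len(summaries)
    df = K - 2
    if df < 1:
        return _failed(label)
    X = np.column_stack([np.ones(K), treat])

    if family == "gaussian":
        y = np.array([s.mean for s in summaries], dtype=float)
        res = sm.OLS(y, X).fit()
    elif family == "poisson":
        events = np.array([s.events for s in summaries], dtype=float)
        exposure = np.array([s.exposure for s in summaries], dtype=float)
        if np.any(events == 0):
            return _failed(label)  # log rate undefined for a zero-event cluster
        y = np.log(events / exposure)
        res = sm.WLS(y, X, weights=exposure).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    crit = t_dist.ppf(1 - alpha / 2, df)
    return _estimate_from_fit(res.params[1], res.bse[1], crit, label)


# ---------------------------------------------------------------------------
# estimator registry
# ---------------------------------------------------------------------------

Estimator = Callable[[SimulatedTrial, float], EffectEstimate]

_REGISTRY: dict[str, Estimator] = {}


def register_estimator(name: str, fn: Estimator, *, overwrite: bool = False) -> None:
    """Register a custom analysis function under a string label.

    ``fn`` must map (SimulatedTrial, alpha) to an :class:`EffectEstimate`
    and must return ``converged=False`` on degenerate data instead of
    raising.  Duplicate names are rejected unless ``overwrite=True``.
    """
    if not overwrite and name in _REGISTRY:
        raise ValueError(f"estimator {name!r} is already registered")
    _REGISTRY[name] = fn


def get_estimator(name: str) -> Estimator:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown estimator {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_estimators() -> list[str]:
    return sorted(_REGISTRY)


def _cluster_fixed_est(trial: SimulatedTrial, alpha: float) -> EffectEstimate:
    return fit_cluster_fixed(aggregate(trial), trial.family, False, alpha)


def _cluster_fixed_period_est(trial: SimulatedTrial, alpha: float) -> EffectEstimate:
    return fit_cluster_fixed(aggregate(trial), trial.family, True, alpha)


def _single_period_est(trial: SimulatedTrial, alpha: float) -> EffectEstimate:
    return fit_single_period(aggregate(trial), trial.family, alpha)


for _name, _fn in [
    ("cluster_fixed", _cluster_fixed_est),
    ("fixed.effect.cluster.level", _cluster_fixed_est),
    ("cluster_fixed_period", _cluster_fixed_period_est),
    ("fixed.effect.cluster.level.period", _cluster_fixed_period_est),
    ("single_period", _single_period_est),
]:
    _REGISTRY[_name] = _fn
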