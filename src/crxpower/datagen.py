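"""Simulation of individual-level trial data from cluster-level GLMMs.

All three outcome families share one linear predictor,

    eta[i, j, k] = pi[j] + theta * X[k, j] + b[k],

with fixed (or normally perturbed) period effects ``pi``, a fixed treatment
effect ``theta`` on the link scale, and cluster random intercepts
b[k] ~ N(0, sigma_b^2).  The families differ only in the outcome model:

* Gaussian  — Y = eta + e,   e ~ N(0, sigma_w^2)        (identity link)
* binomial  — Y ~ Bernoulli(expit(eta))                  (logit link)
* Poisson   — Y ~ Poisson(T * exp(eta))                  (log link,
  per-participant at-risk time T as multiplicative exposure)

At-risk times are either a fixed constant or negative-binomial draws with a
(mean, size) parameterization, variance mean + mean^2/size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import expit

from .design import TrialDesign, VarianceSpec

__all__ = [
    "GaussianParams",
    "BinomialParams",
    "PoissonParams",
    "FixedAtRisk",
    "NegBinAtRisk",
    "SimulatedTrial",
    "ClusterPeriodSummary",
    "draw_period_effects",
    "draw_cluster_effects",
    "sample_at_risk_times",
    "simulate_trial",
    "aggregate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixedAtRisk:
    """Constant at-risk time per participant (e.g. 10 days for everyone)."""

    time: float

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("at-risk time must be positive")


@dataclass(frozen=True)
class NegBinAtRisk:
    """Negative-binomial at-risk times with mean ``mean`` and dispersion ``size``.

    Variance is mean + mean**2 / size; smaller ``size`` means more variable
    exposure times.  Zero draws are replaced by 1 (the smallest positive
    support value): a participant with no at-risk time carries no
    information and would break the log-exposure offset.
    """

    mean: float
    size: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.size <= 0:
            raise ValueError("negative-binomial mean and size must be positive")


AtRiskSpec = Union[FixedAtRisk, NegBinAtRisk]


def _as_at_risk(spec) -> AtRiskSpec:
    if isinstance(spec, (FixedAtRisk, NegBinAtRisk)):
        return spec
    if np.isscalar(spec):
        return FixedAtRisk(float(spec))
    seq = tuple(np.asarray(spec, dtype=float).ravel())
    if len(seq) == 1:
        return FixedAtRisk(seq[0])
    if len(seq) == 2:
        return NegBinAtRisk(*seq)
    raise ValueError("at-risk spec must be a scalar time or a (mean, size) pair")


@dataclass(frozen=True)
class GaussianParams:
    """Parameters of the continuous-outcome (linear mixed) model."""

    period_effect: float | np.ndarray
    effect_size: float
    variances: VarianceSpec
    period_var: float = 0.0
    family = "gaussian"

    def __post_init__(self) -> None:
        if self.period_var < 0:
            raise ValueError("period_var must be >= 0")

    @property
    def btw_clust_var(self) -> float:
        return self.variances.btw_clust_var


@dataclass(frozen=True)
class BinomialParams:
    """Parameters of the binary-outcome logistic model (log-odds scale)."""

    period_effect: float | np.ndarray
    effect_size: float
    btw_clust_var: float
    period_var: float = 0.0
    family = "binomial"

    def __post_init__(self) -> None:
        if self.period_var < 0 or self.btw_clust_var < 0:
            raise ValueError("variances must be >= 0")


@dataclass(frozen=True)
class PoissonParams:
    """Parameters of the count-outcome log-linear model (log-rate scale)."""

    period_effect: float | np.ndarray
    effect_size: float
    btw_clust_var: float
    at_risk: AtRiskSpec
    period_var: float = 0.0
    family = "poisson"

    def __post_init__(self) -> None:
        if self.period_var < 0 or self.btw_clust_var < 0:
            raise ValueError("variances must be >= 0")
        object.__setattr__(self, "at_risk", _as_at_risk(self.at_risk))


TrialParams = Union[GaussianParams, BinomialParams, PoissonParams]


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated realization of a trial, at the individual level.

    Flat arrays of length n (total participant-periods): outcome ``y``,
    participant exposure (count family only), and the cluster/period/arm
    index of every observation.  The realized period and cluster effects are
    kept for diagnostics.
    """

    design: TrialDesign
    family: str
    y: np.ndarray = field(repr=False)
    cluster_idx: np.ndarray = field(repr=False)
    period_idx: np.ndarray = field(repr=False)
    treatment: np.ndarray = field(repr=False)
    exposure: np.ndarray | None = field(repr=False)
    realized_period_effects: np.ndarray
    realized_cluster_effects: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = self.design.n_participants
        if len(self.y) != n:
            raise ValueError("outcome length does not match design sizes")
        if self.family == "binomial" and not np.isin(self.y, (0, 1)).all():
            raise ValueError("binary outcomes must be 0/1")
        if self.family == "poisson":
            if np.any(self.y < 0) or not np.issubdtype(self.y.dtype, np.integer):
                raise ValueError("count outcomes must be non-negative integers")


@dataclass(frozen=True)
class ClusterPeriodSummary:
    """Aggregate of one cluster-period cell.

    ``events`` is the event total (count family) or number of successes
    (binary); ``exposure`` is total at-risk time (count) or the denominator
    n (binary/Gaussian); ``mean``/``sd`` are filled for Gaussian outcomes.
    """

    cluster: int
    period: int
    treatment: int
    n: int
    family: str
    events: float | None = None
    exposure: float | None = None
    mean: float | None = None
    sd: float | None = None


def draw_period_effects(
    n_periods: int,
    period_effect,
    period_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Realize the J period effects.

    ``period_effect`` is a scalar (same center every period) or a length-J
    vector of per-period centers.  With ``period_var`` = 0 the centers are
    returned verbatim; otherwise independent N(center, period_var) draws are
    returned, one per period.
    """
    if period_var < 0:
        raise ValueError("period_var must be >= 0")
    base = np.asarray(period_effect, dtype=float)
    if base.ndim == 0:
        base = np.full(n_periods, float(base))
    elif base.shape != (n_periods,):
        raise ValueError(f"period_effect must be scalar or length {n_periods}")
    if period_var == 0:
        return base.copy()
    return base + rng.normal(0.0, np.sqrt(period_var), size=n_periods)


def draw_cluster_effects(
    n_clusters: int, btw_clust_var: float, rng: np.random.Generator
) -> np.ndarray:
    """K iid N(0, σ_b²) cluster random intercepts (all zero when σ_b² = 0)."""
    if btw_clust_var < 0:
        raise ValueError("btw_clust_var must be >= 0")
    if btw_clust_var == 0:
        return np.zeros(n_clusters)
    return rng.normal(0.0, np.sqrt(btw_clust_var), size=n_clusters)


def sample_at_risk_times(at_risk, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-participant at-risk times under a fixed or negative-binomial spec.

    Negative-binomial draws of 0 are replaced by 1 (see
    :class:`NegBinAtRisk`); the replacement rate is logged when non-zero.
    """
    spec = _as_at_risk(at_risk)
    if isinstance(spec, FixedAtRisk):
        return np.full(n, spec.time)
    p = spec.size / (spec.size + spec.mean)
    times = rng.negative_binomial(spec.size, p, size=n).astype(float)
    n_zero = int(np.count_nonzero(times == 0))
    if n_zero:
        logger.debug(
            "replaced %d/%d zero at-risk draws with 1 (mean=%g, size=%g)",
            n_zero, n, spec.mean, spec.size,
        )
        times[times == 0] = 1.0
    return times


def simulate_trial(
    design: TrialDesign, params: TrialParams, rng: np.random.Generator
) -> SimulatedTrial:
    """Simulate one trial realization from the GLMM for ``params.family``."""
    K, J = design.n_clusters, design.n_periods
    pi = draw_period_effects(J, params.period_effect, params.period_var, rng)
    if params.family == "gaussian":
        sigma_b2 = params.variances.btw_clust_var
    else:
        sigma_b2 = params.btw_clust_var
    b = draw_cluster_effects(K, sigma_b2, rng)

    sizes = design.cluster_size.ravel()  # cluster-major: (k0 j0), (k0 j1), ...
    cp_cluster = np.repeat(np.arange(K), J)
    cp_period = np.tile(np.arange(J), K)
    cluster_idx = np.repeat(cp_cluster, sizes)
    period_idx = np.repeat(cp_period, sizes)
    treatment = design.assignment[cluster_idx, period_idx]
    eta = pi[period_idx] + params.effect_size * treatment + b[cluster_idx]

    exposure = None
    if params.family == "gaussian":
        y = eta + rng.normal(0.0, np.sqrt(params.variances.indiv_var), size=eta.size)
    elif params.family == "binomial":
        y = rng.binomial(1, expit(eta)).astype(np.int64)
    elif params.family == "poisson":
        exposure = sample_at_risk_times(params.at_risk, eta.size, rng)
        y = rng.poisson(exposure * np.exp(eta)).astype(np.int64)
    else:  # pragma: no cover - families are fixed by the params classes
        raise ValueError(f"unknown outcome family {params.family!r}")

    return SimulatedTrial(
        design=design,
        family=params.family,
        y=y,
        cluster_idx=cluster_idx,
        period_idx=period_idx,
        treatment=treatment,
        exposure=exposure,
        realized_period_effects=pi,
        realized_cluster_effects=b,
    )


def aggregate(trial: SimulatedTrial) -> list[ClusterPeriodSummary]:
    """Reduce a trial to its K×J cluster-period summaries.

    Aggregation is exact (sums/denominators, not approximations): the
    summaries' event totals reproduce the individual-level totals, which is
    what makes cluster-level analysis loss-free when no individual-level
    covariates enter the model.
    """
    K, J = trial.design.n_clusters, trial.design.n_periods
    key = trial.cluster_idx * J + trial.period_idx
    n_cells = K * J
    n = np.bincount(key, minlength=n_cells)
    ysum = np.bincount(key, weights=trial.y, minlength=n_cells)

    if trial.family == "gaussian":
        ysq = np.bincount(key, weights=trial.y**2, minlength=n_cells)
    if trial.family == "poisson":
        expo = np.bincount(key, weights=trial.exposure, minlength=n_cells)

    out: list[ClusterPeriodSummary] = []
    for k in range(K):
        for j in range(J):
            c = k * J + j
            base = dict(
                cluster=k,
                period=j,
                treatment=int(trial.design.assignment[k, j]),
                n=int(n[c]),
                family=trial.family,
            )
            if trial.family == "poisson":
                out.append(
                    ClusterPeriodSummary(**base, events=ysum[c], exposure=expo[c])
                )
            elif trial.family == "binomial":
                out.append(
                    ClusterPeriodSummary(**base, events=ysum[c], exposure=float(n[c]))
                )
            else:
                mean = ysum[c] / n[c]
                var = (ysq[c] - n[c] * mean**2) / (n[c] - 1) if n[c] > 1 else np.nan
                sd = float(np.sqrt(max(var, 0.0))) if n[c] > 1 else float("nan")
                out.append(
                    ClusterPeriodSummary(
                        **base, mean=float(mean), sd=sd, exposure=float(n[c])
                    )
                )
    return out
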