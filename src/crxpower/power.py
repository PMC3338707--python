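"""Monte-Carlo power engine: simulate, fit, count rejections.

Empirical power is the fraction of simulated trials, generated under a
stated alternative, in which the null hypothesis of no treatment effect is
rejected by the chosen analysis.  The engine also runs parameter sweeps
(power curves) and minimum-cluster searches, stabilizing simulated power
curves with isotonic (pool-adjacent-violators) regression before any
threshold search.

Reproducibility: replicate i of a run with master seed ``s`` draws from
``np.random.SeedSequence(entropy=s, spawn_key=(i,))``, so results are
bit-identical for a given seed regardless of execution order, and sweep
points use independent derived seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.proportion import proportion_confint

from .config import RunConfig, load_config
from .datagen import simulate_trial
from .estimators import Estimator, get_estimator, reject_null

__all__ = [
    "PowerResult",
    "SweepResult",
    "MinClustersResult",
    "HighFailureRateWarning",
    "estimate_power",
    "run_power",
    "power_sweep",
    "min_clusters_for_power",
]


class HighFailureRateWarning(UserWarning):
    """More than 1% of replicates produced a non-converged fit."""


@dataclass(frozen=True)
class PowerResult:
    """Empirical power of one design/parameter configuration.

    ``power`` is rejections over *converged* replicates: a failed fit yields
    no test decision, and counting failures as non-rejections would bias
    power downward.  ``failure_rate`` reports how often that happened so the
    user can judge whether the denominator is trustworthy.  ``mc_ci`` is a
    Wilson 95% interval for the Monte-Carlo uncertainty of ``power``.
    """

    n_sim: int
    n_converged: int
    n_rejected: int
    power: float
    mc_ci: tuple[float, float]
    alpha: float
    master_seed: int
    estimates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_rejected <= self.n_converged <= self.n_sim:
            raise ValueError("inconsistent rejection/convergence tallies")
        if not self.mc_ci[0] <= self.power <= self.mc_ci[1]:
            raise ValueError("Monte-Carlo interval must bracket the power estimate")

    @property
    def failure_rate(self) -> float:
        return 1.0 - self.n_converged / self.n_sim

    def to_dict(self, include_estimates: bool = False) -> dict:
        out = {
            "n_sim": self.n_sim,
            "n_converged": self.n_converged,
            "n_rejected": self.n_rejected,
            "power": self.power,
            "mc_ci": list(self.mc_ci),
            "alpha": self.alpha,
            "failure_rate": self.failure_rate,
            "master_seed": self.master_seed,
        }
        if include_estimates:
            out["estimates"] = self.estimates.tolist()
        return out


def _replicate_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    )


def _point_seed(master_seed: int, index: int) -> int:
    # grid point 0 reuses the master seed, so a length-1 sweep reproduces a
    # plain estimate_power call exactly
    return int((master_seed + 1_000_003 * index) % 2**31)


def estimate_power(
    design,
    params,
    estimator: str | Estimator = "cluster_fixed",
    n_sim: int = 1000,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> PowerResult:
    """Estimate empirical power by simulation.

    Each of the ``n_sim`` replicates simulates a trial from ``params`` on
    ``design``, fits the estimator, and applies the CI-covers-zero rule.
    A :class:`HighFailureRateWarning` is emitted when more than 1% of
    replicates fail to converge; if *all* replicates fail a ``RuntimeError``
    is raised.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    est_fn = get_estimator(estimator) if isinstance(estimator, str) else estimator

    n_converged = n_rejected = 0
    thetas: list[float] = []
    for i in range(n_sim):
        rng = _replicate_rng(master_seed, i)
        trial = simulate_trial(design, params, rng)
        est = est_fn(trial, alpha)
        if est.converged:
            n_converged += 1
            thetas.append(est.theta_hat)
            if reject_null(est, alpha):
                n_rejected += 1
    if n_converged == 0:
        raise RuntimeError(
            f"all {n_sim} replicates failed to produce a converged fit"
        )
    power = n_rejected / n_converged
    lo, hi = proportion_confint(n_rejected, n_converged, alpha=0.05, method="wilson")
    # guard against the Wilson bounds missing the point estimate by an ulp
    # at the boundaries (e.g. 300/300 rejections)
    lo, hi = min(float(lo), power), max(float(hi), power)
    result = PowerResult(
        n_sim=n_sim,
        n_converged=n_converged,
        n_rejected=n_rejected,
        power=power,
        mc_ci=(float(lo), float(hi)),
        alpha=alpha,
        master_seed=master_seed,
        estimates=np.asarray(thetas),
    )
    if result.failure_rate > 0.01:
        warnings.warn(
            f"{n_sim - n_converged}/{n_sim} replicates failed to converge "
            f"(failure rate {result.failure_rate:.1%}); power denominator is "
            "the converged replicates only",
            HighFailureRateWarning,
            stacklevel=2,
        )
    return result


def run_power(config: RunConfig | dict) -> PowerResult:
    """Run :func:`estimate_power` from a validated configuration."""
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    design, params = cfg.build()
    return estimate_power(
        design,
        params,
        estimator=cfg.resolved_estimator(),
        n_sim=cfg.n_sim,
        alpha=cfg.alpha,
        master_seed=cfg.master_seed,
    )


_MONOTONE_PARAMS = {"n_clusters", "cluster_size"}


@dataclass(frozen=True)
class SweepResult:
    """Power evaluated along a one-parameter grid.

    ``results[i]`` is the :class:`PowerResult` for ``grid[i]`` (None when
    that point errored; the message is kept in ``errors``).  ``smoothed``
    holds isotonic-regression power values when the varied parameter is a
    sample-size-like quantity (cluster count or cluster size), for which
    true power is monotone and the smoother is assumption-light.
    """

    param_name: str
    grid: tuple
    results: tuple
    smoothed: tuple | None
    errors: dict[int, str]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, (g, r) in enumerate(zip(self.grid, self.results)):
            row = {"grid_value": g}
            if r is None:
                row.update(power=np.nan, ci_low=np.nan, ci_high=np.nan,
                           n_converged=0, failure_rate=np.nan)
            else:
                row.update(power=r.power, ci_low=r.mc_ci[0], ci_high=r.mc_ci[1],
                           n_converged=r.n_converged, failure_rate=r.failure_rate)
            if self.smoothed is not None:
                row["smoothed_power"] = self.smoothed[i]
            rows.append(row)
        return pd.DataFrame(rows)


def _smooth(grid, results) -> tuple | None:
    ok = [i for i, r in enumerate(results) if r is not None]
    if len(ok) < 2:
        return None
    x = np.asarray([grid[i] for i in ok], dtype=float)
    y = np.asarray([results[i].power for i in ok])
    w = np.asarray([results[i].n_converged for i in ok], dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(x, y, sample_weight=w)
    smoothed = [None] * len(grid)
    for i, v in zip(ok, fitted):
        smoothed[i] = float(v)
    return tuple(smoothed)


def power_sweep(
    base_config: RunConfig | dict,
    param_name: str,
    grid,
    n_sim: int | None = None,
    master_seed: int | None = None,
) -> SweepResult:
    """Evaluate power along a grid of one configuration parameter.

    Grid points run on independent derived seeds; a point whose
    configuration is invalid (e.g. an odd cluster count in a balanced
    crossover) records its error and the sweep continues.
    """
    cfg = base_config if isinstance(base_config, RunConfig) else load_config(base_config)
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    seed0 = cfg.master_seed if master_seed is None else master_seed

    results: list[PowerResult | None] = []
    errors: dict[int, str] = {}
    for i, value in enumerate(grid):
        overrides = {param_name: value, "master_seed": _point_seed(seed0, i)}
        if n_sim is not None:
            overrides["n_sim"] = n_sim
        try:
            results.append(run_power(cfg.replace(**overrides)))
        except Exception as exc:  # per-point failure must not abort the sweep
            errors[i] = str(exc)
            results.append(None)
    smoothed = _smooth(grid, results) if param_name in _MONOTONE_PARAMS else None
    return SweepResult(
        param_name=param_name,
        grid=tuple(grid),
        results=tuple(results),
        smoothed=smoothed,
        errors=errors,
    )


@dataclass(frozen=True)
class MinClustersResult:
    """Outcome of a minimum-cluster search.

    ``k_star`` is the smallest grid cluster count whose isotonic-smoothed
    power reaches the target, or None when the grid was exhausted
    (``reached`` False); no extrapolation beyond the grid is attempted.
    """

    target_power: float
    k_star: int | None
    reached: bool
    sweep: SweepResult


def min_clusters_for_power(
    base_config: RunConfig | dict,
    target_power: float,
    k_grid,
    n_sim: int | None = None,
    master_seed: int | None = None,
) -> MinClustersResult:
    """Smallest cluster count on a grid achieving a target smoothed power."""
    if not 0 <= target_power < 1:
        raise ValueError("target power must lie in [0, 1)")
    sweep = power_sweep(base_config, "n_clusters", k_grid, n_sim, master_seed)
    smoothed = sweep.smoothed
    if smoothed is None:  # single usable point: fall back to the raw power
        smoothed = tuple(
            None if r is None else r.power for r in sweep.results
        )
    for k, p in zip(sweep.grid, smoothed):
        if p is not None and p >= target_power:
            return MinClustersResult(target_power, int(k), True, sweep)
    return MinClustersResult(target_power, None, False, sweep)
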