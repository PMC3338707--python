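"""Trial geometry, treatment allocation and variance-component bookkeeping.

A cluster-randomized trial (CRT) randomizes intact groups (clusters) of
participants to study arms; a cluster-randomized crossover trial (CRXO)
additionally crosses every cluster over between treatment and control in
successive study periods, so that inference rests on within-cluster
contrasts.  This module defines the design objects shared by the data
generator, the estimators and the power engine:

* :class:`TrialDesign` — K clusters × J periods, cluster-period sizes and
  the binary treatment-assignment matrix ``X[k, j]``.
* :class:`VarianceSpec` — the (σ_b², σ_w², ICC) triple for continuous
  outcomes, where ICC = σ_b² / (σ_b² + σ_w²).
* helpers to build canonical designs, randomize the cluster-to-sequence
  allocation, complete a partially specified variance triple, and calibrate
  a between-cluster variance against a rate ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "TrialDesign",
    "VarianceSpec",
    "make_design",
    "randomize_assignment",
    "complete_variances",
    "calibrate_btw_clust_var",
]

_ICC_TOL = 1e-12


@dataclass(frozen=True)
class TrialDesign:
    """Geometry and treatment allocation of a (crossover) cluster trial.

    Parameters
    ----------
    n_clusters
        Number of clusters K (≥ 2; a between- or within-cluster contrast
        needs at least two clusters).
    n_periods
        Number of study periods J (≥ 1).  J = 1 is a parallel-arm CRT;
        J ≥ 2 is a crossover in which every cluster sees both conditions.
    cluster_size
        K×J integer array of participants per cluster-period.
    assignment
        K×J binary matrix; ``assignment[k, j] = 1`` when cluster k is on
        treatment during period j.
    """

    n_clusters: int
    n_periods: int
    cluster_size: np.ndarray = field(repr=False)
    assignment: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        K, J = self.n_clusters, self.n_periods
        if K < 2:
            raise ValueError("need at least 2 clusters for a cluster-level contrast")
        if J < 1:
            raise ValueError("need at least 1 study period")
        sizes = np.asarray(self.cluster_size, dtype=int)
        assign = np.asarray(self.assignment, dtype=int)
        if sizes.shape != (K, J):
            raise ValueError(f"cluster_size must have shape {(K, J)}, got {sizes.shape}")
        if assign.shape != (K, J):
            raise ValueError(f"assignment must have shape {(K, J)}, got {assign.shape}")
        if np.any(sizes < 1):
            raise ValueError("all cluster-period sizes must be >= 1")
        if not np.isin(assign, (0, 1)).all():
            raise ValueError("assignment entries must be 0 or 1")
        if J == 1:
            n_treated = int(assign.sum())
            if n_treated not in (K // 2, (K + 1) // 2):
                raise ValueError(
                    "single-period design must split clusters (near-)evenly "
                    f"between arms; got {n_treated} of {K} treated"
                )
        else:
            rows = assign.sum(axis=1)
            if np.any(rows == 0) or np.any(rows == J):
                raise ValueError(
                    "crossover design: every cluster needs at least one treated "
                    "and one control period"
                )
        object.__setattr__(self, "cluster_size", sizes)
        object.__setattr__(self, "assignment", assign)

    @property
    def n_participants(self) -> int:
        """Total number of participant-period observations."""
        return int(self.cluster_size.sum())

    def sequences(self) -> list[tuple[int, ...]]:
        """Treatment sequence of each cluster, as a list of J-tuples."""
        return [tuple(row) for row in self.assignment]


def make_design(n_clusters: int, n_periods: int, cluster_size) -> TrialDesign:
    """Build a canonical balanced design.

    The canonical allocation is deterministic: for J = 1 the first ⌈K/2⌉
    clusters are treated; for J ≥ 2 the first K/2 clusters follow the
    treatment-first alternating sequence (1, 0, 1, …) and the remainder its
    complement (0, 1, 0, …), so every cluster crosses over each period.
    Use :func:`randomize_assignment` to permute cluster labels.

    ``cluster_size`` may be a scalar (applied to every cluster-period) or a
    K×J array.

    Raises
    ------
    ValueError
        If K < 2, sizes are non-positive, or K is odd for a J ≥ 2 balanced
        crossover (the two sequences could not be evenly filled).
    """
    K, J = int(n_clusters), int(n_periods)
    if K < 2:
        raise ValueError("n_clusters must be >= 2")
    if J < 1:
        raise ValueError("n_periods must be >= 1")
    sizes = np.asarray(cluster_size, dtype=int)
    if sizes.ndim == 0:
        sizes = np.full((K, J), int(sizes))
    elif sizes.shape != (K, J):
        raise ValueError(f"cluster_size must be scalar or shape {(K, J)}")
    if J == 1:
        n_treat = (K + 1) // 2
        assign = np.zeros((K, 1), dtype=int)
        assign[:n_treat, 0] = 1
    else:
        if K % 2:
            raise ValueError(
                "balanced crossover needs an even number of clusters "
                f"(got K={K} with J={J})"
            )
        seq_a = np.arange(J) % 2 == 0  # treatment first
        assign = np.empty((K, J), dtype=int)
        assign[: K // 2] = seq_a.astype(int)
        assign[K // 2 :] = 1 - seq_a.astype(int)
    return TrialDesign(K, J, sizes, assign)


def randomize_assignment(design: TrialDesign, rng: np.random.Generator) -> TrialDesign:
    """Randomly permute which cluster gets which treatment sequence.

    The multiset of sequences (and the per-sequence cluster counts) is
    preserved for every seed; only the cluster-to-sequence labels change.
    Cluster-period sizes stay attached to their cluster labels.
    """
    perm = rng.permutation(design.n_clusters)
    return TrialDesign(
        design.n_clusters,
        design.n_periods,
        design.cluster_size,
        design.assignment[perm],
    )


@dataclass(frozen=True)
class VarianceSpec:
    """Completed variance triple for the continuous-outcome model.

    ``icc = btw_clust_var / (btw_clust_var + indiv_var)`` holds to 1e-12.
    """

    btw_clust_var: float
    indiv_var: float
    icc: float

    def __post_init__(self) -> None:
        if self.btw_clust_var < 0:
            raise ValueError("between-cluster variance must be >= 0")
        if self.indiv_var <= 0:
            raise ValueError("individual-level variance must be > 0")
        if not 0 <= self.icc < 1:
            raise ValueError("ICC must lie in [0, 1)")
        implied = self.btw_clust_var / (self.btw_clust_var + self.indiv_var)
        if abs(implied - self.icc) > 1e-9:
            raise ValueError(
                f"inconsistent variance triple: ICC={self.icc} but "
                f"sigma_b^2/(sigma_b^2+sigma_w^2)={implied}"
            )


def complete_variances(
    btw_clust_var: float | None = None,
    indiv_var: float | None = None,
    icc: float | None = None,
) -> VarianceSpec:
    """Complete the (σ_b², σ_w², ICC) triple from any two of its members.

    Exactly two of the three arguments must be given (all three are
    accepted only if mutually consistent).  The identity
    ICC = σ_b² / (σ_b² + σ_w²) determines the third member.
    """
    given = [v is not None for v in (btw_clust_var, indiv_var, icc)]
    if sum(given) < 2:
        raise ValueError(
            "need at least two of btw_clust_var, indiv_var, icc to complete "
            "the variance specification"
        )
    if icc is not None and not 0 <= icc < 1:
        raise ValueError("ICC must lie in [0, 1)")
    if sum(given) == 3:
        return VarianceSpec(float(btw_clust_var), float(indiv_var), float(icc))
    if icc is None:
        if btw_clust_var < 0 or indiv_var <= 0:
            raise ValueError("variances must be non-negative (indiv_var positive)")
        icc = btw_clust_var / (btw_clust_var + indiv_var)
    elif indiv_var is None:
        if icc == 0:
            if btw_clust_var != 0:
                raise ValueError("ICC=0 requires btw_clust_var=0; indiv_var is then free")
            raise ValueError("cannot infer indiv_var from ICC=0 and btw_clust_var=0")
        indiv_var = btw_clust_var * (1 - icc) / icc
    else:  # btw_clust_var is None
        btw_clust_var = icc * indiv_var / (1 - icc)
    return VarianceSpec(float(btw_clust_var), float(indiv_var), float(icc))


def calibrate_btw_clust_var(
    baseline_log_rate: float,
    rate_ceiling: float,
    prob: float = 0.9,
    grid=None,
) -> float:
    """Largest grid value of σ_b² keeping most clusters below a rate ceiling.

    With lognormal cluster rates exp(baseline_log_rate + b), b ~ N(0, σ_b²),
    the fraction of clusters below ``rate_ceiling`` is
    Φ((log rate_ceiling − baseline_log_rate)/σ_b).  Returns the largest σ_b²
    on the grid (default 0.1, 0.2, …, 1.0) for which that fraction is at
    least ``prob`` — the variance-elicitation rule used when only a plausible
    upper bound on cluster-level rates is available.
    """
    if grid is None:
        grid = np.round(np.arange(0.1, 1.05, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly increasing")
    gap = math.log(rate_ceiling) - baseline_log_rate
    if gap <= 0:
        raise ValueError("rate ceiling must exceed the baseline rate")
    frac_below = norm.cdf(gap / np.sqrt(grid))
    ok = frac_below >= prob
    if not ok.any():
        raise ValueError("no grid value satisfies the rate-ceiling constraint")
    return float(grid[ok][-1])
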