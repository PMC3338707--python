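"""Estimators: closed-form oracles, invariances and failure handling."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

import crxpower as cp
from crxpower.datagen import ClusterPeriodSummary, aggregate
from crxpower.datasets import crossover_count_table, crude_irr, table_summaries
from crxpower.estimators import _REGISTRY


def count_cell(cluster, period, treatment, events, exposure, n=1):
    return ClusterPeriodSummary(
        cluster=cluster, period=period, treatment=treatment, n=n,
        family="poisson", events=float(events), exposure=float(exposure),
    )


def random_count_summaries(rng, n_clusters, equal_exposure=True):
    """Small random crossover count dataset with no degenerate cells."""
    out = []
    for k in range(n_clusters):
        expo = 10.0 if equal_exposure else float(rng.uniform(5, 20))
        treated_first = k % 2 == 0
        for j in range(2):
            treated = int(j == 0) if treated_first else int(j == 1)
            events = int(rng.poisson(8)) + 1  # keep every cell positive
            out.append(count_cell(k, j, treated, events, expo))
    return out


def brute_force_poisson_theta(summaries):
    """Independent oracle: maximize the fixed-effects Poisson log-likelihood
    over (gamma_1..gamma_K, theta) by generic numerical optimization."""
    clusters = sorted({s.cluster for s in summaries})
    cmap = {c: i for i, c in enumerate(clusters)}
    y = np.array([s.events for s in summaries])
    expo = np.array([s.exposure for s in summaries])
    treat = np.array([s.treatment for s in summaries], dtype=float)
    cidx = np.array([cmap[s.cluster] for s in summaries])
    K = len(clusters)

    def negll(par):
        gamma, theta = par[:K], par[K]
        eta = np.log(expo) + gamma[cidx] + theta * treat
        return float(np.sum(np.exp(eta) - y * eta))

    res = minimize(negll, np.zeros(K + 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    return float(res.x[K])


class TestClusterFixedPoisson:
    def test_bundled_table_matches_closed_form(self):
        est = cp.fit_cluster_fixed(table_summaries(), "poisson")
        assert est.converged
        assert est.theta_hat == pytest.approx(math.log(68 / 106), abs=1e-6)

    def test_bundled_table_crude_irr_column(self):
        irr = crude_irr(crossover_count_table()).round(2)
        assert irr.tolist() == [0.71, 0.41, 0.38, 0.67, 0.45, 0.35, 1.25, 1.0, 1.0, 0.89]

    def test_perfect_symmetry_gives_zero_effect(self):
        cells = [
            count_cell(0, 0, 1, 7, 10), count_cell(0, 1, 0, 7, 10),
            count_cell(1, 0, 0, 7, 10), count_cell(1, 1, 1, 7, 10),
        ]
        est = cp.fit_cluster_fixed(cells, "poisson")
        assert est.theta_hat == pytest.approx(0.0, abs=1e-8)
        assert est.ci_low < 0 < est.ci_high

    def test_single_period_not_identifiable(self):
        cells = [count_cell(k, 0, k % 2, 5, 10) for k in range(4)]
        with pytest.raises(ValueError):
            cp.fit_cluster_fixed(cells, "poisson")

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_brute_force_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        cells = random_count_summaries(rng, int(rng.integers(2, 5)),
                                       equal_exposure=bool(seed % 2))
        est = cp.fit_cluster_fixed(cells, "poisson")
        assert est.converged
        assert est.theta_hat == pytest.approx(brute_force_poisson_theta(cells), abs=1e-6)

    def test_equal_exposure_closed_form(self):
        rng = np.random.default_rng(1)
        cells = random_count_summaries(rng, 5, equal_exposure=True)
        treated = sum(s.events for s in cells if s.treatment == 1)
        control = sum(s.events for s in cells if s.treatment == 0)
        est = cp.fit_cluster_fixed(cells, "poisson")
        assert est.theta_hat == pytest.approx(math.log(treated / control), abs=1e-8)

    def test_zero_event_cluster_fails_without_raising(self):
        cells = [
            count_cell(0, 0, 1, 0, 10), count_cell(0, 1, 0, 0, 10),
            count_cell(1, 0, 0, 9, 10), count_cell(1, 1, 1, 7, 10),
        ]
        est = cp.fit_cluster_fixed(cells, "poisson")
        assert not est.converged
        assert math.isnan(est.theta_hat)

    def test_cluster_relabelling_invariance(self):
        rng = np.random.default_rng(7)
        cells = random_count_summaries(rng, 4)
        relabel = {0: 3, 1: 0, 2: 2, 3: 1}
        shuffled = [
            ClusterPeriodSummary(
                cluster=relabel[s.cluster], period=s.period, treatment=s.treatment,
                n=s.n, family=s.family, events=s.events, exposure=s.exposure,
            )
            for s in cells
        ]
        a = cp.fit_cluster_fixed(cells, "poisson")
        b = cp.fit_cluster_fixed(shuffled, "poisson")
        assert a.theta_hat == pytest.approx(b.theta_hat, abs=1e-10)

    def test_period_swap_invariance_with_period_effect(self):
        rng = np.random.default_rng(8)
        cells = random_count_summaries(rng, 4)
        swapped = [
            ClusterPeriodSummary(
                cluster=s.cluster, period=1 - s.period, treatment=s.treatment,
                n=s.n, family=s.family, events=s.events, exposure=s.exposure,
            )
            for s in cells
        ]
        a = cp.fit_cluster_fixed(cells, "poisson", include_period_effect=True)
        b = cp.fit_cluster_fixed(swapped, "poisson", include_period_effect=True)
        assert a.theta_hat == pytest.approx(b.theta_hat, abs=1e-10)

    def test_ci_width_scales_with_root_k(self):
        """Wald width ~ 1/sqrt(K) at fixed per-cluster information."""
        widths = {}
        for K in (10, 40, 160):
            design = cp.make_design(K, 2, 50)
            params = cp.PoissonParams(math.log(0.02), 0.0, 0.0, 10)
            w = []
            for i in range(20):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=K, spawn_key=(i,))
                )
                est = cp.fit_cluster_fixed(
                    aggregate(cp.simulate_trial(design, params, rng)), "poisson"
                )
                w.append(est.ci_high - est.ci_low)
            widths[K] = np.mean(w)
        assert widths[10] / widths[40] == pytest.approx(2.0, rel=0.15)
        assert widths[40] / widths[160] == pytest.approx(2.0, rel=0.15)


class TestClusterFixedOtherFamilies:
    def _binomial_cells(self, succ):
        cells = []
        for k, (s0, s1) in enumerate(succ):
            cells.append(ClusterPeriodSummary(k, 0, k % 2, 100, "binomial",
                                              events=float(s1 if k % 2 else s0)))
            cells.append(ClusterPeriodSummary(k, 1, 1 - k % 2, 100, "binomial",
                                              events=float(s0 if k % 2 else s1)))
        return cells

    def test_binomial_symmetry(self):
        est = cp.fit_cluster_fixed(
            self._binomial_cells([(40, 40), (55, 55)]), "binomial"
        )
        assert est.converged
        assert est.theta_hat == pytest.approx(0.0, abs=1e-8)

    def test_binomial_all_success_cluster_fails(self):
        est = cp.fit_cluster_fixed(
            self._binomial_cells([(100, 100), (55, 50)]), "binomial"
        )
        assert not est.converged

    def test_gaussian_recovers_shift(self):
        cells = []
        for k in range(4):
            for j in range(2):
                treated = int(j == 0) if k % 2 == 0 else int(j == 1)
                mean = 1.0 + 0.5 * treated + 0.1 * k
                cells.append(ClusterPeriodSummary(k, j, treated, 25, "gaussian",
                                                  mean=mean, sd=1.0, exposure=25.0))
        est = cp.fit_cluster_fixed(cells, "gaussian")
        assert est.theta_hat == pytest.approx(0.5, abs=1e-8)


class TestSinglePeriod:
    def test_pooled_logistic_closed_form(self):
        cells = [
            ClusterPeriodSummary(0, 0, 0, 100, "binomial", events=50.0),
            ClusterPeriodSummary(1, 0, 0, 100, "binomial", events=50.0),
            ClusterPeriodSummary(2, 0, 1, 100, "binomial", events=60.0),
            ClusterPeriodSummary(3, 0, 1, 100, "binomial", events=60.0),
        ]
        est = cp.fit_single_period(cells, "binomial")
        assert est.theta_hat == pytest.approx(math.log(1.5), abs=1e-10)
        # dual route: the closed form is the pooled-logistic MLE
        y = np.array([[120.0, 80.0], [100.0, 100.0]])
        X = np.array([[1.0, 1.0], [1.0, 0.0]])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert est.theta_hat == pytest.approx(glm.params[1], abs=1e-8)
        assert est.se == pytest.approx(glm.bse[1], abs=1e-8)

    def test_binomial_zero_cell_fails(self):
        cells = [
            ClusterPeriodSummary(0, 0, 0, 50, "binomial", events=0.0),
            ClusterPeriodSummary(1, 0, 1, 50, "binomial", events=20.0),
        ]
        assert not cp.fit_single_period(cells, "binomial").converged

    def test_gaussian_equal_means_symmetric_interval(self):
        cells = [
            ClusterPeriodSummary(k, 0, int(k >= 2), 10, "gaussian", mean=2.0, sd=1.0)
            for k in range(4)
        ]
        est = cp.fit_single_period(cells, "gaussian")
        assert est.theta_hat == pytest.approx(0.0, abs=1e-10)
        assert est.ci_low == pytest.approx(-est.ci_high, abs=1e-10)

    def test_poisson_identical_arms_zero_effect(self):
        cells = [
            count_cell(0, 0, 0, 12, 100), count_cell(1, 0, 0, 8, 100),
            count_cell(2, 0, 1, 12, 100), count_cell(3, 0, 1, 8, 100),
        ]
        est = cp.fit_single_period(cells, "poisson")
        assert est.theta_hat == pytest.approx(0.0, abs=1e-10)

    def test_poisson_zero_event_cluster_fails(self):
        cells = [
            count_cell(0, 0, 0, 0, 100), count_cell(1, 0, 0, 8, 100),
            count_cell(2, 0, 1, 12, 100), count_cell(3, 0, 1, 8, 100),
        ]
        assert not cp.fit_single_period(cells, "poisson").converged

    def test_crossover_data_rejected(self):
        cells = [count_cell(0, j, j, 5, 10) for j in range(2)]
        with pytest.raises(ValueError):
            cp.fit_single_period(cells, "poisson")


class TestRejectionRule:
    def test_interval_excluding_zero_rejects(self):
        est = cp.EffectEstimate(-0.3, 0.1, -0.5, -0.1, True, "x")
        assert cp.reject_null(est)

    def test_interval_covering_zero_fails_to_reject(self):
        est = cp.EffectEstimate(0.05, 0.1, -0.1, 0.2, True, "x")
        assert not cp.reject_null(est)

    def test_boundary_endpoint_counts_as_covering(self):
        est = cp.EffectEstimate(-0.1, 0.06, -0.2, 0.0, True, "x")
        assert not cp.reject_null(est)

    def test_non_converged_estimate_rejected(self):
        nan = float("nan")
        est = cp.EffectEstimate(nan, nan, nan, nan, False, "x")
        with pytest.raises(ValueError):
            cp.reject_null(est)


class TestRegistry:
    def test_duplicate_name_rejected(self):
        with pytest.raises(ValueError):
            cp.register_estimator("cluster_fixed", lambda t, a: None)

    def test_alias_runs_identically(self, example_d_crxo):
        design, params = example_d_crxo
        name = "cluster_fixed_alias_test"
        _REGISTRY.pop(name, None)
        cp.register_estimator(name, cp.get_estimator("cluster_fixed"))
        a = cp.estimate_power(design, params, "cluster_fixed", n_sim=50, master_seed=4)
        b = cp.estimate_power(design, params, name, n_sim=50, master_seed=4)
        assert a.power == b.power
        assert np.array_equal(a.estimates, b.estimates)

    def test_degenerate_custom_estimators_pin_power(self, example_d_crxo):
        design, params = example_d_crxo

        def always_reject(trial, alpha):
            return cp.EffectEstimate(1.0, 0.1, 0.8, 1.2, True, "always")

        def never_reject(trial, alpha):
            return cp.EffectEstimate(0.0, 10.0, -1e9, 1e9, True, "never")

        hi = cp.estimate_power(design, params, always_reject, n_sim=30, master_seed=0)
        lo = cp.estimate_power(design, params, never_reject, n_sim=30, master_seed=0)
        assert hi.power == 1.0
        assert lo.power == 0.0
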