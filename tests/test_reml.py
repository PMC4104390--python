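"""REML fitting against independent likelihood oracles and model invariants."""

import numpy as np
import pytest

from snpherit import (
    RemlOptions,
    compute_grm,
    fit_reml,
    h2_observed,
    restricted_log_likelihood,
    simulate_cohort,
    simulate_null_cohort,
    SimulationConfig,
)

from conftest import make_genotypes


def dense_reml_loglik(y, X, A, sg, se):
    """From-scratch dense evaluation of the restricted likelihood (the oracle:
    plain numpy inverses and slogdet, no shared code with the fitter)."""
    n = len(y)
    V = sg * A + se * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.inv(XtVinvX) @ X.T @ Vinv
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVinvX)[1]
                   + float(y @ P @ y))


def toy_instance(n, m, seed, h2=0.5):
    """Small genotype-based instance with a continuous phenotype of known h2."""
    rng = np.random.default_rng(seed)
    g = make_genotypes(n, m, seed=seed)
    grm = compute_grm(g, maf_min=0.0)
    lam, U = np.linalg.eigh(grm.values)
    lam = np.clip(lam, 0, None)
    gval = U @ (np.sqrt(h2 * lam) * rng.standard_normal(n))
    y = gval + rng.normal(0, np.sqrt(1 - h2), n)
    return y, grm


class TestRestrictedLikelihood:
    def test_matches_independent_dense_formula(self):
        rng = np.random.default_rng(17)
        w = rng.normal(size=(4, 6))
        A = w @ w.T / 6
        y = rng.normal(size=4)
        X = np.ones((4, 1))
        ours = restricted_log_likelihood(y, None, A, [0.5], 0.5)
        oracle = dense_reml_loglik(y, X, A, 0.5, 0.5)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_identifiability_ridge_with_identity_grm(self):
        """With A = I the likelihood depends only on sigma2_g + sigma2_e."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        A = np.eye(12)
        values = [restricted_log_likelihood(y, None, A, [sg], 1.0 - sg)
                  for sg in (0.2, 0.5, 0.8)]
        assert np.ptp(values) < 1e-9

    def test_singular_v_rejected(self):
        y = np.zeros(5) + [1, 0, 1, 0, 1]
        with pytest.raises(ValueError, match="positive definite"):
            restricted_log_likelihood(y, None, np.eye(5), [0.0], 0.0)


class TestFitReml:
    def test_scale_equivariance(self):
        y, grm = toy_instance(60, 200, seed=5)
        fit1 = fit_reml(y, grm.values)
        fit2 = fit_reml(2.0 * y, grm.values)
        assert fit2.sigma2_g[0] == pytest.approx(4 * fit1.sigma2_g[0], rel=1e-3)
        assert fit2.sigma2_e == pytest.approx(4 * fit1.sigma2_e, rel=1e-3)
        assert fit2.h2_obs_total == pytest.approx(fit1.h2_obs_total, abs=1e-5)

    def test_null_phenotype_near_zero(self):
        cohort = simulate_null_cohort(50, 150, {"1": 1000}, seed=9)
        grm = compute_grm(cohort.genotypes)
        fit = fit_reml(cohort.phenotype, grm)
        assert fit.h2_obs_total <= max(2 * fit.h2_se_total, 0.25)

    def test_grid_search_oracle_small_instance(self):
        """AI-REML optimum vs a two-stage 200x200 grid maximization of the
        public restricted likelihood on an n=40 instance."""
        y, grm = toy_instance(40, 120, seed=23)
        fit = fit_reml(y, grm.values)
        vp = np.var(y, ddof=1)

        def loglik_or_neg_inf(sg, se):
            try:
                return restricted_log_likelihood(y, None, grm.values, [sg], se)
            except ValueError:  # V not positive definite at this grid point
                return -np.inf

        grid = np.linspace(1e-4, 2 * vp, 200)
        best = max(((sg, se) for sg in grid for se in grid),
                   key=lambda t: loglik_or_neg_inf(*t))
        span = grid[1] - grid[0]
        fine_g = np.linspace(max(best[0] - span, 1e-6), best[0] + span, 200)
        fine_e = np.linspace(max(best[1] - span, 1e-6), best[1] + span, 200)
        best = max(((sg, se) for sg in fine_g for se in fine_e),
                   key=lambda t: loglik_or_neg_inf(*t))
        assert fit.sigma2_g[0] == pytest.approx(best[0], abs=1e-3)
        assert fit.sigma2_e == pytest.approx(best[1], abs=1e-3)

    def test_em_and_ai_agree(self):
        y, grm = toy_instance(50, 150, seed=31)
        fit_ai = fit_reml(y, grm.values)
        fit_em = fit_reml(y, grm.values,
                          options=RemlOptions(algorithm="em", max_iter=2000,
                                              loglik_tol=1e-12))
        assert fit_em.sigma2_g[0] == pytest.approx(fit_ai.sigma2_g[0], abs=1e-4)
        assert fit_em.sigma2_e == pytest.approx(fit_ai.sigma2_e, abs=1e-4)
        assert fit_em.n_iter >= fit_ai.n_iter

    def test_permutation_invariance(self):
        y, grm = toy_instance(35, 100, seed=41)
        fit = fit_reml(y, grm.values)
        rng = np.random.default_rng(0)
        perm = rng.permutation(35)
        fit_p = fit_reml(y[perm], grm.values[np.ix_(perm, perm)])
        assert fit_p.sigma2_g[0] == pytest.approx(fit.sigma2_g[0], abs=1e-8)
        assert fit_p.sigma2_e == pytest.approx(fit.sigma2_e, abs=1e-8)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-8)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_unconstrained_null_negative_half_the_time(self):
        """Without the constraint, null-trait genetic variances land below 0
        in roughly half the seeds — the pile-up at 0 under the constraint is
        produced by the clamp, not by the optimizer."""
        negatives = 0
        n_seeds = 16
        for s in range(n_seeds):
            cohort = simulate_null_cohort(40, 120, {"1": 600}, seed=100 + s)
            grm = compute_grm(cohort.genotypes)
            fit = fit_reml(cohort.phenotype, grm,
                           options=RemlOptions(constrain=False))
            negatives += fit.sigma2_g[0] < 0
        assert 0.2 <= negatives / n_seeds <= 0.8

    def test_two_component_fit_attributes_signal_to_causal_chromosome(self):
        """Joint chr-6 + rest fit on cohorts whose causal SNPs all sit on one
        chromosome: component 1 recovers the signal, component 2 stays small."""
        h2_focal, h2_rest = [], []
        for s in range(6):
            cfg = SimulationConfig(n_snps_per_chrom={"6": 400, "2": 600},
                                   h2_true=0.5, prevalence_K=0.25, n_cases=90,
                                   causal_spec={"6": (40, 0.5)}, seed=700 + s)
            cohort = simulate_cohort(cfg)
            g6 = compute_grm(cohort.genotypes, chroms=["6"])
            gr = compute_grm(cohort.genotypes, exclude_chroms=["6"])
            fit = fit_reml(cohort.phenotype, [g6, gr])
            h2_focal.append(fit.h2_obs[0])
            h2_rest.append(fit.h2_obs[1])
        assert np.mean(h2_focal) > 3 * np.std(h2_focal, ddof=1) / np.sqrt(6)
        assert np.mean(h2_rest) < np.mean(h2_focal) / 2
        assert np.mean(h2_rest) < 0.1

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            fit_reml(np.array([1.0, 0.0]), np.eye(2))


class TestH2Observed:
    def test_equal_components_give_half(self):
        y, grm = toy_instance(60, 200, seed=55)
        fit = fit_reml(y, grm.values)
        fit.sigma2_g[0] = fit.sigma2_e = 0.3
        h2, h2_total, _, _ = h2_observed(fit)
        assert h2[0] == pytest.approx(0.5) and h2_total == pytest.approx(0.5)

    def test_null_estimate_sits_on_boundary(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=80)  # no genetic signal at all
        w = rng.normal(size=(80, 300))
        A = w @ w.T / 300
        np.fill_diagonal(A, 1.0)
        fit = fit_reml(y, A)
        if fit.h2_obs_total < 1e-4:
            assert fit.boundary[0]

    def test_delta_method_se_matches_parametric_bootstrap(self):
        """Delta-method SE of h2 vs the SD of 200 parametric-bootstrap
        refits at the fitted parameters (within 25% relative error)."""
        y, grm = toy_instance(70, 250, seed=77, h2=0.6)
        fit = fit_reml(y, grm)
        lam, U = np.linalg.eigh(grm.values)
        lam = np.clip(lam, 0, None)
        rng = np.random.default_rng(123)
        draws = []
        for _ in range(200):
            d = fit.sigma2_g[0] * lam + fit.sigma2_e
            yb = fit.beta[0] + U @ (np.sqrt(d) * rng.standard_normal(70))
            draws.append(fit_reml(yb, grm.values).h2_obs_total)
        boot_sd = np.std(draws, ddof=1)
        assert fit.h2_se_total == pytest.approx(boot_sd, rel=0.25)
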