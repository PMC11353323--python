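"""The MMMC Gaussian likelihood against a dense multivariate-normal oracle,
empirical Bayes predictions, and degenerate-structure behaviour."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from mmhurdle import GeneratorConfig, generate
from mmhurdle.lmm import MMMCDesign, build_design
from mmhurdle.membership import build_membership_table, derive_hcpm_weights
from mmhurdle.vpc import VarianceComponents


def _random_instance(rng, n=30, n_mun=3, n_hcp=4, n_hcpm=3, p=2):
    """A small random MMMC design with row-normalised weight blocks."""
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p else np.empty((n, 0))
    z = rng.normal(size=n)

    def norm_rows(M):
        return M / M.sum(axis=1, keepdims=True)

    Z2 = np.zeros((n, n_mun))
    Z2[np.arange(n), rng.integers(0, n_mun, n)] = 1.0
    W = np.zeros((n, n_hcp))
    for i in range(n):
        k = rng.integers(1, min(3, n_hcp) + 1)
        cols = rng.choice(n_hcp, size=k, replace=False)
        W[i, cols] = rng.dirichlet(np.ones(k))
    O = np.zeros((n, n_hcpm))
    for i in range(n):
        k = rng.integers(1, min(2, n_hcpm) + 1)
        cols = rng.choice(n_hcpm, size=k, replace=False)
        O[i, cols] = rng.dirichlet(np.ones(k))
    blocks = {
        "ind_mun": sp.csr_matrix(Z2),
        "hcp": sp.csr_matrix(W),
        "hcpm": sp.csr_matrix(norm_rows(O)),
    }
    return MMMCDesign(z, X, blocks), (Z2, W, norm_rows(O))


def _dense_loglik(design_mats, z, X, beta, variances, s2e):
    """Oracle: explicit V, multivariate-normal logpdf."""
    Z2, W, O = design_mats
    V = (
        variances[0] * Z2 @ Z2.T
        + variances[1] * W @ W.T
        + variances[2] * O @ O.T
        + s2e * np.eye(len(z))
    )
    return multivariate_normal.logpdf(z, mean=X @ beta, cov=V)


class TestLoglikOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_dense_mvn_logpdf(self, seed):
        rng = np.random.default_rng(seed)
        design, mats = _random_instance(rng, n=int(rng.integers(10, 51)))
        for _ in range(3):
            variances = rng.uniform(0.05, 1.0, 3)
            s2e = rng.uniform(0.2, 1.5)
            beta = rng.normal(size=design.p)
            ours = design.loglik(
                dict(zip(("ind_mun", "hcp", "hcpm"), variances)), s2e, beta=beta
            )
            oracle = _dense_loglik(mats, design.z, design.X, beta, variances, s2e)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_profiled_beta_is_gls_optimum(self):
        rng = np.random.default_rng(9)
        design, mats = _random_instance(rng)
        variances = {"ind_mun": 0.3, "hcp": 0.2, "hcpm": 0.1}
        prof = design.loglik(variances, 0.8)
        beta_hat = design.gls_beta(variances, 0.8)
        at_opt = design.loglik(variances, 0.8, beta=beta_hat)
        assert prof == pytest.approx(at_opt, abs=1e-10)
        for _ in range(5):
            assert design.loglik(variances, 0.8, beta=beta_hat + rng.normal(0, 0.1, design.p)) < prof

    def test_single_standard_normal_observation(self):
        design = MMMCDesign(np.zeros(1), np.empty((1, 0)), {})
        ll = design.loglik({}, 1.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_invariant_to_observation_permutation(self):
        rng = np.random.default_rng(10)
        design, mats = _random_instance(rng, n=25)
        perm = rng.permutation(25)
        Z2, W, O = mats
        design_p = MMMCDesign(
            design.z[perm],
            design.X[perm],
            {
                "ind_mun": sp.csr_matrix(Z2[perm]),
                "hcp": sp.csr_matrix(W[perm]),
                "hcpm": sp.csr_matrix(O[perm]),
            },
        )
        v = {"ind_mun": 0.2, "hcp": 0.4, "hcpm": 0.3}
        assert design.loglik(v, 0.9) == pytest.approx(
            design_p.loglik(v, 0.9), abs=1e-9
        )

    def test_accepts_variance_components_object(self):
        rng = np.random.default_rng(11)
        design, _ = _random_instance(rng)
        vc = VarianceComponents(0.1, 0.2, 0.3, 0.7)
        assert design.loglik(vc) == pytest.approx(
            design.loglik({"ind_mun": 0.1, "hcp": 0.2, "hcpm": 0.3}, 0.7), abs=1e-12
        )


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_woodbury_equals_dense_on_random_instances(seed):
    """Property: the low-rank likelihood equals the dense oracle for any
    small random instance and admissible parameter point."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    design, mats = _random_instance(rng, n=n)
    variances = rng.uniform(0.0, 1.0, 3)  # zeros allowed
    s2e = rng.uniform(0.1, 2.0)
    beta = rng.normal(size=design.p)
    ours = design.loglik(
        dict(zip(("ind_mun", "hcp", "hcpm"), variances)), s2e, beta=beta
    )
    oracle = _dense_loglik(mats, design.z, design.X, beta, variances, s2e)
    assert ours == pytest.approx(oracle, abs=1e-7)


class TestImpliedVariance:
    def test_diag_matches_dense_v_and_weight_sum_squares(self):
        rng = np.random.default_rng(12)
        design, mats = _random_instance(rng, n=20)
        Z2, W, O = mats
        v = {"ind_mun": 0.15, "hcp": 0.35, "hcpm": 0.25}
        s2e = 0.6
        dense_V = (
            v["ind_mun"] * Z2 @ Z2.T + v["hcp"] * W @ W.T + v["hcpm"] * O @ O.T
            + s2e * np.eye(20)
        )
        ours = design.implied_variance_diag(v, s2e)
        assert np.allclose(ours, np.diag(dense_V), atol=1e-10)
        # the closed form: s2_mun + s2_hcp*sum(w^2) + s2_hcpm*sum(o^2) + s2e
        closed = (
            v["ind_mun"]
            + v["hcp"] * (W**2).sum(axis=1)
            + v["hcpm"] * (O**2).sum(axis=1)
            + s2e
        )
        assert np.allclose(ours, closed, atol=1e-10)


class TestFit:
    def test_zero_cluster_variances_hit_boundary(self):
        cfg = GeneratorConfig(
            n_individuals=2000,
            sigma2_ind_mun=0.0,
            sigma2_hcp=0.0,
            sigma2_hcpm=0.0,
            sigma2_e=0.8,
            hospitalisation_probability=0.9,  # keep most individuals
        )
        ds = generate(cfg, seed=21)
        mt = build_membership_table(ds.visits)
        omega = derive_hcpm_weights(mt, ds.hcps)
        hosp = ds.individuals[ds.individuals["hospitalised"] == 1]
        z = hosp.set_index("individual_id")["latent_z"]
        design = build_design(z, ds.individuals, mt, omega, ["male", "age_std"])
        fit = design.fit(n_starts=2)
        # a truly-zero variance is estimated at (or within sampling noise
        # of) the boundary; the residual variance is recovered
        assert fit.components.sigma2_ind_mun < 0.02
        assert fit.components.sigma2_hcp < 0.02
        assert fit.components.sigma2_hcpm < 0.02
        assert fit.components.sigma2_e == pytest.approx(0.8, rel=0.05)
        assert len(fit.boundary) >= 1

    def test_aic_bic_definitions(self, medium_dataset):
        ds = medium_dataset
        mt = build_membership_table(ds.visits)
        omega = derive_hcpm_weights(mt, ds.hcps)
        hosp = ds.individuals[ds.individuals["hospitalised"] == 1]
        z = hosp.set_index("individual_id")["latent_z"]
        fit = build_design(z, ds.individuals, mt, omega, ["male"]).fit(n_starts=1)
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)
        assert fit.bic == pytest.approx(
            fit.k_params * np.log(fit.n_obs) - 2 * fit.loglik
        )

    def test_rank_deficient_x_rejected(self):
        rng = np.random.default_rng(13)
        design, _ = _random_instance(rng)
        X_bad = np.column_stack([design.X, design.X[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            MMMCDesign(design.z, X_bad, {k: v for k, v in design.blocks.items()})

    def test_reml_and_ml_differ_but_agree_at_large_n(self):
        rng = np.random.default_rng(14)
        design, _ = _random_instance(rng, n=40)
        ml = design.fit(reml=False, n_starts=1)
        reml = design.fit(reml=True, n_starts=1)
        assert ml.loglik != pytest.approx(reml.loglik, abs=1e-3)


class TestEmpiricalBayes:
    def test_matches_dense_conditional_mean_oracle(self):
        rng = np.random.default_rng(15)
        design, mats = _random_instance(rng, n=25)
        fit = design.fit(n_starts=1)
        Z2, W, O = mats
        U = np.hstack([Z2, W, O])
        c = fit.components
        g = np.concatenate(
            [
                np.full(Z2.shape[1], c.sigma2_ind_mun),
                np.full(W.shape[1], c.sigma2_hcp),
                np.full(O.shape[1], c.sigma2_hcpm),
            ]
        )
        V = U @ np.diag(g) @ U.T + c.sigma2_e * np.eye(25)
        r = design.z - design.X @ fit.beta.to_numpy()
        oracle = np.diag(g) @ U.T @ np.linalg.solve(V, r)
        eb = design.empirical_bayes(fit)
        got = np.concatenate(
            [eb["ind_mun"]["eb_mean"], eb["hcp"]["eb_mean"], eb["hcpm"]["eb_mean"]]
        )
        assert np.allclose(got, oracle, atol=1e-8)

    def test_zero_variance_level_shrinks_to_zero(self):
        rng = np.random.default_rng(16)
        design, _ = _random_instance(rng, n=30)
        # refit after forcing a level to zero via a degenerate fit object
        fit = design.fit(n_starts=1)
        from dataclasses import replace

        comps = VarianceComponents(0.0, fit.components.sigma2_hcp,
                                   fit.components.sigma2_hcpm,
                                   fit.components.sigma2_e)
        fit0 = replace(fit, components=comps)
        eb = design.empirical_bayes(fit0)
        assert np.allclose(eb["ind_mun"]["eb_mean"], 0.0)

    def test_predictions_centre_near_zero(self, medium_dataset):
        ds = medium_dataset
        mt = build_membership_table(ds.visits)
        omega = derive_hcpm_weights(mt, ds.hcps)
        hosp = ds.individuals[ds.individuals["hospitalised"] == 1]
        z = hosp.set_index("individual_id")["latent_z"]
        design = build_design(z, ds.individuals, mt, omega, ["male", "age_std"])
        fit = design.fit(n_starts=1)
        eb = design.empirical_bayes(fit)
        for level in ("ind_mun", "hcp", "hcpm"):
            vals = eb[level]["eb_mean"].to_numpy()
            if vals.std() > 0:
                assert abs(vals.mean()) < 0.5 * vals.std()
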