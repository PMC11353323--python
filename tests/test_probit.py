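"""The municipality-clustered probit: quadrature accuracy against a dense
numerical-integration oracle, invariances, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import log_ndtr
from scipy.stats import norm

from mmhurdle import fit_probit, predict_probability, probit_loglik
from mmhurdle.probit import ProbitFit, SeparationError


def _simulate(rng, n_groups, per_group, alpha, sigma2, x_sd=1.0):
    g = np.repeat(np.arange(n_groups), per_group)
    n = len(g)
    x = rng.normal(0, x_sd, n)
    eps = rng.normal(0, np.sqrt(sigma2), n_groups)
    eta = alpha[0] + alpha[1] * x + eps[g]
    y = (rng.random(n) < norm.cdf(eta)).astype(int)
    return pd.DataFrame(
        {
            "individual_id": range(n),
            "residence_municipality_id": [f"m{i}" for i in g],
            "x": x,
            "n_hospitalisations": y,
        }
    )


def _oracle_loglik(alpha, sigma2, X, y, group_idx):
    """Independent oracle: per-cluster marginal likelihood by high-order
    fixed quadrature over the random intercept."""
    eta = X @ alpha
    q = 2.0 * y - 1.0
    total = 0.0
    for g in np.unique(group_idx):
        sel = group_idx == g

        def integrand(b):
            return np.exp(
                log_ndtr(q[sel] * (eta[sel] + b)).sum()
            ) * norm.pdf(b, scale=np.sqrt(sigma2))

        val, _ = integrate.quad(integrand, -8 * np.sqrt(sigma2) - 3,
                                8 * np.sqrt(sigma2) + 3, limit=400)
        total += np.log(val)
    return total


class TestLikelihood:
    def test_matches_dense_integration_oracle(self):
        rng = np.random.default_rng(0)
        df = _simulate(rng, 3, 10, (0.3, -0.5), 0.4)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["n_hospitalisations"].to_numpy(float)
        gidx = pd.factorize(df["residence_municipality_id"])[0]
        for alpha, s2 in [((0.3, -0.5), 0.4), ((0.0, 1.0), 0.1), ((-0.2, 0.2), 1.5)]:
            ours = probit_loglik(np.array(alpha), s2, X, y, gidx, n_quad=15)
            oracle = _oracle_loglik(np.array(alpha), s2, X, y, gidx)
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_quadrature_converged_at_default_nodes(self):
        rng = np.random.default_rng(1)
        df = _simulate(rng, 5, 20, (0.2, 0.4), 0.3)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["n_hospitalisations"].to_numpy(float)
        gidx = pd.factorize(df["residence_municipality_id"])[0]
        a = np.array([0.2, 0.4])
        l15 = probit_loglik(a, 0.3, X, y, gidx, n_quad=15)
        l41 = probit_loglik(a, 0.3, X, y, gidx, n_quad=41)
        assert abs(l15 - l41) < 1e-6

    def test_plain_quadrature_agrees_with_adaptive(self):
        rng = np.random.default_rng(2)
        df = _simulate(rng, 4, 15, (0.1, 0.3), 0.2)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["n_hospitalisations"].to_numpy(float)
        gidx = pd.factorize(df["residence_municipality_id"])[0]
        a = np.array([0.1, 0.3])
        assert probit_loglik(a, 0.2, X, y, gidx, 31, adaptive=True) == pytest.approx(
            probit_loglik(a, 0.2, X, y, gidx, 61, adaptive=False), abs=1e-6
        )

    def test_invariant_to_municipality_relabelling(self):
        rng = np.random.default_rng(3)
        df = _simulate(rng, 6, 12, (0.0, 0.5), 0.5)
        fit1 = fit_probit(df, ["x"])
        relabel = {f"m{i}": f"zz{9 - i}" for i in range(6)}
        df2 = df.assign(
            residence_municipality_id=df["residence_municipality_id"].map(relabel)
        )
        fit2 = fit_probit(df2, ["x"])
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-8)


class TestFit:
    def test_zero_variance_collapses_to_plain_probit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        df = _simulate(rng, 20, 60, (0.4, -0.7), 0.0)
        fit = fit_probit(df, ["x"])
        assert fit.sigma2_eps < 1e-4
        X = np.column_stack([np.ones(len(df)), df["x"]])
        plain = sm.Probit(df["n_hospitalisations"].to_numpy(), X).fit(disp=0)
        se = np.asarray(plain.bse)
        params = np.asarray(plain.params)
        assert abs(fit.alpha["const"] - params[0]) < 2.5 * se[0]
        assert abs(fit.alpha["x"] - params[1]) < 2.5 * se[1]

    def test_direction_flip_negates_alpha_only(self):
        rng = np.random.default_rng(5)
        df = _simulate(rng, 10, 40, (0.3, 0.5), 0.3)
        f_h = fit_probit(df, ["x"], direction="hospitalised")
        f_z = fit_probit(df, ["x"], direction="zero")
        assert f_h.loglik == pytest.approx(f_z.loglik, abs=1e-5)
        assert f_h.sigma2_eps == pytest.approx(f_z.sigma2_eps, abs=1e-3)
        assert np.allclose(f_h.alpha, -f_z.alpha, atol=1e-3)

    def test_recovery_improves_with_sample_size(self):
        truth = 0.3
        errs = {}
        for n_per, seed0 in ((15, 100), (120, 200)):
            estimates = []
            for s in range(6):
                rng = np.random.default_rng(seed0 + s)
                df = _simulate(rng, 40, n_per, (0.2, 0.4), truth)
                estimates.append(fit_probit(df, ["x"], n_quad=9).sigma2_eps)
            errs[n_per] = np.sqrt(np.mean((np.array(estimates) - truth) ** 2))
        assert errs[120] < errs[15]

    def test_constant_response_raises_separation(self):
        df = pd.DataFrame(
            {
                "individual_id": range(20),
                "residence_municipality_id": ["a"] * 10 + ["b"] * 10,
                "x": np.linspace(-1, 1, 20),
                "n_hospitalisations": 1,
            }
        )
        with pytest.raises(SeparationError):
            fit_probit(df, ["x"])


class TestPredict:
    def _fit(self):
        rng = np.random.default_rng(6)
        df = _simulate(rng, 8, 30, (0.2, 0.6), 0.4)
        return fit_probit(df, ["x"]), df

    def test_symmetry_at_zero_index(self):
        fit = ProbitFit(
            alpha=pd.Series({"const": 0.0, "x": 0.0}),
            sigma2_eps=0.0,
            loglik=0.0,
            n_obs=0,
            n_groups=0,
            n_quadrature_points=15,
            direction="hospitalised",
            n_iter=0,
            grad_norm=0.0,
            boundary=True,
            converged=True,
        )
        new = pd.DataFrame({"x": [0.0, 1.0]})
        assert predict_probability(fit, new)[0] == pytest.approx(0.5)
        assert np.allclose(
            predict_probability(fit, new, "population"),
            predict_probability(fit, new, "conditional"),
        )

    def test_population_average_matches_monte_carlo(self):
        fit, df = self._fit()
        new = df.head(20)
        rng = np.random.default_rng(7)
        draws = rng.normal(0, np.sqrt(fit.sigma2_eps), 10**6)
        X = np.column_stack([np.ones(len(new)), new["x"]])
        eta = X @ fit.alpha.to_numpy()
        mc = np.array([norm.cdf(e + draws).mean() for e in eta])
        ours = predict_probability(fit, new, "population")
        assert np.allclose(ours, mc, atol=1e-3)

    def test_covariate_mismatch_rejected(self):
        fit, _ = self._fit()
        with pytest.raises(ValueError, match="missing"):
            predict_probability(fit, pd.DataFrame({"other": [1.0]}))
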