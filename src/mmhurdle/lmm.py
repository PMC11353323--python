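"""Gaussian multiple-membership multiple-classification (MMMC) mixed model.

The magnitude part of the hurdle: for hospitalised individuals, the
standardised log count z follows

    z_i = x_i' beta + u2_{mun(i)} + sum_j w_ij u3_j + sum_k omega_ik v4_k + e_i

with independent normal random effects for the residence municipality (u2),
the attended providers (u3, weighted by care shares w), and the provider
municipalities (v4, weighted by omega), plus an individual residual. The
marginal covariance is

    V = s2_mun Z2 Z2' + s2_hcp W W' + s2_hcpm O O' + s2_e I,

low-rank plus diagonal, so the likelihood is evaluated with the Woodbury
identity on the q x q capacity matrix (q = #municipalities + #providers +
#provider municipalities), never forming V. Fixed effects are profiled out
by GLS at each variance evaluation; variances are optimised on the log
scale with several starts. Estimation is maximum likelihood by default (the
model battery compares fixed-effect specifications by likelihood ratios and
AIC/BIC); REML is available.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .vpc import VarianceComponents

__all__ = ["MMMCFit", "MMMCDesign", "fit_mmmc", "build_design"]

_BOUNDARY_TOL = 1e-8
_LOGVAR_LB = -30.0


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class MMMCFit:
    """Result of a Gaussian mixed fit with any subset of the random blocks."""

    beta: pd.Series
    components: VarianceComponents
    loglik: float
    aic: float
    bic: float
    n_obs: int
    k_params: int
    structure: tuple[str, ...]  # random blocks present, e.g. ('ind_mun','hcp','hcpm')
    design_summary: dict
    boundary: tuple[str, ...]
    converged: bool
    n_iter: int
    reml: bool
    data_fingerprint: str


class MMMCDesign:
    """Prepared design: response, fixed effects, and sparse random blocks.

    ``blocks`` maps a level name to an (n x q_l) sparse weight matrix whose
    rows are the membership weights of that level (an indicator matrix for
    single-membership levels). All cross-products needed by the likelihood
    are precomputed once, so each evaluation costs O(q^3) independent of n.
    """

    def __init__(
        self,
        z: np.ndarray,
        X: np.ndarray,
        blocks: dict[str, sp.spmatrix],
        beta_names: list[str] | None = None,
        level_labels: dict[str, list] | None = None,
    ):
        self.z = np.asarray(z, dtype=float)
        self.X = np.asarray(X, dtype=float)
        n, p = self.X.shape
        if len(self.z) != n:
            raise ValueError("z and X row counts differ")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("fixed-effect design X is rank deficient")
        self.block_names = tuple(blocks)
        self.blocks = {k: sp.csr_matrix(v) for k, v in blocks.items()}
        for k, B in self.blocks.items():
            if B.shape[0] != n:
                raise ValueError(f"block {k!r} has {B.shape[0]} rows, expected {n}")
        self.beta_names = beta_names or [f"x{j}" for j in range(p)]
        self.level_labels = level_labels or {}
        self.n, self.p = n, p
        self.q_per_block = {k: B.shape[1] for k, B in self.blocks.items()}
        self.q = sum(self.q_per_block.values())

        U = sp.hstack([self.blocks[k] for k in self.block_names], format="csr") \
            if self.block_names else sp.csr_matrix((n, 0))
        self._U = U
        # precomputed cross-products
        self._S = np.asarray((U.T @ U).todense())  # q x q
        self._UtX = np.asarray(U.T @ self.X)
        self._Utz = np.asarray(U.T @ self.z).ravel()
        self._XtX = self.X.T @ self.X
        self._Xtz = self.X.T @ self.z
        self._ztz = float(self.z @ self.z)
        # map block -> slice in the stacked U
        self.slices: dict[str, slice] = {}
        off = 0
        for k in self.block_names:
            self.slices[k] = slice(off, off + self.q_per_block[k])
            off += self.q_per_block[k]
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.z).tobytes())
        h.update(np.ascontiguousarray(self.X).tobytes())
        self.fingerprint = h.hexdigest()[:16]

    # -- likelihood --------------------------------------------------------
    def _factor(self, variances: dict[str, float], s2e: float):
        """Cholesky of the capacity matrix C = s2e I + D S D with
        D = diag(per-column sd of the scaled random effects)."""
        if s2e <= 0:
            raise ValueError("residual variance must be > 0")
        d = np.empty(self.q)
        for k in self.block_names:
            d[self.slices[k]] = np.sqrt(max(variances[k], 0.0))
        C = (d[:, None] * self._S) * d[None, :]
        C[np.diag_indices_from(C)] += s2e
        try:
            cf = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"covariance numerically non-positive-definite at variances "
                f"{variances} (residual {s2e})"
            ) from err
        logdet_V = self.n * np.log(s2e) + 2.0 * np.sum(
            np.log(np.diag(cf[0]))
        ) - self.q * np.log(s2e)
        return cf, d, logdet_V

    def _solves(self, cf, d, s2e):
        """Return helper computing a'V^{-1}b from precomputed U'a, U'b."""

        def quad(at_b: float, Ua: np.ndarray, Ub: np.ndarray) -> float:
            da, db = d * Ua, d * Ub
            return (at_b - float(da @ cho_solve(cf, db))) / s2e

        return quad

    def loglik(
        self,
        variances: dict[str, float] | VarianceComponents,
        s2e: float | None = None,
        beta: np.ndarray | None = None,
        reml: bool = False,
    ) -> float:
        """Marginal Gaussian log-likelihood; beta profiled by GLS if omitted.

        Accepts either a dict of block variances plus ``s2e``, or a full
        :class:`VarianceComponents` (levels absent from the design must be
        zero there).
        """
        if isinstance(variances, VarianceComponents):
            vc = variances
            variances = {k: vc[{"ind_mun": "ind_mun", "hcp": "hcp", "hcpm": "hcpm"}[k]]
                         for k in self.block_names}
            s2e = vc.sigma2_e
        if s2e is None:
            raise ValueError("residual variance s2e required")
        cf, d, logdet_V = self._factor(variances, s2e)

        # X'V^{-1}X, X'V^{-1}z, z'V^{-1}z via Woodbury with precomputed pieces
        DUX = d[:, None] * self._UtX
        DUz = d * self._Utz
        sol_X = cho_solve(cf, DUX)
        sol_z = cho_solve(cf, DUz)
        XtViX = (self._XtX - DUX.T @ sol_X) / s2e
        XtViz = (self._Xtz - DUX.T @ sol_z) / s2e
        ztViz = (self._ztz - DUz @ sol_z) / s2e

        if beta is None:
            beta = np.linalg.solve(XtViX, XtViz)
        beta = np.asarray(beta, dtype=float)
        rss = ztViz - 2.0 * beta @ XtViz + beta @ XtViX @ beta
        ll = -0.5 * (self.n * np.log(2 * np.pi) + logdet_V + rss)
        if reml:
            sign, ld = np.linalg.slogdet(XtViX)
            if sign <= 0:
                raise ValueError("X'V^{-1}X not positive definite")
            ll += -0.5 * ld + 0.5 * self.p * np.log(2 * np.pi)
        return float(ll)

    def gls_beta(self, variances: dict[str, float], s2e: float) -> np.ndarray:
        cf, d, _ = self._factor(variances, s2e)
        DUX = d[:, None] * self._UtX
        DUz = d * self._Utz
        XtViX = (self._XtX - DUX.T @ cho_solve(cf, DUX)) / s2e
        XtViz = (self._Xtz - DUX.T @ cho_solve(cf, DUz)) / s2e
        return np.linalg.solve(XtViX, XtViz)

    # -- diagnostics -------------------------------------------------------
    def weak_identifiability(self, tol: float = 1e-8) -> bool:
        """True when the stacked random-effect design is rank deficient
        beyond its structural deficiency.

        Because every block's rows sum to one, stacking b blocks always
        loses b-1 column ranks (a constant shifted between levels leaves the
        fit unchanged); that is inherent to multiple membership and leaves
        the variances identified. Extra deficiency — e.g. a
        provider-municipality column identical to its sole
        single-membership provider's column — leaves the corresponding
        variances only jointly identified and is what this flags."""
        if self.q == 0:
            return False
        eig = np.linalg.eigvalsh(self._S)
        n_null = int(np.sum(eig < tol * max(eig[-1], 1.0)))
        structural = max(len(self.block_names) - 1, 0)
        return n_null > structural

    def implied_variance_diag(
        self, variances: dict[str, float], s2e: float
    ) -> np.ndarray:
        """diag(V): per-individual total variance from the fitted components
        and that individual's squared membership weights."""
        out = np.full(self.n, s2e)
        for k in self.block_names:
            B = self.blocks[k]
            out = out + variances[k] * np.asarray(B.multiply(B).sum(axis=1)).ravel()
        return out

    # -- empirical Bayes ---------------------------------------------------
    def empirical_bayes(self, fit: "MMMCFit") -> dict[str, pd.DataFrame]:
        """BLUP conditional means and SDs of every random effect, plus
        standardised residuals under key ``'residual'``.

        Levels with (near-)zero fitted variance shrink to exactly zero.
        """
        variances = {k: fit.components[k] for k in self.block_names}
        s2e = fit.components.sigma2_e
        cf, d, _ = self._factor(variances, s2e)
        beta = fit.beta.to_numpy()
        r = self.z - self.X @ beta
        Ur = np.asarray(self._U.T @ r).ravel()
        DUr = d * Ur
        sol_r = cho_solve(cf, DUr)
        # b_hat = G U' V^{-1} r ; with G = D^2: D * [ (DUr - D S D C^{-1} DUr)/s2e ]
        inner = (DUr - (d[:, None] * self._S * d[None, :]) @ sol_r) / s2e
        b_hat = d * inner
        # conditional variance diag: G - G U'V^{-1}U G
        UtViU = (self._S - (self._S * d[None, :]) @ cho_solve(cf, d[:, None] * self._S)) / s2e
        g = d**2
        cond_var = g - g * np.einsum("ii->i", UtViU) * g
        cond_var = np.maximum(cond_var, 0.0)
        out: dict[str, pd.DataFrame] = {}
        for k in self.block_names:
            sl = self.slices[k]
            labels = self.level_labels.get(k, list(range(self.q_per_block[k])))
            out[k] = pd.DataFrame(
                {
                    "unit": labels,
                    "eb_mean": b_hat[sl] if variances[k] > _BOUNDARY_TOL else 0.0 * b_hat[sl],
                    "eb_sd": np.sqrt(cond_var[sl]),
                }
            )
        resid = r - np.asarray(self._U @ b_hat).ravel()
        out["residual"] = pd.DataFrame(
            {"residual": resid, "standardised": resid / np.sqrt(s2e)}
        )
        return out

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        reml: bool = False,
        n_starts: int = 3,
        max_iter: int = 500,
        seed: int = 0,
    ) -> MMMCFit:
        """Maximise the (restricted) likelihood over log-variances.

        Multiple starting points guard against local optima; the best
        optimum is kept. Variances pinned below ~1e-8 are reported as
        boundary estimates, not silently zeroed.
        """
        nb = len(self.block_names)
        var_z = float(np.var(self.z)) if self.n > 1 else 1.0
        var_z = max(var_z, 1e-6)

        def nll(theta: np.ndarray) -> float:
            variances = {
                k: float(np.exp(theta[i])) for i, k in enumerate(self.block_names)
            }
            try:
                return -self.loglik(variances, float(np.exp(theta[-1])), reml=reml)
            except (ValueError, np.linalg.LinAlgError):
                # numerically non-PD corner (e.g. huge cluster variances with
                # vanishing residual): steer the optimiser away
                return 1e12

        starts = []
        equal = np.log(np.full(nb + 1, var_z / (nb + 1)))
        starts.append(equal)
        if n_starts > 1:
            mostly_resid = np.append(
                np.log(np.full(nb, 0.05 * var_z)), np.log(0.85 * var_z)
            )
            starts.append(mostly_resid)
        rng = np.random.default_rng(seed)
        while len(starts) < n_starts:
            starts.append(equal + rng.normal(0, 1.0, nb + 1))

        best = None
        trace = []
        for x0 in starts:
            res = minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=[(_LOGVAR_LB, 5.0)] * (nb + 1),
                options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-8},
            )
            trace.append((res.fun, res.message))
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("all starts failed", trace)
        grad_ok = best.jac is None or np.max(np.abs(best.jac)) < 1e-2
        if not best.success and not grad_ok:
            raise ConvergenceError(f"optimiser did not converge: {best.message}", trace)

        variances = {
            k: float(np.exp(best.x[i])) for i, k in enumerate(self.block_names)
        }
        s2e = float(np.exp(best.x[-1]))
        beta = self.gls_beta(variances, s2e)
        ll = self.loglik(variances, s2e, reml=reml)
        boundary = tuple(k for k, v in variances.items() if v < _BOUNDARY_TOL)
        comps = VarianceComponents(
            sigma2_ind_mun=variances.get("ind_mun", 0.0),
            sigma2_hcp=variances.get("hcp", 0.0),
            sigma2_hcpm=variances.get("hcpm", 0.0),
            sigma2_e=s2e,
        )
        k_params = self.p + nb + 1
        aic = 2 * k_params - 2 * ll
        bic = k_params * np.log(self.n) - 2 * ll
        if self.weak_identifiability():
            warnings.warn(
                "random-effect design is rank deficient; some variance "
                "components are only weakly identified",
                stacklevel=2,
            )
        return MMMCFit(
            beta=pd.Series(beta, index=self.beta_names),
            components=comps,
            loglik=ll,
            aic=float(aic),
            bic=float(bic),
            n_obs=self.n,
            k_params=k_params,
            structure=self.block_names,
            design_summary={
                "n": self.n,
                "p": self.p,
                **{f"q_{k}": v for k, v in self.q_per_block.items()},
            },
            boundary=boundary,
            converged=bool(best.success or grad_ok),
            n_iter=int(best.nit),
            reml=reml,
            data_fingerprint=self.fingerprint,
        )


def _weight_matrix(
    table: pd.DataFrame,
    ids: pd.Series,
    unit_col: str,
    weight_col: str,
) -> tuple[sp.csr_matrix, list]:
    """Sparse (n x q) weight matrix aligned to the individual order in ids."""
    row_pos = {v: i for i, v in enumerate(ids)}
    sub = table[table["individual_id"].isin(row_pos)]
    units, col_idx = np.unique(sub[unit_col], return_inverse=True)
    rows = sub["individual_id"].map(row_pos).to_numpy()
    M = sp.csr_matrix(
        (sub[weight_col].to_numpy(dtype=float), (rows, col_idx)),
        shape=(len(ids), len(units)),
    )
    return M, list(units)


def build_design(
    z,
    individuals: pd.DataFrame,
    mt: pd.DataFrame,
    hcpm_mt: pd.DataFrame,
    covariates: list[str] | None = None,
    residence_col: str = "residence_municipality_id",
    structure: tuple[str, ...] = ("ind_mun", "hcp", "hcpm"),
) -> MMMCDesign:
    """Assemble an :class:`MMMCDesign` for the hospitalised subset.

    ``z`` is a :class:`~mmhurdle.preprocessing.TransformedOutcome` or a
    Series indexed by individual_id. ``structure`` selects which random
    blocks enter: the full model uses all three; alternatives (see
    :mod:`mmhurdle.selection`) drop or replace blocks.
    """
    from .preprocessing import TransformedOutcome

    if isinstance(z, TransformedOutcome):
        z = z.z
    ids = pd.Series(z.index)
    ind = individuals.set_index("individual_id").loc[ids]
    covariates = list(covariates or [])
    X = np.column_stack(
        [np.ones(len(ids))] + [ind[c].to_numpy(dtype=float) for c in covariates]
    )
    blocks: dict[str, sp.spmatrix] = {}
    labels: dict[str, list] = {}
    for name in structure:
        if name == "ind_mun":
            res = ind[residence_col].reset_index()
            res["weight"] = 1.0
            blocks[name], labels[name] = _weight_matrix(
                res, ids, residence_col, "weight"
            )
        elif name == "hcp":
            blocks[name], labels[name] = _weight_matrix(mt, ids, "hcp_id", "weight_w")
        elif name == "hcpm":
            blocks[name], labels[name] = _weight_matrix(
                hcpm_mt, ids, "municipality_id", "weight_omega"
            )
        elif name == "hcp_main":
            # hard single-membership on the largest-weight provider; ties
            # break to the smallest provider id (visit order is not modelled)
            mt_sorted = mt.sort_values(
                ["individual_id", "weight_w", "hcp_id"],
                ascending=[True, False, True],
            )
            main = mt_sorted.drop_duplicates("individual_id").copy()
            main["weight"] = 1.0
            blocks[name], labels[name] = _weight_matrix(main, ids, "hcp_id", "weight")
        else:
            raise ValueError(f"unknown random block {name!r}")
    return MMMCDesign(
        z=z.to_numpy(dtype=float),
        X=X,
        blocks=blocks,
        beta_names=["const"] + covariates,
        level_labels=labels,
    )


def fit_mmmc(
    z,
    individuals: pd.DataFrame,
    mt: pd.DataFrame,
    hcpm_mt: pd.DataFrame,
    covariates: list[str] | None = None,
    residence_col: str = "residence_municipality_id",
    reml: bool = False,
    n_starts: int = 3,
) -> MMMCFit:
    """Fit the full four-variance-component MMMC model by (RE)ML.

    Convenience wrapper over :func:`build_design` + :meth:`MMMCDesign.fit`.
    """
    design = build_design(
        z, individuals, mt, hcpm_mt, covariates, residence_col
    )
    return design.fit(reml=reml, n_starts=n_starts)
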