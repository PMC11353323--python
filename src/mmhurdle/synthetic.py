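"""Synthetic register-like data with known ground truth.

Emulates the structure of a national administrative register of psychiatric
care: ~98 municipalities, three provider types (general practitioners,
community-based care, hospital departments) located in municipalities,
individuals attending a handful of providers with care-share weights, and a
two-part (hurdle) outcome — a municipality-clustered probit decides who is
hospitalised, and a four-component multiple-membership Gaussian model on the
standardised log scale generates counts for those who are.

All generating parameters are recorded in the returned dataset so parameter
recovery can be tested downstream. Randomness is split per component from a
single seed, so e.g. covariate draws do not shift when the outcome model
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "summarize"]

# Published distribution of distinct providers per individual (shares for
# 1..13 providers) used as the shape of the attendance-count distribution.
_HCP_COUNT_SHAPE = np.array(
    [10.03, 42.64, 26.61, 11.92, 4.90, 1.93, 0.96, 0.43, 0.25, 0.15, 0.09, 0.07, 0.04]
)
_HCP_COUNT_SHAPE /= _HCP_COUNT_SHAPE.sum()

# Full-scale register sizes the provider counts are scaled from.
_FULL_SCALE_N = 64_694
_FULL_SCALE_HCPS = {"GP": 2100, "community": 145, "hospital_department": 42}


def _tilt_to_mean(shape: np.ndarray, target_mean: float) -> np.ndarray:
    """Exponentially tilt a distribution on 1..K to a requested mean.

    Solves for r in p_k ∝ shape_k * r^k such that E[k] = target. Used because
    the published count distribution and the published mean disagree
    slightly; the tilt keeps the shape while honouring the stated mean.
    """
    k = np.arange(1, len(shape) + 1)

    def mean_at(r: float) -> float:
        q = shape * r**k
        q = q / q.sum()
        return float((k * q).sum())

    lo, hi = 1e-3, 10.0
    if not (mean_at(lo) <= target_mean <= mean_at(hi)):
        raise ValueError(f"target mean {target_mean} unreachable by tilting")
    r = brentq(lambda x: mean_at(x) - target_mean, lo, hi, xtol=1e-12)
    q = shape * r**k
    return q / q.sum()


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic register.

    Defaults are the emulated study's conditions: 98 municipalities, provider
    counts scaled from the full register (2100 GPs / 145 community providers
    / 42 hospital departments at 64,694 individuals), ~30% hospitalised, a
    probit municipality variance of 0.022, and Gaussian variance components
    (ind_mun, hcp, hcpm, residual) = (0.032, 0.075, 0.241, 0.720) on the
    standardised log scale.
    """

    n_individuals: int = 5000
    n_municipalities: int = 98
    n_gps: int | None = None  # None: scaled from the full register
    n_community: int | None = None
    n_hospital_depts: int | None = None
    mean_hcps_per_individual: float = 2.23
    max_hcps_per_individual: int = 13
    out_of_municipality_prob: float = 0.6
    dirichlet_concentration: float = 1.0
    hospitalisation_probability: float = 0.30
    # probit part
    sigma2_eps: float = 0.022
    probit_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.113, "age_std": 0.13, "dx_substance": 0.5}
    )
    # Gaussian part: (ind_mun, hcp, hcpm, residual) variances
    sigma2_ind_mun: float = 0.032
    sigma2_hcp: float = 0.075
    sigma2_hcpm: float = 0.241
    sigma2_e: float = 0.720
    gauss_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.10, "age_std": 0.05}
    )
    # count inversion: ln y ~ m + s*z, chosen so counts have roughly the
    # register's mean/SD of 5.76 (9.41) among the hospitalised (s accounts
    # for Var(z) ~ 1.07 at the default variance components)
    count_log_mean: float = 1.103
    count_log_sd: float = 1.10
    mean_days_per_hospitalisation: float = 8.6

    def resolved_hcp_counts(self) -> dict[str, int]:
        f = self.n_individuals / _FULL_SCALE_N
        scaled = {
            "GP": max(20, round(_FULL_SCALE_HCPS["GP"] * f)),
            "community": max(4, round(_FULL_SCALE_HCPS["community"] * f)),
            "hospital_department": max(2, round(_FULL_SCALE_HCPS["hospital_department"] * f)),
        }
        if self.n_gps is not None:
            scaled["GP"] = self.n_gps
        if self.n_community is not None:
            scaled["community"] = self.n_community
        if self.n_hospital_depts is not None:
            scaled["hospital_department"] = self.n_hospital_depts
        return scaled

    def validate(self) -> None:
        if self.n_individuals < 1 or self.n_municipalities < 2:
            raise ValueError("need >= 1 individual and >= 2 municipalities")
        for name in ("sigma2_eps", "sigma2_ind_mun", "sigma2_hcp", "sigma2_hcpm", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.hospitalisation_probability < 1:
            raise ValueError("hospitalisation_probability must be in (0, 1)")
        if not 0 <= self.out_of_municipality_prob <= 1:
            raise ValueError("out_of_municipality_prob must be in [0, 1]")
        total_hcps = sum(self.resolved_hcp_counts().values())
        if self.max_hcps_per_individual > total_hcps:
            raise ValueError(
                f"max_hcps_per_individual ({self.max_hcps_per_individual}) exceeds "
                f"the number of providers ({total_hcps})"
            )
        if not 1.0 <= self.mean_hcps_per_individual <= self.max_hcps_per_individual:
            raise ValueError("mean_hcps_per_individual out of range")


@dataclass
class SyntheticDataset:
    """Generated tables plus the exact parameters that produced them."""

    individuals: pd.DataFrame
    visits: pd.DataFrame
    hcps: pd.DataFrame
    municipalities: pd.DataFrame
    truth: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "individuals": self.individuals,
            "visits": self.visits,
            "hcps": self.hcps,
            "municipalities": self.municipalities,
        }


# Marginal prevalences (main diagnosis group) loosely matching the emulated
# register's descriptive table.
_DX_GROUPS = {
    "dx_organic": 0.0215,
    "dx_substance": 0.1032,
    "dx_schizophrenia": 0.1963,
    "dx_mood": 0.2314,
    "dx_neurotic": 0.3683,
    "dx_eating": 0.0171,
    "dx_personality": 0.1213,
    "dx_intellectual": 0.0209,
    "dx_developmental": 0.0217,
}


def _make_municipalities(rng: np.random.Generator, m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "municipality_id": [f"M{i:03d}" for i in range(m)],
            "assisted_living": (rng.random(m) < 0.90).astype(int),
            "personal_support": (rng.random(m) < 0.80).astype(int),
            "psych_therapy": (rng.random(m) < 0.21).astype(int),
            "pop_density": np.round(np.exp(rng.normal(9.6, 1.1, m)), 1),
        }
    )


def _make_hcps(
    rng: np.random.Generator, counts: dict[str, int], mun_ids: np.ndarray
) -> pd.DataFrame:
    rows = []
    idx = 0
    for hcp_type, n in counts.items():
        # spread providers over municipalities; GPs cover as many
        # municipalities as possible before doubling up
        if hcp_type == "GP" and n >= len(mun_ids):
            base = np.concatenate(
                [mun_ids, rng.choice(mun_ids, size=n - len(mun_ids), replace=True)]
            )
            rng.shuffle(base)
            locs = base
        else:
            locs = rng.choice(mun_ids, size=n, replace=True)
        cap = {
            "GP": rng.lognormal(3.0, 0.8, n),  # patients per GP, mean ~40
            "community": rng.lognormal(6.0, 1.2, n),  # episodes per year
            "hospital_department": rng.lognormal(3.1, 0.7, n),  # bed capacity
        }[hcp_type]
        for j in range(n):
            rows.append(
                {
                    "hcp_id": f"H{idx:05d}",
                    "hcp_type": hcp_type,
                    "municipality_id": locs[j],
                    "capacity": round(float(cap[j]), 2),
                    "teaching": int(hcp_type == "hospital_department" and rng.random() < 0.26),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def _draw_individuals(rng: np.random.Generator, n: int, mun_ids: np.ndarray) -> pd.DataFrame:
    # residence distribution: municipalities differ in catchment size
    mun_weights = rng.dirichlet(np.full(len(mun_ids), 5.0))
    residence = rng.choice(mun_ids, size=n, p=mun_weights)
    age = np.clip(rng.normal(36.2, 13.2, n), 18, 65)
    df = pd.DataFrame(
        {
            "individual_id": [f"I{i:06d}" for i in range(n)],
            "residence_municipality_id": residence,
            "male": (rng.random(n) < 0.454).astype(int),
            "age": np.round(age, 1),
            "living_alone": (rng.random(n) < 0.447).astype(int),
            "disability_pension": (rng.random(n) < 0.198).astype(int),
            "new_in_2016": (rng.random(n) < 0.054).astype(int),
            "psych_comorbidity": rng.poisson(0.519, n),
            "somatic_comorbidity": rng.poisson(1.493, n),
        }
    )
    df["age_std"] = (df["age"] - 36.2) / 13.2
    # one main diagnosis group per individual
    groups = list(_DX_GROUPS)
    probs = np.array(list(_DX_GROUPS.values()))
    probs = probs / probs.sum()
    main = rng.choice(len(groups), size=n, p=probs)
    for g_idx, g in enumerate(groups):
        df[g] = (main == g_idx).astype(int)
    return df


def _assign_attendance(
    rng: np.random.Generator,
    individuals: pd.DataFrame,
    hcps: pd.DataFrame,
    cfg: GeneratorConfig,
) -> pd.DataFrame:
    """Pick attended providers and integer visit counts per individual.

    Everyone starts with a GP near home (gatekeeping); each further provider
    is drawn from the residence municipality with probability
    1 - out_of_municipality_prob, else anywhere, inducing the
    cross-municipality attendance that makes residence and provider
    municipalities cross-classified. Visit counts allocate a
    Dirichlet-multinomial total so every attended provider gets >= 1 visit;
    care weights are the implied proportions.
    """
    if cfg.max_hcps_per_individual == 1 or cfg.mean_hcps_per_individual == 1.0:
        count_probs = np.array([1.0] + [0.0] * (cfg.max_hcps_per_individual - 1))
    else:
        count_probs = _tilt_to_mean(_HCP_COUNT_SHAPE[: cfg.max_hcps_per_individual],
                                    cfg.mean_hcps_per_individual)
    ks = np.arange(1, cfg.max_hcps_per_individual + 1)

    hcp_ids = hcps["hcp_id"].to_numpy()
    hcp_mun = hcps["municipality_id"].to_numpy()
    is_gp = (hcps["hcp_type"] == "GP").to_numpy()
    by_mun: dict[str, np.ndarray] = {}
    gp_by_mun: dict[str, np.ndarray] = {}
    for mun in np.unique(hcp_mun):
        mask = hcp_mun == mun
        by_mun[mun] = np.flatnonzero(mask)
        gp_by_mun[mun] = np.flatnonzero(mask & is_gp)
    all_idx = np.arange(len(hcp_ids))
    all_gp = np.flatnonzero(is_gp)

    n = len(individuals)
    d_all = rng.choice(ks, size=n, p=count_probs)
    res_all = individuals["residence_municipality_id"].to_numpy()

    rows_ind, rows_hcp, rows_units = [], [], []
    for i in range(n):
        d = int(d_all[i])
        res = res_all[i]
        chosen: list[int] = []
        # gatekeeping GP, local if the municipality has one
        local_gps = gp_by_mun.get(res, np.empty(0, dtype=int))
        pool = local_gps if len(local_gps) else all_gp
        chosen.append(int(pool[rng.integers(len(pool))]))
        tries = 0
        while len(chosen) < d and tries < 50 * d:
            tries += 1
            local = by_mun.get(res, np.empty(0, dtype=int))
            if len(local) and rng.random() >= cfg.out_of_municipality_prob:
                pool = local
            else:
                pool = all_idx
            cand = int(pool[rng.integers(len(pool))])
            if cand not in chosen:
                chosen.append(cand)
        d = len(chosen)  # may fall short only in tiny configurations
        p = rng.dirichlet(np.full(d, cfg.dirichlet_concentration))
        total_extra = rng.poisson(3.0 * d)
        extra = rng.multinomial(total_extra, p)
        units = 1 + extra
        rows_ind.extend([individuals["individual_id"].iat[i]] * d)
        rows_hcp.extend(hcp_ids[j] for j in chosen)
        rows_units.extend(int(u) for u in units)
    return pd.DataFrame(
        {"individual_id": rows_ind, "hcp_id": rows_hcp, "care_units": rows_units}
    )


def _linear_predictor(df: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(df))
    for name, c in coefs.items():
        lp += c * df[name].to_numpy(dtype=float)
    return lp


def generate(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Draw a full synthetic register.

    The same (config, seed) pair is byte-reproducible. The probit intercept
    is calibrated numerically so the marginal hospitalisation probability
    matches the configured target given the drawn covariates.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    ss = np.random.SeedSequence(seed)
    r_mun, r_hcp, r_ind, r_att, r_probit, r_gauss = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    municipalities = _make_municipalities(r_mun, cfg.n_municipalities)
    mun_ids = municipalities["municipality_id"].to_numpy()
    hcps = _make_hcps(r_hcp, cfg.resolved_hcp_counts(), mun_ids)
    individuals = _draw_individuals(r_ind, cfg.n_individuals, mun_ids)
    visits = _assign_attendance(r_att, individuals, hcps, cfg)

    # --- probit part: hospitalised or not ---------------------------------
    lp = _linear_predictor(individuals, cfg.probit_coefs)
    eps = r_probit.normal(0.0, np.sqrt(cfg.sigma2_eps), cfg.n_municipalities)
    eps_map = dict(zip(mun_ids, eps))
    eps_i = individuals["residence_municipality_id"].map(eps_map).to_numpy()

    def marginal(a0: float) -> float:
        # integrate the municipality effect analytically
        return float(norm.cdf((a0 + lp) / np.sqrt(1.0 + cfg.sigma2_eps)).mean())

    target = cfg.hospitalisation_probability
    alpha0 = brentq(lambda a: marginal(a) - target, -20, 20, xtol=1e-10)
    p_hosp = norm.cdf(alpha0 + lp + eps_i)
    hospitalised = (r_probit.random(cfg.n_individuals) < p_hosp).astype(int)

    # --- Gaussian part: standardised log count for the hospitalised -------
    from .membership import build_membership_table, derive_hcpm_weights

    mt = build_membership_table(visits)
    omega = derive_hcpm_weights(mt, hcps)
    u2 = r_gauss.normal(0.0, np.sqrt(cfg.sigma2_ind_mun), cfg.n_municipalities)
    u2_map = dict(zip(mun_ids, u2))
    u3 = r_gauss.normal(0.0, np.sqrt(cfg.sigma2_hcp), len(hcps))
    u3_map = dict(zip(hcps["hcp_id"], u3))
    v4 = r_gauss.normal(0.0, np.sqrt(cfg.sigma2_hcpm), cfg.n_municipalities)
    v4_map = dict(zip(mun_ids, v4))

    hcp_term = (
        mt.assign(t=mt["weight_w"] * mt["hcp_id"].map(u3_map))
        .groupby("individual_id")["t"]
        .sum()
    )
    hcpm_term = (
        omega.assign(t=omega["weight_omega"] * omega["municipality_id"].map(v4_map))
        .groupby("individual_id")["t"]
        .sum()
    )
    xb = _linear_predictor(individuals, cfg.gauss_coefs)
    e = r_gauss.normal(0.0, np.sqrt(cfg.sigma2_e), cfg.n_individuals)
    ids = individuals["individual_id"]
    z = (
        xb
        + individuals["residence_municipality_id"].map(u2_map).to_numpy()
        + ids.map(hcp_term).to_numpy()
        + ids.map(hcpm_term).to_numpy()
        + e
    )
    counts = np.where(
        hospitalised == 1,
        np.maximum(1, np.rint(np.exp(cfg.count_log_mean + cfg.count_log_sd * z))),
        0,
    ).astype(int)
    days_per = r_gauss.gamma(2.0, cfg.mean_days_per_hospitalisation / 2.0,
                             cfg.n_individuals)
    individuals = individuals.assign(
        hospitalised=hospitalised,
        n_hospitalisations=counts,
        n_inpatient_days=np.rint(counts * days_per).astype(int),
        latent_z=z,
    )

    truth = {
        "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(cfg).items()},
        "seed": seed,
        "alpha0": float(alpha0),
        "sigma2_eps": cfg.sigma2_eps,
        "variance_components": {
            "ind_mun": cfg.sigma2_ind_mun,
            "hcp": cfg.sigma2_hcp,
            "hcpm": cfg.sigma2_hcpm,
            "e": cfg.sigma2_e,
        },
        "probit_coefs": dict(cfg.probit_coefs),
        "gauss_coefs": dict(cfg.gauss_coefs),
    }
    return SyntheticDataset(
        individuals=individuals,
        visits=visits,
        hcps=hcps,
        municipalities=municipalities,
        truth=truth,
    )


def summarize(dataset: SyntheticDataset) -> dict:
    """Descriptive statistics mirroring the register's published tables:
    hospitalised fraction, count moments among the hospitalised, and the
    distributions of distinct providers / provider municipalities."""
    ind = dataset.individuals
    visits = dataset.visits
    hosp = ind[ind["n_hospitalisations"] > 0]
    n_hcps = visits.groupby("individual_id")["hcp_id"].nunique()
    loc = dataset.hcps.set_index("hcp_id")["municipality_id"]
    n_hcpms = (
        visits.assign(mun=visits["hcp_id"].map(loc))
        .groupby("individual_id")["mun"]
        .nunique()
    )
    summary = {
        "n_individuals": int(len(ind)),
        "n_hcps": int(len(dataset.hcps)),
        "n_municipalities": int(len(dataset.municipalities)),
        "hospitalised_fraction": float((ind["n_hospitalisations"] > 0).mean()),
        "mean_hospitalisations_among_hospitalised": (
            float(hosp["n_hospitalisations"].mean()) if len(hosp) else float("nan")
        ),
        "sd_hospitalisations_among_hospitalised": (
            float(hosp["n_hospitalisations"].std(ddof=1)) if len(hosp) > 1 else float("nan")
        ),
        "mean_distinct_hcps": float(n_hcps.mean()),
        "hcp_count_distribution": n_hcps.value_counts(normalize=True).sort_index().to_dict(),
        "hcpm_count_distribution": n_hcpms.value_counts(normalize=True).sort_index().to_dict(),
        "downstream_feasible": bool((ind["n_hospitalisations"] > 0).sum() >= 2),
    }
    return summary
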