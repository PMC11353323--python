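"""Variance partitioning over care profiles.

The Gaussian part of the hurdle model decomposes the outcome variance of an
individual into four sources: the individual residual, the healthcare
providers (HCPs) the individual attends, the municipalities those providers
are located in (HCPMs), and the individual's municipality of residence.
Because HCP and HCPM effects enter through membership weights, the total
variance is profile-specific:

    Var(z_i) = sigma2_ind_mun + sigma2_hcp * sum_j w_ij^2
             + sigma2_hcpm * sum_k omega_ik^2 + sigma2_e

A *care profile* is a hypothetical weight vector pair (w over HCPs, omega
over HCPMs). Variance partition coefficients (VPCs) divide each term by the
profile's total, so the share attributable to each level can be compared
across utilisation patterns. *Explained total variance* compares the total
under a covariate-free variance-component model against the fully adjusted
model at a fixed profile.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "CareProfile",
    "VpcResult",
    "total_variance",
    "vpc",
    "explained_total_variance",
    "component_reduction",
    "scenario_grid",
]

#: Names of the random-effect levels of the Gaussian part.
LEVELS = ("individual", "hcp", "hcpm", "ind_mun")


@dataclass(frozen=True)
class VarianceComponents:
    """The four variances of the Gaussian (count-magnitude) part.

    All variances are on the standardised-log-outcome scale and hence
    dimensionless.

    Parameters
    ----------
    sigma2_ind_mun
        Variance of the residence-municipality random effect.
    sigma2_hcp
        Variance of the healthcare-provider random effects.
    sigma2_hcpm
        Variance of the provider-municipality random effects.
    sigma2_e
        Individual residual variance.
    """

    sigma2_ind_mun: float
    sigma2_hcp: float
    sigma2_hcpm: float
    sigma2_e: float

    def __post_init__(self) -> None:
        for name in ("sigma2_ind_mun", "sigma2_hcp", "sigma2_hcpm", "sigma2_e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"variance component {name} must be >= 0, got {v!r}")

    def __getitem__(self, level: str) -> float:
        try:
            return {
                "individual": self.sigma2_e,
                "hcp": self.sigma2_hcp,
                "hcpm": self.sigma2_hcpm,
                "ind_mun": self.sigma2_ind_mun,
            }[level]
        except KeyError:
            raise KeyError(f"unknown level {level!r}; valid levels: {LEVELS}") from None

    def as_dict(self) -> dict[str, float]:
        return {lvl: self[lvl] for lvl in LEVELS}


@dataclass(frozen=True)
class CareProfile:
    """A hypothetical membership-weight scheme for scenario analysis.

    ``w`` weights hypothetical HCPs, ``omega`` hypothetical HCPMs. Weights
    normally sum to one; printed scenario profiles such as (0.75, 0.12, 0.12)
    whose published digits sum to 0.99 may be used verbatim by setting
    ``literal=True``, which relaxes the sum constraint to (0.95, 1].
    """

    w: tuple[float, ...]
    omega: tuple[float, ...]
    label: str = ""
    literal: bool = False

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.w)
        omega = tuple(float(x) for x in self.omega)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "omega", omega)
        if not w or not omega:
            raise ValueError("care profile needs at least one weight per level")
        for name, ws in (("w", w), ("omega", omega)):
            arr = np.asarray(ws)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} weights must be finite and >= 0")
            s = arr.sum()
            if self.literal:
                if not (0.95 < s <= 1.0 + 1e-9):
                    raise ValueError(
                        f"literal profile {name} weights sum to {s:.6g}; "
                        "must lie in (0.95, 1]"
                    )
            elif abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"{name} weights sum to {s:.6g}, not 1; pass literal=True "
                    "to use a printed profile verbatim"
                )

    # -- constructors ------------------------------------------------------
    @classmethod
    def single(cls) -> "CareProfile":
        """All care with one HCP in one HCPM."""
        return cls((1.0,), (1.0,), label="single")

    @classmethod
    def equal(cls, n_hcp: int, n_hcpm: int = 1) -> "CareProfile":
        """Equal weights over ``n_hcp`` HCPs and ``n_hcpm`` HCPMs."""
        if n_hcp < 1 or n_hcpm < 1:
            raise ValueError("counts must be >= 1")
        if n_hcpm > n_hcp:
            raise ValueError("cannot attend more HCPMs than HCPs")
        return cls(
            (1.0 / n_hcp,) * n_hcp,
            (1.0 / n_hcpm,) * n_hcpm,
            label=f"equal {n_hcp} HCP / {n_hcpm} HCPM",
        )

    @property
    def n_hcp(self) -> int:
        return len(self.w)

    @property
    def n_hcpm(self) -> int:
        return len(self.omega)

    def sum_squares(self) -> tuple[float, float]:
        """Return (sum of w^2, sum of omega^2)."""
        return float(np.sum(np.square(self.w))), float(np.sum(np.square(self.omega)))


@dataclass(frozen=True)
class VpcResult:
    """Variance partition at a single care profile; VPCs are fractions."""

    total_variance: float
    vpc_individual: float
    vpc_hcp: float
    vpc_hcpm: float
    vpc_ind_mun: float
    profile: CareProfile = field(compare=False, default=CareProfile.single())

    def as_dict(self) -> dict[str, float]:
        return {
            "total_variance": self.total_variance,
            "individual": self.vpc_individual,
            "hcp": self.vpc_hcp,
            "hcpm": self.vpc_hcpm,
            "ind_mun": self.vpc_ind_mun,
        }


def total_variance(components: VarianceComponents, profile: CareProfile) -> float:
    """Profile-specific total outcome variance.

    For a single-membership profile this reduces to the plain sum of the
    four components.
    """
    sw2, so2 = profile.sum_squares()
    return (
        components.sigma2_ind_mun
        + components.sigma2_hcp * sw2
        + components.sigma2_hcpm * so2
        + components.sigma2_e
    )


def vpc(components: VarianceComponents, profile: CareProfile) -> VpcResult:
    """Partition the profile-specific total variance across the four levels.

    Returns fractions that sum to one. Raises if the total variance is zero.
    """
    sw2, so2 = profile.sum_squares()
    terms = {
        "individual": components.sigma2_e,
        "hcp": components.sigma2_hcp * sw2,
        "hcpm": components.sigma2_hcpm * so2,
        "ind_mun": components.sigma2_ind_mun,
    }
    total = sum(terms.values())
    if total <= 0:
        raise ValueError("total variance is zero; VPCs undefined")
    return VpcResult(
        total_variance=total,
        vpc_individual=terms["individual"] / total,
        vpc_hcp=terms["hcp"] / total,
        vpc_hcpm=terms["hcpm"] / total,
        vpc_ind_mun=terms["ind_mun"] / total,
        profile=profile,
    )


def explained_total_variance(
    vcm: VarianceComponents, full: VarianceComponents, profile: CareProfile
) -> float:
    """Relative reduction in total variance from the covariate-free model.

    ``1 - Var_full / Var_vcm`` at the given profile. May be negative when a
    component rises after adjustment (reported as an increase, not an error).
    """
    base = total_variance(vcm, profile)
    if base <= 0:
        raise ValueError("variance-component model total variance is zero")
    return 1.0 - total_variance(full, profile) / base


def component_reduction(
    vcm: VarianceComponents, full: VarianceComponents, level: str
) -> float:
    """Relative reduction of one variance component after adjustment.

    ``1 - full[level] / vcm[level]``; negative values indicate the component
    increased.
    """
    base = vcm[level]
    if base <= 0:
        raise ValueError(f"variance-component model has zero variance at {level!r}")
    return 1.0 - full[level] / base


# -- scenario grids --------------------------------------------------------

def _default_profiles(n_hcp_max: int = 6, n_hcpm_max: int = 3) -> list[CareProfile]:
    """The printed scenario families: single, equal splits, and the
    dominant-provider profile 0.75/0.12/0.12 (used verbatim)."""
    profiles: list[CareProfile] = []
    for n_hcp in range(1, n_hcp_max + 1):
        for n_hcpm in range(1, min(n_hcp, n_hcpm_max) + 1):
            profiles.append(CareProfile.equal(n_hcp, n_hcpm))
    dom = (0.75, 0.12, 0.12)
    if n_hcp_max >= 3:
        for n_hcpm in range(1, min(3, n_hcpm_max) + 1):
            omega = dom if n_hcpm == 3 else (1.0 / n_hcpm,) * n_hcpm
            profiles.append(
                CareProfile(dom, omega, label="dominant 0.75/0.12/0.12", literal=True)
            )
    return profiles


def scenario_grid(
    components: VarianceComponents,
    full: VarianceComponents | None = None,
    profiles: list[CareProfile] | None = None,
) -> pd.DataFrame:
    """Tabulate VPCs (and, optionally, explained variance) over profiles.

    Returns a long-format frame with one row per profile, suitable for
    plotting scenario figures. ``explained_pct`` is included when a second,
    covariate-adjusted component set is supplied.
    """
    if profiles is None:
        profiles = _default_profiles()
    rows = []
    for p in profiles:
        if p.n_hcpm > p.n_hcp:
            raise ValueError(f"profile {p.label!r} has more HCPMs than HCPs")
        res = vpc(components, p)
        row = {
            "n_hcp": p.n_hcp,
            "n_hcpm": p.n_hcpm,
            "w_profile": "/".join(f"{x:g}" for x in p.w),
            "omega_profile": "/".join(f"{x:g}" for x in p.omega),
            "label": p.label,
            "literal": p.literal,
            "total_var": res.total_variance,
            "vpc_individual": res.vpc_individual,
            "vpc_hcp": res.vpc_hcp,
            "vpc_hcpm": res.vpc_hcpm,
            "vpc_ind_mun": res.vpc_ind_mun,
        }
        if full is not None:
            row["explained_pct"] = 100.0 * explained_total_variance(
                components, full, p
            )
        rows.append(row)
    return pd.DataFrame(rows)
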