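"""Multiple-membership weight construction and weighted covariate aggregation.

Individuals receive care from several healthcare providers (HCPs) during the
study year. Each attended HCP gets a weight ``w`` equal to the share of the
individual's total care volume spent there; summing those weights over the
providers co-located in a municipality yields the provider-municipality
(HCPM) weights ``omega``. Both weight vectors sum to one per individual.

Tables are plain pandas DataFrames with documented columns:

* visits:       individual_id, hcp_id, care_units
* membership:   individual_id, hcp_id, weight_w
* HCPM weights: individual_id, municipality_id, weight_omega
* HCPs:         hcp_id, hcp_type, municipality_id, <covariates>
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vpc import CareProfile

__all__ = [
    "build_membership_table",
    "derive_hcpm_weights",
    "weight_sum_squares",
    "aggregate_weighted_covariates",
    "validate_membership",
]

HCP_TYPES = ("GP", "community", "hospital_department")

WEIGHT_SUM_TOL = 1e-12


class MembershipError(ValueError):
    """Invalid membership structure (weights, references, or care volumes)."""


def build_membership_table(visits: pd.DataFrame) -> pd.DataFrame:
    """Turn a long visit table into per-individual HCP care weights.

    Duplicate (individual, HCP) rows are summed before weighting, so weights
    are per unique provider. ``care_units`` may be any nonnegative measure of
    care volume (visits, episodes, or days) — the choice of unit is the
    caller's; weights are invariant to its scale within an individual.

    Raises
    ------
    MembershipError
        If any care_units is negative or an individual's total care is zero.
    """
    required = {"individual_id", "hcp_id", "care_units"}
    missing = required - set(visits.columns)
    if missing:
        raise MembershipError(f"visits table missing columns: {sorted(missing)}")
    if (visits["care_units"] < 0).any():
        bad = visits.loc[visits["care_units"] < 0, "individual_id"].unique()
        raise MembershipError(f"negative care_units for individuals: {list(bad)[:10]}")
    agg = (
        visits.groupby(["individual_id", "hcp_id"], sort=False, as_index=False)[
            "care_units"
        ].sum()
    )
    totals = agg.groupby("individual_id", sort=False)["care_units"].transform("sum")
    zero = totals == 0
    if zero.any():
        bad = agg.loc[zero, "individual_id"].unique()
        raise MembershipError(f"zero total care for individuals: {list(bad)[:10]}")
    out = agg.assign(weight_w=agg["care_units"] / totals).drop(columns="care_units")
    return out


def validate_membership(
    mt: pd.DataFrame,
    weight_col: str = "weight_w",
    tol: float = WEIGHT_SUM_TOL,
) -> None:
    """Check per-individual weights sum to 1 and lie in (0, 1]."""
    w = mt[weight_col]
    if ((w <= 0) | (w > 1 + tol)).any():
        raise MembershipError(f"{weight_col} values must lie in (0, 1]")
    sums = mt.groupby("individual_id")[weight_col].sum()
    off = sums[(sums - 1.0).abs() > 1e-9]
    if len(off):
        raise MembershipError(
            f"per-individual {weight_col} sums deviate from 1 for "
            f"{len(off)} individuals, e.g. {dict(off.head(5))}"
        )


def derive_hcpm_weights(mt: pd.DataFrame, hcps: pd.DataFrame) -> pd.DataFrame:
    """Aggregate HCP weights into provider-municipality (HCPM) weights.

    omega_{i,k} is the sum of w_{i,j} over the HCPs j located in municipality
    k, i.e. the share of the individual's care received in that municipality.
    """
    unknown = set(mt["hcp_id"]) - set(hcps["hcp_id"])
    if unknown:
        raise MembershipError(f"hcp_ids not in HCP table: {sorted(unknown)[:10]}")
    loc = hcps.set_index("hcp_id")["municipality_id"]
    merged = mt.assign(municipality_id=mt["hcp_id"].map(loc))
    out = (
        merged.groupby(["individual_id", "municipality_id"], sort=False, as_index=False)[
            "weight_w"
        ]
        .sum()
        .rename(columns={"weight_w": "weight_omega"})
    )
    return out


def weight_sum_squares(
    mt: pd.DataFrame | CareProfile,
    hcpm_mt: pd.DataFrame | None = None,
) -> pd.DataFrame | tuple[float, float]:
    """Sums of squared membership weights, the kernel of the total-variance
    formula.

    For a :class:`~mmhurdle.vpc.CareProfile`, returns the pair
    ``(sum w^2, sum omega^2)``. For membership tables, returns a frame with
    one row per individual and columns ``sum_w2`` (and ``sum_omega2`` when
    the HCPM table is supplied). Each sum lies in (0, 1].
    """
    if isinstance(mt, CareProfile):
        return mt.sum_squares()
    sw2 = (
        mt.assign(sq=mt["weight_w"] ** 2)
        .groupby("individual_id")["sq"]
        .sum()
        .rename("sum_w2")
    )
    out = sw2.reset_index()
    if hcpm_mt is not None:
        so2 = (
            hcpm_mt.assign(sq=hcpm_mt["weight_omega"] ** 2)
            .groupby("individual_id")["sq"]
            .sum()
            .rename("sum_omega2")
        )
        out = out.merge(so2.reset_index(), on="individual_id", how="outer")
    return out


def _weighted_aggregate(
    weights: pd.DataFrame,
    units: pd.DataFrame,
    unit_id: str,
    weight_col: str,
    covariates: list[str],
    prefix: str,
) -> pd.DataFrame:
    sub = units.set_index(unit_id)[covariates]
    na_units = sub.index[sub.isna().any(axis=1)]
    used = set(weights[unit_id])
    offending = [u for u in na_units if u in used]
    if offending:
        raise MembershipError(
            f"missing covariate values for units: {offending[:10]} "
            "(no silent imputation)"
        )
    merged = weights.merge(
        sub, left_on=unit_id, right_index=True, how="left", validate="m:1"
    )
    for c in covariates:
        merged[c] = merged[c] * merged[weight_col]
    agg = merged.groupby("individual_id")[covariates].sum()
    return agg.add_prefix(prefix)


def aggregate_weighted_covariates(
    mt: pd.DataFrame,
    hcps: pd.DataFrame,
    municipalities: pd.DataFrame | None = None,
    hcp_covariates: list[str] | None = None,
    hcpm_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-individual weighted averages of provider and provider-municipality
    covariates.

    HCP covariates are averaged with the w weights, municipality covariates
    with the derived omega weights; columns are prefixed ``hcp_`` and
    ``hcpm_``. Missing covariate values on any referenced unit raise.
    """
    if hcp_covariates is None:
        hcp_covariates = [
            c for c in hcps.columns if c not in ("hcp_id", "hcp_type", "municipality_id")
        ]
    parts = []
    if hcp_covariates:
        parts.append(
            _weighted_aggregate(mt, hcps, "hcp_id", "weight_w", hcp_covariates, "hcp_")
        )
    if municipalities is not None:
        if hcpm_covariates is None:
            hcpm_covariates = [
                c for c in municipalities.columns if c != "municipality_id"
            ]
        omega = derive_hcpm_weights(mt, hcps)
        if hcpm_covariates:
            parts.append(
                _weighted_aggregate(
                    omega,
                    municipalities,
                    "municipality_id",
                    "weight_omega",
                    hcpm_covariates,
                    "hcpm_",
                )
            )
    if not parts:
        raise MembershipError("no covariates to aggregate")
    out = parts[0]
    for p in parts[1:]:
        out = out.join(p, how="outer")
    return out.reset_index()
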