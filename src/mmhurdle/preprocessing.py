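"""Outcome transformation, outlier exclusion, and subgroup filters.

The raw outcome is a yearly count of psychiatric inpatient hospitalisations.
The magnitude part of the hurdle model is fitted to the natural-log count,
standardised to mean zero and unit SD over the hospitalised subset (the only
individuals that part sees). Exclusion rules mirror the study design:
individuals attending more than 13 distinct providers or more than 7
distinct provider municipalities are dropped as outliers, and an optional
extreme-case rule removes very large outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .membership import derive_hcpm_weights

__all__ = [
    "TransformedOutcome",
    "transform_outcome",
    "apply_exclusions",
    "subgroup_filter",
    "SUBGROUP_SPECS",
]


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class TransformedOutcome:
    """Standardised log counts for the hospitalised subset.

    ``z = (ln y - mean_log) / sd_log`` computed over individuals with y > 0;
    the transform parameters are retained so counts can be recovered.
    """

    table: pd.DataFrame  # individual_id, z
    mean_log: float
    sd_log: float

    @property
    def z(self) -> pd.Series:
        return self.table.set_index("individual_id")["z"]

    def inverse(self, z: np.ndarray | pd.Series) -> np.ndarray:
        """Map standardised values back to the count scale (not rounded)."""
        return np.exp(self.mean_log + self.sd_log * np.asarray(z, dtype=float))


def transform_outcome(
    individuals: pd.DataFrame, count_col: str = "n_hospitalisations"
) -> TransformedOutcome:
    """Log-linearise and standardise the count outcome over the hospitalised
    subset.

    Natural logs are used; since the result is standardised, the base only
    affects the stored transform parameters, not the fitted model.
    """
    y = individuals.loc[individuals[count_col] > 0, ["individual_id", count_col]]
    if len(y) == 0:
        raise PreprocessingError("no hospitalised individuals; outcome all zero")
    if len(y) < 2:
        raise PreprocessingError("need at least two hospitalised individuals")
    logs = np.log(y[count_col].to_numpy(dtype=float))
    m = float(logs.mean())
    s = float(logs.std(ddof=1))
    if s == 0.0:
        raise PreprocessingError(
            "log counts are constant over the hospitalised subset; "
            "standardisation undefined"
        )
    table = pd.DataFrame({"individual_id": y["individual_id"], "z": (logs - m) / s})
    return TransformedOutcome(table=table.reset_index(drop=True), mean_log=m, sd_log=s)


def apply_exclusions(
    individuals: pd.DataFrame,
    mt: pd.DataFrame,
    hcps: pd.DataFrame,
    max_hcps: int = 13,
    max_hcpms: int = 7,
    extreme_threshold: float | None = None,
    extreme_scale: str = "z",
    count_col: str = "n_hospitalisations",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop outlier individuals and report what was removed.

    Rules, applied jointly (an individual is dropped if any rule fires):

    * more than ``max_hcps`` distinct providers (default 13);
    * more than ``max_hcpms`` distinct provider municipalities (default 7);
    * optionally, extreme outcomes: ``extreme_scale="z"`` removes
      |standardised log count| > threshold, ``"count"`` removes raw counts
      above the threshold. Off by default.

    Returns the filtered individual table, the filtered membership table
    (all rows of retained individuals, values untouched), and a report dict.
    """
    n_hcps = mt.groupby("individual_id")["hcp_id"].nunique()
    omega = derive_hcpm_weights(mt, hcps)
    n_hcpms = omega.groupby("individual_id")["municipality_id"].nunique()

    ids = individuals["individual_id"]
    drop_hcp = ids.map(n_hcps).fillna(0) > max_hcps
    drop_hcpm = ids.map(n_hcpms).fillna(0) > max_hcpms

    drop_extreme = pd.Series(False, index=individuals.index)
    if extreme_threshold is not None:
        if extreme_scale == "z":
            t = transform_outcome(individuals, count_col=count_col)
            zmap = t.z
            drop_extreme = ids.map(zmap).abs() > extreme_threshold
            drop_extreme = drop_extreme.fillna(False)
        elif extreme_scale == "count":
            drop_extreme = individuals[count_col] > extreme_threshold
        else:
            raise PreprocessingError(
                f"extreme_scale must be 'z' or 'count', got {extreme_scale!r}"
            )

    keep = ~(drop_hcp | drop_hcpm | drop_extreme)
    out_ind = individuals.loc[keep].copy()
    out_mt = mt[mt["individual_id"].isin(out_ind["individual_id"])].copy()
    report = {
        "n_input": int(len(individuals)),
        "removed_too_many_hcps": int(drop_hcp.sum()),
        "removed_too_many_hcpms": int(drop_hcpm.sum()),
        "removed_extreme": int(drop_extreme.sum()),
        "n_output": int(len(out_ind)),
    }
    if len(out_ind) == 0:
        import warnings

        warnings.warn("all individuals excluded", stacklevel=2)
    return out_ind, out_mt, report


# Named subgroup rules. Diagnosis groups enter as precomputed 0/1 indicator
# columns (dx_*); no ICD parsing happens here.
SUBGROUP_SPECS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "exclude_organic_intellectual_developmental": lambda df: ~(
        df["dx_organic"].astype(bool)
        | df["dx_intellectual"].astype(bool)
        | df["dx_developmental"].astype(bool)
    ),
    "schizophrenia_or_mood_only": lambda df: (
        df["dx_schizophrenia"].astype(bool) | df["dx_mood"].astype(bool)
    ),
    "exclude_new_in_2016": lambda df: ~df["new_in_2016"].astype(bool),
}


def subgroup_filter(
    individuals: pd.DataFrame,
    spec: str | Callable[[pd.DataFrame], pd.Series],
) -> pd.DataFrame:
    """Row-select a named subgroup, or apply an arbitrary boolean predicate.

    Filtering is pure row selection; retained rows are returned unchanged.
    """
    if callable(spec):
        mask = spec(individuals)
    else:
        try:
            rule = SUBGROUP_SPECS[spec]
        except KeyError:
            raise PreprocessingError(
                f"unknown subgroup spec {spec!r}; valid specs: "
                f"{sorted(SUBGROUP_SPECS)}"
            ) from None
        mask = rule(individuals)
    return individuals.loc[np.asarray(mask, dtype=bool)].copy()
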