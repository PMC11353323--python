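"""Alternative random structures and model comparison.

The robustness battery fits the magnitude model under simpler random
structures and compares them: the full four-component MMMC model, the same
without the provider-municipality level, a cross-classified model that
pretends each individual is nested in a single ("main", largest-weight)
provider, a multiple-membership model with providers only, and a
single-level regression. Nested pairs are compared by likelihood-ratio
tests (with the 50:50 chi-square mixture for a variance tested on its
boundary); non-nested pairs by AIC/BIC only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .lmm import MMMCDesign, MMMCFit, build_design

__all__ = ["STRUCTURES", "fit_alternative", "compare", "ModelComparison"]

#: random blocks per named structure
STRUCTURES: dict[str, tuple[str, ...]] = {
    "mmmc_full": ("ind_mun", "hcp", "hcpm"),
    "mmmc_no_hcpm": ("ind_mun", "hcp"),
    "cross_classified": ("ind_mun", "hcp_main"),
    "mm_only": ("hcp",),
    "single_level": (),
}

# pairs (general, restricted) where the restricted model is the general one
# with some variance components pinned at zero
_NESTED: list[tuple[str, str]] = [
    ("mmmc_full", "mmmc_no_hcpm"),
    ("mmmc_full", "mm_only"),
    ("mmmc_full", "single_level"),
    ("mmmc_no_hcpm", "mm_only"),
    ("mmmc_no_hcpm", "single_level"),
    ("mm_only", "single_level"),
    ("cross_classified", "single_level"),
]


@dataclass
class ModelComparison:
    """AIC/BIC table plus LRTs for the declared nested pairs."""

    table: pd.DataFrame
    lrt: pd.DataFrame

    def best(self, criterion: str = "aic") -> str:
        return self.table.sort_values(criterion).iloc[0]["model"]


def fit_alternative(
    z,
    individuals: pd.DataFrame,
    mt: pd.DataFrame,
    hcpm_mt: pd.DataFrame,
    structure: str,
    covariates: list[str] | None = None,
    residence_col: str = "residence_municipality_id",
    reml: bool = False,
    n_starts: int = 3,
) -> MMMCFit:
    """Fit one named alternative random structure.

    ``single_level`` has no random blocks and reduces to ordinary least
    squares (same code path, closed-form-equivalent likelihood).
    """
    try:
        blocks = STRUCTURES[structure]
    except KeyError:
        raise ValueError(
            f"unknown structure {structure!r}; valid: {sorted(STRUCTURES)}"
        ) from None
    design = build_design(
        z, individuals, mt, hcpm_mt, covariates, residence_col, structure=blocks
    )
    fit = design.fit(reml=reml, n_starts=max(1, n_starts if blocks else 1))
    fit.design_summary["structure_name"] = structure
    return fit


def compare(fits: dict[str, MMMCFit]) -> ModelComparison:
    """Compare fits of different random structures on identical data.

    Raises when the fits' data fingerprints differ (they must share the
    response and fixed-effect design). LRT statistics use 2*(ll_general -
    ll_restricted); for a single boundary variance component the p-value is
    the 50:50 mixture of chi2_0 and chi2_1, flagged in the output; larger
    df use the plain chi-square and are flagged as conservative.
    """
    prints = {f.data_fingerprint for f in fits.values()}
    if len(prints) > 1:
        raise ValueError("fits were computed on different data (fingerprint mismatch)")
    rows = [
        {
            "model": name,
            "loglik": f.loglik,
            "k_params": f.k_params,
            "aic": f.aic,
            "bic": f.bic,
        }
        for name, f in fits.items()
    ]
    table = pd.DataFrame(rows)

    lrt_rows = []
    for general, restricted in _NESTED:
        if general not in fits or restricted not in fits:
            continue
        fg, fr = fits[general], fits[restricted]
        stat = 2.0 * (fg.loglik - fr.loglik)
        stat = max(stat, 0.0)  # clip tiny negative optimisation noise
        df = fg.k_params - fr.k_params
        boundary = True  # variance components are tested on their boundary
        if df == 1:
            p = 0.5 * chi2.sf(stat, 1)
        else:
            p = chi2.sf(stat, df)
        lrt_rows.append(
            {
                "general": general,
                "restricted": restricted,
                "statistic": stat,
                "df": df,
                "p_value": p,
                "boundary_corrected": boundary and df == 1,
            }
        )
    lrt = pd.DataFrame(
        lrt_rows,
        columns=["general", "restricted", "statistic", "df", "p_value",
                 "boundary_corrected"],
    )
    return ModelComparison(table=table, lrt=lrt)
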