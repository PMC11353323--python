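"""Model checking: normality of empirical-Bayes predictions and
correlation screens across unit-level characteristics.

Multilevel models assume normal random effects; a standard check predicts
the empirical Bayes (BLUP) effects per level and inspects their moments and
quantile-quantile behaviour. The correlation screen tabulates pairwise
Pearson correlations between chosen unit characteristics (directions only —
no p-values are attached, by design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MMMCDesign, MMMCFit

__all__ = ["check_random_effect_normality", "correlation_matrix"]

_DEGENERATE_TOL = 1e-8


def check_random_effect_normality(
    fit: MMMCFit, design: MMMCDesign, n_qq: int = 50
) -> dict:
    """Per-level normality summaries of the empirical Bayes predictions.

    Returns, for each random-effect level and for the residuals: sample
    moments (skewness, excess kurtosis), plot-ready theoretical/sample
    quantile pairs, and a ``degenerate`` flag for levels whose fitted
    variance is at the boundary (their predictions are identically zero).
    The report depends on unit values only, not unit labels.
    """
    eb = design.empirical_bayes(fit)
    report: dict[str, dict] = {}
    for level, frame in eb.items():
        values = (
            frame["standardised"] if level == "residual" else frame["eb_mean"]
        ).to_numpy(dtype=float)
        degenerate = (
            level != "residual" and fit.components[level] < _DEGENERATE_TOL
        )
        section: dict = {
            "n": int(len(values)),
            "degenerate": bool(degenerate),
        }
        if degenerate or len(values) < 3 or np.allclose(values, values[0]):
            section.update(skewness=None, excess_kurtosis=None, qq=None)
        else:
            probs = (np.arange(1, n_qq + 1) - 0.5) / n_qq
            sd = values.std(ddof=1)
            section.update(
                skewness=float(stats.skew(values)),
                excess_kurtosis=float(stats.kurtosis(values)),
                qq={
                    "theoretical": stats.norm.ppf(probs).tolist(),
                    "sample": np.quantile(
                        (values - values.mean()) / sd, probs
                    ).tolist(),
                },
            )
        report[level] = section
    return report


def correlation_matrix(
    units: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations with pairwise-complete observations.

    Returns (correlations, pairwise sample sizes, constant variables).
    Constant variables have undefined correlations; their entries are left
    missing and their names reported rather than propagating NaN silently.
    """
    if len(units) < 3:
        raise ValueError("need at least three units")
    missing = [v for v in variables if v not in units.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    sub = units[variables].astype(float)
    constant = [
        v for v in variables if sub[v].dropna().nunique() <= 1
    ]
    corr = pd.DataFrame(np.nan, index=variables, columns=variables)
    ns = pd.DataFrame(0, index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i:]:
            pair = sub[[a, b]].dropna()
            ns.loc[a, b] = ns.loc[b, a] = len(pair)
            if a in constant or b in constant:
                continue
            if a == b:
                corr.loc[a, b] = 1.0
                continue
            r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            corr.loc[a, b] = corr.loc[b, a] = r
    return corr, ns, constant
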