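"""High-level analysis pipelines composing the fitting, weighting and
estimation steps.

These are the entry points a typical analysis uses: build the weight set
for one (estimand, method) pair, or run the four-method comparison
(pooled full PS, SES-stratum-specific health-status PS, pooled
health-status PS, deweighting) across the ATE/ATT/ATO estimands.
"""

from __future__ import annotations

import pandas as pd

from .data_model import DisparityDataset
from .estimation import DisparityEstimate, estimate_disparity, unadjusted_difference
from .propensity import (
    fit_full_ps_pooled,
    fit_health_status_ps,
    fit_ses_ps_saturated,
    fit_stratified_full_ps,
)
from .weights import WeightSet, comparator_weights, deweighting_weights

__all__ = ["build_weights", "analyze", "four_method_comparison", "METHODS"]

METHODS = ("full_ps", "sshs_ps", "health_ps", "deweighting")


def build_weights(
    data: DisparityDataset,
    estimand: str = "att",
    method: str = "deweighting",
    ps_method: str = "cbps",
) -> WeightSet:
    """Fit the propensity scores a method needs and return its weight set.

    ``deweighting`` divides SSHS-PS balancing weights (stratified full PS)
    by saturated SES-PS balancing weights; the three comparators apply
    plain balancing weights to their named propensity score.
    """
    if method == "deweighting":
        e_full = fit_stratified_full_ps(data, estimator=ps_method, estimand=estimand)
        e_ses = fit_ses_ps_saturated(data)
        return deweighting_weights(e_full, e_ses, estimand)
    if method == "sshs_ps":
        e = fit_stratified_full_ps(data, estimator=ps_method, estimand=estimand)
    elif method == "full_ps":
        e = fit_full_ps_pooled(data, estimator=ps_method, estimand=estimand)
    elif method == "health_ps":
        e = fit_health_status_ps(data, estimator=ps_method, estimand=estimand)
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return comparator_weights(e, estimand, method)


def analyze(
    data: DisparityDataset,
    estimand: str = "att",
    method: str = "deweighting",
    ps_method: str = "cbps",
    level: float = 0.95,
) -> tuple[DisparityEstimate, WeightSet]:
    """One (estimand, method) disparity analysis: weights plus estimate."""
    w = build_weights(data, estimand, method, ps_method)
    return estimate_disparity(data, w, level=level), w


def four_method_comparison(
    data: DisparityDataset,
    estimands: tuple[str, ...] = ("ate", "att", "ato"),
    ps_method: str = "cbps",
    percent: bool | None = None,
) -> pd.DataFrame:
    """Disparity estimates for every method × estimand, plus the crude row.

    Returns a table with the point estimate and 95% interval per row,
    scaled to percentage points when the outcome is binary (matching how
    such comparisons are conventionally reported).
    """
    if percent is None:
        percent = data.outcome_is_binary
    rows = [unadjusted_difference(data).summary(percent=percent)]
    for estimand in estimands:
        for method in METHODS:
            est, _ = analyze(data, estimand, method, ps_method)
            rows.append(est.summary(percent=percent))
    return pd.DataFrame(rows)
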