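"""Disparity point estimates, confidence intervals and weighted Table-1s.

The disparity estimate is the Hájek difference of weighted outcome means,

    τ̂_g = Σ ω₁(Xᵢ) Zᵢ Yᵢ / Σ ω₁(Xᵢ) Zᵢ  −  Σ ω₀(Xᵢ)(1−Zᵢ)Yᵢ / Σ ω₀(Xᵢ)(1−Zᵢ),

a ratio form invariant to rescaling either group's weights.  Standard
errors use Taylor linearization of each Hájek mean treating the weights as
fixed (the behaviour of standard survey software); uncertainty from
propensity-score estimation is not propagated.  A subject-resampling
bootstrap is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DisparityDataset
from .errors import ValidationError
from .weights import WeightSet

__all__ = [
    "DisparityEstimate",
    "WeightedCharacteristics",
    "estimate_disparity",
    "unadjusted_difference",
    "ci_weighted",
    "bootstrap_se",
    "weighted_characteristics",
]


@dataclass
class DisparityEstimate:
    """Point estimate and interval for a weighted average controlled difference.

    ``tau_hat = mu1_hat - mu0_hat`` on the raw outcome scale.  For binary
    outcomes :meth:`summary` reports percentage points (×100).
    """

    tau_hat: float
    mu1_hat: float
    mu0_hat: float
    se: float
    ci_low: float
    ci_high: float
    estimand: str
    method: str
    level: float = 0.95
    p_value: float | None = None

    def summary(self, percent: bool = True) -> dict:
        """Flat dict of the estimate; ``percent`` scales ×100 (pp)."""
        s = 100.0 if percent else 1.0
        out = {
            "estimand": self.estimand,
            "method": self.method,
            "estimate": self.tau_hat * s,
            "se": self.se * s,
            "ci_low": self.ci_low * s,
            "ci_high": self.ci_high * s,
        }
        if self.p_value is not None:
            out["p_value"] = self.p_value
        return out


def _hajek(y: np.ndarray, w: np.ndarray) -> float:
    total = w.sum()
    if total <= 0:
        raise ValidationError("zero total weight in a group")
    return float(np.sum(w * y) / total)


def _linearized_var(y: np.ndarray, w: np.ndarray) -> float:
    """Taylor-linearization variance of a Hájek mean with fixed weights.

    V = Σ w²(y − μ̂)² / (Σw)².  With unit weights this is the n-divisor
    variance of the sample mean (the n−1 → n convention).
    """
    if len(y) < 2:
        raise ValidationError("variance undefined for a single-subject group")
    mu = _hajek(y, w)
    return float(np.sum(w**2 * (y - mu) ** 2) / w.sum() ** 2)


def ci_weighted(
    data: DisparityDataset, w: WeightSet, level: float = 0.95
) -> tuple[float, float, float]:
    """Standard error and normal-quantile interval for the weighted difference.

    Groups are treated as independent: Var(τ̂) = V₁ + V₀ with each V the
    linearization variance of that group's Hájek mean.
    """
    if len(w) != data.n_subjects:
        raise ValidationError("weights not aligned with the dataset")
    m = data.Z == 1
    mu1 = _hajek(data.Y[m], w.omega1[m])
    mu0 = _hajek(data.Y[~m], w.omega0[~m])
    var = _linearized_var(data.Y[m], w.omega1[m]) + _linearized_var(
        data.Y[~m], w.omega0[~m]
    )
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(0.5 + level / 2)
    tau = mu1 - mu0
    return se, tau - zq * se, tau + zq * se


def estimate_disparity(
    data: DisparityDataset, w: WeightSet, level: float = 0.95
) -> DisparityEstimate:
    """Hájek difference of weighted outcome means with a normal interval."""
    if len(w) != data.n_subjects:
        raise ValidationError("weights not aligned with the dataset")
    m = data.Z == 1
    mu1 = _hajek(data.Y[m], w.omega1[m])
    mu0 = _hajek(data.Y[~m], w.omega0[~m])
    se, lo, hi = ci_weighted(data, w, level=level)
    return DisparityEstimate(
        tau_hat=mu1 - mu0,
        mu1_hat=mu1,
        mu0_hat=mu0,
        se=se,
        ci_low=lo,
        ci_high=hi,
        estimand=w.estimand,
        method=w.method,
        level=level,
    )


def unadjusted_difference(
    data: DisparityDataset, level: float = 0.95
) -> DisparityEstimate:
    """Crude (unweighted) group difference in outcome means.

    For a binary outcome the interval and p-value use the two-proportion
    normal approximation with n-divisor variances; for a continuous
    outcome the same linearized variance applies but no p-value is
    attached.
    """
    m = data.Z == 1
    y1, y0 = data.Y[m], data.Y[~m]
    mu1, mu0 = float(y1.mean()), float(y0.mean())
    var = y1.var(ddof=0) / len(y1) + y0.var(ddof=0) / len(y0)
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(0.5 + level / 2)
    tau = mu1 - mu0
    p_value = None
    if data.outcome_is_binary:
        if se > 0:
            p_value = float(2 * stats.norm.sf(abs(tau) / se))
        else:
            p_value = 1.0 if tau == 0 else 0.0
    return DisparityEstimate(
        tau_hat=tau,
        mu1_hat=mu1,
        mu0_hat=mu0,
        se=se,
        ci_low=tau - zq * se,
        ci_high=tau + zq * se,
        estimand="unadjusted",
        method="unadjusted",
        level=level,
        p_value=p_value,
    )


def bootstrap_se(
    data: DisparityDataset,
    w: WeightSet,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Bootstrap SE of τ̂ resampling subjects within each group.

    Weights travel with their subjects (they are treated as fixed
    characteristics), matching the linearization estimator's frame of
    reference.
    """
    rng = np.random.default_rng(seed)
    m = data.Z == 1
    y1, w1 = data.Y[m], w.omega1[m]
    y0, w0 = data.Y[~m], w.omega0[~m]
    n1, n0 = len(y1), len(y0)
    taus = np.empty(n_boot)
    for b in range(n_boot):
        i1 = rng.integers(0, n1, n1)
        i0 = rng.integers(0, n0, n0)
        taus[b] = _hajek(y1[i1], w1[i1]) - _hajek(y0[i0], w0[i0])
    return float(taus.std(ddof=1))


@dataclass
class WeightedCharacteristics:
    """Weighted covariate means in the target populations (weighted Table-1).

    ``table`` has one row per covariate with the weighted minority mean
    (m₁), weighted majority mean (m₀) and raw group means; ``n1_weighted``
    and ``n0_weighted`` are the weighted group totals (sums of weights) —
    the "N" rows of a weighted characteristics table.
    """

    table: pd.DataFrame
    n1_weighted: float
    n0_weighted: float
    n1: int
    n0: int


def weighted_characteristics(
    data: DisparityDataset, w: WeightSet, covariates: list[str] | None = None
) -> WeightedCharacteristics:
    """Weighted means of covariates under a weight set (m₁ and m₀).

    Each covariate mean is the Hájek mean with outcome replaced by the
    covariate.  SES covariates are included as numeric indicators (binary
    categorical columns map to 0/1); with unit weights the output equals
    the raw group means.
    """
    if len(w) != data.n_subjects:
        raise ValidationError("weights not aligned with the dataset")
    frame = pd.concat(
        [
            _numeric_ses(data.X_s).reset_index(drop=True),
            data.X_h.reset_index(drop=True),
        ],
        axis=1,
    )
    if covariates is not None:
        frame = frame[list(covariates)]
    m = data.Z == 1
    w1, w0 = w.omega1[m], w.omega0[~m]
    rows = []
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        rows.append(
            {
                "covariate": col,
                "m1": _hajek(x[m], w1),
                "m0": _hajek(x[~m], w0),
                "raw_mean_minority": float(x[m].mean()),
                "raw_mean_majority": float(x[~m].mean()),
            }
        )
    return WeightedCharacteristics(
        table=pd.DataFrame(rows).set_index("covariate"),
        n1_weighted=float(w1.sum()),
        n0_weighted=float(w0.sum()),
        n1=int(m.sum()),
        n0=int((~m).sum()),
    )


def _numeric_ses(X_s: pd.DataFrame) -> pd.DataFrame:
    """SES columns as numeric indicators (binary → 0/1, else one per level)."""
    out = {}
    for col in X_s.columns:
        s = X_s[col]
        if np.issubdtype(s.dtype, np.number):
            out[col] = s.astype(float)
            continue
        levels = sorted(map(str, s.unique()))
        if len(levels) == 2:
            out[col] = (s.astype(str) == levels[1]).astype(float)
        else:
            for lev in levels:
                out[f"{col}_{lev}"] = (s.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=X_s.index)
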