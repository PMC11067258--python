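"""Balancing weights, tilting functions and the deweighting construction.

A selection function ``g(e)`` fixes the target population of a weighted
comparison: ``g = 1`` targets the combined population (ATE), ``g = e`` the
minority population (ATT) and ``g = e(1−e)`` the overlap population (ATO).
The balancing weights tilt each group toward that population:

    ω₁ᴮ(x) = g(e(x)) / e(x),     ω₀ᴮ(x) = g(e(x)) / (1 − e(x)).

Deweighting divides the full-PS balancing weights by the analogous weights
built from the SES-only propensity score,

    ω₁(x) = ω₁ᴮ(x) / ω₁ᴮ(xˢ),    ω₀(x) = ω₀ᴮ(x) / ω₀ᴮ(xˢ),

which preserves each group's marginal SES distribution while balancing the
conditional distribution of health status given SES.  All downstream
estimators are ratio (Hájek) forms, so weights are stored unnormalized and
every result is invariant to rescaling either group's weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PositivityError, ValidationError
from .propensity import PropensityVector

__all__ = [
    "SELECTION_FUNCTIONS",
    "selection_function",
    "balancing_weights",
    "deweighting_weights",
    "comparator_weights",
    "weight_summary",
    "WeightSet",
]

#: The three tilting functions analysed: combined (ate), minority (att)
#: and overlap (ato) target populations.
SELECTION_FUNCTIONS = {
    "ate": lambda e: np.ones_like(e),
    "att": lambda e: e,
    "ato": lambda e: e * (1.0 - e),
}

COMPARATOR_METHODS = ("full_ps", "sshs_ps", "health_ps")


def selection_function(name: str):
    """Return the tilting function ``g(e)`` for a named estimand."""
    try:
        return SELECTION_FUNCTIONS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown estimand {name!r}; choose from {sorted(SELECTION_FUNCTIONS)}"
        ) from None


@dataclass
class WeightSet:
    """Per-subject minority (ω₁) and majority (ω₀) weights.

    Both arrays cover every subject; ω₁ is meaningful for minority rows and
    ω₀ for majority rows.  Weights are unnormalized (scale-free): every
    estimator and diagnostic downstream is a ratio form.
    """

    omega1: np.ndarray
    omega0: np.ndarray
    estimand: str
    method: str

    def __post_init__(self):
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.omega0 = np.asarray(self.omega0, dtype=float)
        if self.omega1.shape != self.omega0.shape:
            raise ValidationError("omega1 and omega0 must have equal length")
        for name, w in (("omega1", self.omega1), ("omega0", self.omega0)):
            if np.any(~np.isfinite(w)):
                raise ValidationError(f"{name} contains non-finite weights")
            if np.any(w < 0):
                raise ValidationError(f"{name} contains negative weights")

    def __len__(self) -> int:
        return len(self.omega1)

    def to_frame(self, Z: np.ndarray | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"omega1": self.omega1, "omega0": self.omega0})
        if Z is not None:
            out.insert(0, "Z", np.asarray(Z))
        return out


def _as_probs(e) -> np.ndarray:
    vals = e.values if isinstance(e, PropensityVector) else np.asarray(e, float)
    if np.any((vals <= 0.0) | (vals >= 1.0)):
        raise PositivityError(
            "propensity scores at 0 or 1 produce infinite balancing weights"
        )
    return vals


def balancing_weights(e, estimand: str = "ate") -> tuple[np.ndarray, np.ndarray]:
    """Balancing weights (ω₁ᴮ, ω₀ᴮ) = (g(e)/e, g(e)/(1−e)) for one PS.

    ATE → (1/e, 1/(1−e)); ATT → (1, e/(1−e)); ATO → (1−e, e).
    """
    e = _as_probs(e)
    g = selection_function(estimand)(e)
    return g / e, g / (1.0 - e)


def deweighting_weights(e_full, e_ses, estimand: str = "ate") -> WeightSet:
    """Deweighting weights: full-PS balancing weights over SES-PS ones.

    Specializations (recovered algebraically from the ratio):
    ATE → (e(xˢ)/e(x), (1−e(xˢ))/(1−e(x)));
    ATT → (1, [e(x)/(1−e(x))]·[(1−e(xˢ))/e(xˢ)]);
    ATO → ((1−e(x))/(1−e(xˢ)), e(x)/e(xˢ)).
    """
    ef = _as_probs(e_full)
    es = _as_probs(e_ses)
    if ef.shape != es.shape:
        raise ValidationError(
            "full-PS and SES-PS vectors cover different subject sets "
            f"({ef.shape[0]} vs {es.shape[0]})"
        )
    b1_full, b0_full = balancing_weights(ef, estimand)
    b1_ses, b0_ses = balancing_weights(es, estimand)
    w = WeightSet(
        omega1=b1_full / b1_ses,
        omega0=b0_full / b0_ses,
        estimand=estimand.lower(),
        method="deweighting",
    )
    if estimand.lower() == "att":
        # g(e) = e makes ω₁ᴮ ≡ 1 for both scores; enforce the identity
        # exactly rather than leaving it to floating-point division.
        w.omega1 = np.ones_like(w.omega1)
    return w


def comparator_weights(e, estimand: str = "ate", method: str = "sshs_ps") -> WeightSet:
    """Plain balancing weights for a named comparator propensity score.

    ``full_ps`` (pooled all-covariate PS), ``sshs_ps`` (stratum-specific
    health-status PS) and ``health_ps`` (pooled health-status PS) weight by
    g(e)/e and g(e)/(1−e) without deweighting; these are the standard
    comparators against which deweighting is judged.
    """
    if method not in COMPARATOR_METHODS:
        raise ValueError(
            f"unknown comparator {method!r}; choose from {COMPARATOR_METHODS}"
        )
    b1, b0 = balancing_weights(e, estimand)
    return WeightSet(omega1=b1, omega0=b0, estimand=estimand.lower(), method=method)


def weight_summary(
    w: WeightSet, Z: np.ndarray, flag_multiple: float = 10.0
) -> pd.DataFrame:
    """Effective sample sizes and dispersion of the weights per group.

    ESS = (Σw)²/Σw² within each group; weights larger than
    ``flag_multiple`` times the group mean are counted as extreme.
    """
    Z = np.asarray(Z).astype(bool)
    rows = []
    for label, wv in (("minority", w.omega1[Z]), ("majority", w.omega0[~Z])):
        if wv.size == 0:
            raise ValidationError(f"{label} group is empty")
        total = wv.sum()
        ess = total**2 / np.sum(wv**2)
        mean = wv.mean()
        rows.append(
            {
                "group": label,
                "n": wv.size,
                "ess": ess,
                "min": wv.min(),
                "max": wv.max(),
                "cv": wv.std(ddof=0) / mean if mean > 0 else np.nan,
                "n_extreme": int(np.sum(wv > flag_multiple * mean)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
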