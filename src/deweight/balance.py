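"""IOM-concordance balance diagnostics.

Four absolute-standardized-mean-difference (ASMD) metrics summarize what a
weight set does to the data:

* ``D``   — weighted between-group ASMD of a covariate (the standard
  diagnostic), denominated by the pooled *unweighted* group SDs;
* ``D₁``  — how much the minority weights alter the minority SES
  distribution: |unweighted − weighted minority mean| / unweighted
  minority SD, per SES covariate;
* ``D₀``  — the majority analogue;
* ``D_r`` — between-group ASMD of each health covariate *within* SES
  subgroup r, denominated by pooled unweighted within-subgroup SDs.

IOM concordance asks that D₁ and D₀ be small (SES preserved) while D_r is
small in every subgroup (health status balanced conditional on SES).  Any
value above the conventional 0.1 threshold flags the weight set as not
IOM-concordant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DisparityDataset
from .errors import ValidationError
from .estimation import _numeric_ses
from .weights import WeightSet

__all__ = [
    "BalanceReport",
    "asmd_between",
    "ses_alteration",
    "subgroup_health_balance",
    "concordance_report",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.1


def _sd(x: np.ndarray) -> float:
    """Unweighted sample SD (ddof=1); 0.0 for degenerate groups."""
    return float(np.std(x, ddof=1)) if len(x) >= 2 else 0.0


def _covariate_frame(
    data: DisparityDataset, covariates: list[str] | None
) -> pd.DataFrame:
    frame = pd.concat(
        [
            _numeric_ses(data.X_s).reset_index(drop=True),
            data.X_h.reset_index(drop=True),
        ],
        axis=1,
    )
    return frame if covariates is None else frame[list(covariates)]


def asmd_between(
    data: DisparityDataset, w: WeightSet, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Weighted between-group ASMD D per covariate.

    Numerator: |Hájek minority mean − Hájek majority mean| under the weight
    set.  Denominator: sqrt of the average of the two *unweighted* group
    variances.  Covariates with zero pooled SD are reported as 0 with a
    ``degenerate`` flag rather than NaN.
    """
    frame = _covariate_frame(data, covariates)
    m = data.Z == 1
    w1, w0 = w.omega1[m], w.omega0[~m]
    if w1.sum() <= 0 or w0.sum() <= 0:
        raise ValidationError("zero total weight in a group")
    rows = []
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        s1, s0 = _sd(x[m]), _sd(x[~m])
        denom = np.sqrt((s1**2 + s0**2) / 2.0)
        num = abs(
            np.sum(w1 * x[m]) / w1.sum() - np.sum(w0 * x[~m]) / w0.sum()
        )
        degenerate = denom == 0.0
        rows.append(
            {
                "covariate": col,
                "D": 0.0 if degenerate else num / denom,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def ses_alteration(
    data: DisparityDataset, w: WeightSet, group: str = "minority"
) -> pd.DataFrame:
    """SES-alteration metric D₁ (minority) or D₀ (majority) per SES covariate.

    Measures how far the weighted SES mean of one group moves from its
    unweighted mean, in units of that group's own unweighted SD.  Zero for
    every SES covariate whenever the group's weights are constant.
    """
    if group not in ("minority", "majority"):
        raise ValueError("group must be 'minority' or 'majority'")
    ses = _numeric_ses(data.X_s)
    if group == "minority":
        sel = data.Z == 1
        wv = w.omega1[sel]
    else:
        sel = data.Z == 0
        wv = w.omega0[sel]
    if wv.sum() <= 0:
        raise ValidationError("zero total weight in the group")
    rows = []
    for col in ses.columns:
        x = ses[col].to_numpy(dtype=float)[sel]
        sd = _sd(x)
        num = abs(x.mean() - np.sum(wv * x) / wv.sum())
        degenerate = sd == 0.0
        rows.append(
            {
                "covariate": col,
                "D": 0.0 if degenerate else num / sd,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def subgroup_health_balance(data: DisparityDataset, w: WeightSet) -> pd.DataFrame:
    """Within-SES-subgroup weighted ASMD D_r per (subgroup, health covariate).

    Restricts the between-group comparison to subjects with G = r; the
    denominator pools the unweighted within-subgroup group SDs.  Cells
    where either group has fewer than two subjects in the subgroup are
    flagged ``insufficient_n`` and reported as NaN; zero-SD cells are
    flagged ``degenerate`` and reported as 0.
    """
    rows = []
    for r in range(1, data.n_subgroups + 1):
        in_r = data.G == r
        m1 = in_r & (data.Z == 1)
        m0 = in_r & (data.Z == 0)
        w1, w0 = w.omega1[m1], w.omega0[m0]
        enough = m1.sum() >= 2 and m0.sum() >= 2
        for col in data.X_h.columns:
            x = data.X_h[col].to_numpy(dtype=float)
            if not enough:
                rows.append(
                    {"subgroup": r, "covariate": col, "D": np.nan,
                     "flag": "insufficient_n"}
                )
                continue
            s1, s0 = _sd(x[m1]), _sd(x[m0])
            denom = np.sqrt((s1**2 + s0**2) / 2.0)
            if denom == 0.0:
                rows.append(
                    {"subgroup": r, "covariate": col, "D": 0.0,
                     "flag": "degenerate"}
                )
                continue
            num = abs(
                np.sum(w1 * x[m1]) / w1.sum() - np.sum(w0 * x[m0]) / w0.sum()
            )
            rows.append(
                {"subgroup": r, "covariate": col, "D": num / denom, "flag": ""}
            )
    return pd.DataFrame(rows)


@dataclass
class BalanceReport:
    """Assembled IOM-concordance diagnostics for one or more weight sets."""

    d1: dict[str, pd.DataFrame]
    d0: dict[str, pd.DataFrame]
    dr: dict[str, pd.DataFrame]
    threshold: float
    flags: pd.DataFrame = field(default=None)
    concordant: dict[str, bool] = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        """Long-format table (metric, covariate, subgroup, value, flag) for plots."""
        parts = []
        for label, df in self.d1.items():
            t = df.reset_index()
            t.insert(0, "metric", "D1")
            t.insert(0, "weights", label)
            t["subgroup"] = np.nan
            parts.append(t.rename(columns={"D": "value"}))
        for label, df in self.d0.items():
            t = df.reset_index()
            t.insert(0, "metric", "D0")
            t.insert(0, "weights", label)
            t["subgroup"] = np.nan
            parts.append(t.rename(columns={"D": "value"}))
        for label, df in self.dr.items():
            t = df.copy()
            t.insert(0, "metric", "Dr")
            t.insert(0, "weights", label)
            parts.append(t.rename(columns={"D": "value"}))
        long = pd.concat(parts, ignore_index=True)
        cols = ["weights", "metric", "covariate", "subgroup", "value"]
        extra = [c for c in long.columns if c not in cols]
        return long[cols + extra]


def concordance_report(
    data: DisparityDataset,
    weight_sets: dict[str, WeightSet] | WeightSet,
    threshold: float = DEFAULT_THRESHOLD,
) -> BalanceReport:
    """Assemble D₁, D₀ and D_r for each supplied weight set and flag excesses.

    A weight set is IOM-concordant when no D₁, D₀ or evaluable D_r entry
    exceeds the threshold (default 0.1, the conventional imbalance cut).
    Cells flagged ``insufficient_n`` are excluded from the flag logic but
    listed in the report.
    """
    if isinstance(weight_sets, WeightSet):
        weight_sets = {weight_sets.method: weight_sets}
    d1, d0, dr, concordant = {}, {}, {}, {}
    flags = []
    for label, w in weight_sets.items():
        d1[label] = ses_alteration(data, w, "minority")
        d0[label] = ses_alteration(data, w, "majority")
        dr[label] = subgroup_health_balance(data, w)
        ok = True
        for metric, df in (("D1", d1[label]), ("D0", d0[label])):
            for cov, row in df.iterrows():
                if row["D"] > threshold:
                    ok = False
                    flags.append(
                        {"weights": label, "metric": metric, "covariate": cov,
                         "subgroup": np.nan, "value": row["D"]}
                    )
        evaluable = dr[label][dr[label]["flag"] != "insufficient_n"]
        for _, row in evaluable.iterrows():
            if row["D"] > threshold:
                ok = False
                flags.append(
                    {"weights": label, "metric": "Dr",
                     "covariate": row["covariate"],
                     "subgroup": row["subgroup"], "value": row["D"]}
                )
        concordant[label] = ok
    report = BalanceReport(
        d1=d1, d0=d0, dr=dr, threshold=threshold,
        flags=pd.DataFrame(
            flags, columns=["weights", "metric", "covariate", "subgroup", "value"]
        ),
        concordant=concordant,
    )
    return report
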