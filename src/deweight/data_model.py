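"""Dataset contract, covariate-role tagging and SES-subgroup construction.

A disparity analysis distinguishes two kinds of covariates:

* **SES variables** (education, income, ...) — categorical, non-clinical;
  under the Institute of Medicine (IOM) definition of a health-care
  disparity their group differences must be *preserved*.
* **health-status variables** — clinical-need covariates (numeric after
  dummy-encoding) whose group differences must be *adjusted away*.

The cross-classification of all SES variables partitions the sample into
subgroups ``G ∈ {1, ..., R}``; propensity models are fitted, and balance
diagnostics evaluated, within these subgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateRoles",
    "DisparityDataset",
    "load_table",
    "make_subgroups",
    "rhc_preprocess",
    "RHC_CONTINUOUS",
    "RHC_CATEGORICAL",
]


@dataclass(frozen=True)
class CovariateRoles:
    """Mapping from analysis roles to columns of the input table.

    Parameters
    ----------
    group : str
        Column holding the binary group indicator (two observed levels).
    minority_level : str
        The level of ``group`` coded as the minority (Z = 1).  Always
        user-specified by name, never inferred from frequency.
    outcome : str
        Outcome column (binary in {0, 1} or real-valued).
    ses : list of str
        Categorical SES covariates (each with a finite set of levels).
    health : list of str
        Health-status covariates, numeric after encoding.
    """

    group: str
    minority_level: object
    outcome: str
    ses: tuple[str, ...] = ()
    health: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "ses", tuple(self.ses))
        object.__setattr__(self, "health", tuple(self.health))
        names = [self.group, self.outcome, *self.ses, *self.health]
        if len(set(names)) != len(names):
            raise SchemaError(
                "covariate roles overlap: group/outcome/ses/health column "
                "names must be pairwise disjoint"
            )

    @property
    def n_ses(self) -> int:
        return len(self.ses)

    @property
    def n_health(self) -> int:
        return len(self.health)

    @classmethod
    def from_yaml(cls, path) -> "CovariateRoles":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            group=cfg["group"],
            minority_level=cfg["minority_level"],
            outcome=cfg["outcome"],
            ses=tuple(cfg.get("ses", ())),
            health=tuple(cfg.get("health", ())),
        )


def make_subgroups(X_s: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign each subject the index of its SES cell.

    Subgroups are the distinct observed combinations of the SES covariates,
    numbered 1..R in lexicographic order of their value tuples so the
    labelling is stable across runs and row orderings.

    Returns
    -------
    G : ndarray of int
        Per-subject subgroup index in ``{1, ..., R}``.
    catalog : DataFrame
        One row per subgroup: the SES values, the index and the count.
    """
    if X_s.shape[0] == 0:
        raise ValidationError("cannot build SES subgroups from an empty table")
    if X_s.shape[1] == 0:
        raise ValidationError("no SES columns supplied")
    if X_s.isna().any().any():
        bad = list(X_s.columns[X_s.isna().any()])
        raise ValidationError(f"missing values in SES columns: {bad}")

    keys = [tuple(row) for row in X_s.itertuples(index=False, name=None)]
    levels = sorted(set(keys), key=lambda t: tuple(map(str, t)))
    index_of = {lev: r + 1 for r, lev in enumerate(levels)}
    G = np.array([index_of[k] for k in keys], dtype=np.int64)

    catalog = pd.DataFrame(levels, columns=list(X_s.columns))
    catalog.insert(0, "subgroup", np.arange(1, len(levels) + 1))
    catalog["n"] = np.bincount(G, minlength=len(levels) + 1)[1:]
    return G, catalog


@dataclass
class DisparityDataset:
    """Validated per-subject data for a disparity analysis.

    Attributes
    ----------
    Z : ndarray of {0, 1}
        Minority indicator (1 = minority).
    Y : ndarray
        Outcome; binary outcomes are stored as floats in {0.0, 1.0}.
    X_s : DataFrame
        SES covariates (categorical; binary ones may be 0/1 integers).
    X_h : DataFrame
        Health-status covariates, numeric.
    G : ndarray of int
        SES-subgroup index in ``{1, ..., R}``; a deterministic function of
        the row of ``X_s``.
    roles : CovariateRoles
    """

    Z: np.ndarray
    Y: np.ndarray
    X_s: pd.DataFrame
    X_h: pd.DataFrame
    roles: CovariateRoles
    G: np.ndarray = field(default=None)
    catalog: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=np.int64)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.Z.shape[0]
        for name, arr in (("Y", self.Y),):
            if arr.shape[0] != n:
                raise ValidationError(f"{name} length {arr.shape[0]} != N={n}")
        for name, df in (("X_s", self.X_s), ("X_h", self.X_h)):
            if df.shape[0] != n:
                raise ValidationError(f"{name} has {df.shape[0]} rows, N={n}")
        if not np.isin(self.Z, (0, 1)).all():
            raise ValidationError("group indicator must be coded 0/1")
        if self.Z.sum() == 0 or self.Z.sum() == n:
            raise ValidationError(
                "both groups must be non-empty (Z needs at least one 0 and one 1)"
            )
        if self.X_h.shape[1] and not all(
            np.issubdtype(dt, np.number) for dt in self.X_h.dtypes
        ):
            raise ValidationError("health-status columns must be numeric")
        if self.X_h.isna().any().any() or np.isnan(self.Y).any():
            raise ValidationError("missing values present after preprocessing")
        if self.G is None:
            self.G, self.catalog = make_subgroups(self.X_s)
        else:
            self.G = np.asarray(self.G, dtype=np.int64)

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return int(self.Z.shape[0])

    @property
    def n_minority(self) -> int:
        return int(self.Z.sum())

    @property
    def n_majority(self) -> int:
        return self.n_subjects - self.n_minority

    @property
    def n_subgroups(self) -> int:
        return int(self.G.max())

    @property
    def outcome_is_binary(self) -> bool:
        return bool(np.isin(self.Y, (0.0, 1.0)).all())

    def subgroup_catalog(self) -> pd.DataFrame:
        """Catalog with per-subgroup minority / majority counts."""
        cat = self.catalog.copy()
        R = self.n_subgroups
        n1 = np.zeros(R, dtype=int)
        n0 = np.zeros(R, dtype=int)
        for r in range(1, R + 1):
            in_r = self.G == r
            n1[r - 1] = int(self.Z[in_r].sum())
            n0[r - 1] = int((~self.Z.astype(bool))[in_r].sum())
        cat["n_minority"] = n1
        cat["n_majority"] = n0
        return cat

    def to_frame(self) -> pd.DataFrame:
        """Flat table: Z, Y, SES, health columns and the subgroup index."""
        out = pd.DataFrame({"Z": self.Z, "Y": self.Y})
        out = pd.concat(
            [out, self.X_s.reset_index(drop=True), self.X_h.reset_index(drop=True)],
            axis=1,
        )
        out["G"] = self.G
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_table(
    path,
    roles: CovariateRoles,
    *,
    missing: str = "fail",
    sep: str | None = None,
) -> DisparityDataset:
    """Read a delimited text file and validate it into a :class:`DisparityDataset`.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with a header row.
    roles : CovariateRoles
        Which columns play which role; ``roles.minority_level`` selects the
        level of the group column coded Z = 1.
    missing : {"fail", "drop"}
        Policy for missing values in role columns.  ``"fail"`` (default)
        raises; ``"drop"`` removes incomplete rows and logs how many.
    sep : str, optional
        Field delimiter; inferred from the file extension when omitted
        (``.tsv`` → tab, otherwise comma).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep)
    return from_frame(raw, roles, missing=missing)


def from_frame(
    raw: pd.DataFrame, roles: CovariateRoles, *, missing: str = "fail"
) -> DisparityDataset:
    """Validate an in-memory table into a :class:`DisparityDataset`."""
    needed = [roles.group, roles.outcome, *roles.ses, *roles.health]
    for col in needed:
        if col not in raw.columns:
            raise SchemaError(f"required column missing from table: {col!r}")
    sub = raw[needed].copy()

    na_cols = list(sub.columns[sub.isna().any()])
    if na_cols:
        if missing == "fail":
            raise ValidationError(
                f"missing values in columns {na_cols}; rerun with "
                "missing='drop' to remove incomplete rows"
            )
        elif missing == "drop":
            before = len(sub)
            sub = sub.dropna()
            logger.info("dropped %d incomplete rows", before - len(sub))
        else:
            raise ValueError(f"unknown missing-data policy: {missing!r}")
    if len(sub) == 0:
        raise ValidationError("no rows remain after applying the missing-data policy")

    grp = sub[roles.group]
    levels = pd.unique(grp)
    if len(levels) != 2:
        raise ValidationError(
            f"group column {roles.group!r} must have exactly two observed "
            f"levels, found {list(levels)}"
        )
    if roles.minority_level not in set(levels):
        raise ValidationError(
            f"minority level {roles.minority_level!r} not observed in "
            f"group column (levels: {list(levels)})"
        )
    Z = (grp == roles.minority_level).to_numpy(dtype=np.int64)

    X_h = sub[list(roles.health)].apply(pd.to_numeric, errors="raise")
    return DisparityDataset(
        Z=Z,
        Y=sub[roles.outcome].to_numpy(dtype=float),
        X_s=sub[list(roles.ses)].reset_index(drop=True),
        X_h=X_h.reset_index(drop=True),
        roles=roles,
    )


# ---------------------------------------------------------------------------
# Right-heart-catheterization (RHC / SUPPORT) preprocessing recipe
# ---------------------------------------------------------------------------

#: The 20 continuous health-status variables and their canonical column
#: names in the public RHC file.  "n_comorbidities" is constructed as the
#: sum of the 12 binary comorbidity-history indicators.
RHC_CONTINUOUS: dict[str, str] = {
    "age": "age",
    "n_comorbidities": "<constructed>",
    "das2d3pc": "das2d3pc",  # Duke activity status index
    "aps1": "aps1",          # APACHE score
    "scoma1": "scoma1",      # Glasgow coma score
    "meanbp1": "meanbp1",
    "wblc1": "wblc1",
    "hrt1": "hrt1",
    "resp1": "resp1",
    "temp1": "temp1",
    "pafi1": "pafi1",
    "alb1": "alb1",
    "hema1": "hema1",
    "bili1": "bili1",
    "crea1": "crea1",
    "sod1": "sod1",
    "pot1": "pot1",
    "paco21": "paco21",
    "ph1": "ph1",
    "wtkilo1": "wtkilo1",
}

#: Categorical health-status variables dummy-encoded with the most frequent
#: level as reference: sex (1 dummy), cancer (2), pooled disease category
#: (3), DNR status (1) — 7 dummies, 27 health-status columns in total.
RHC_CATEGORICAL: tuple[str, ...] = ("sex", "ca", "cat1", "dnr1")

_COMORBIDITY_HISTORY = (
    "cardiohx", "chfhx", "dementhx", "psychhx", "chrpulhx", "renalhx",
    "liverhx", "gibledhx", "malighx", "immunhx", "transhx", "amihx",
)

_INCOME_HIGH = {"$25-$50k", "> $50k"}
_RACE_LEVELS = {"black", "white", "other"}


def _pool_disease_category(cat: pd.Series) -> pd.Series:
    """Collapse the 9-level primary disease category to ARF/CHF/MOSF/Other."""
    s = cat.astype(str)
    pooled = pd.Series("Other", index=s.index)
    pooled[s.str.startswith("ARF")] = "ARF"
    pooled[s.str.startswith("CHF")] = "CHF"
    pooled[s.str.startswith("MOSF")] = "MOSF"
    return pooled


def _dummy_most_frequent_reference(col: pd.Series, name: str) -> pd.DataFrame:
    """Dummy-encode with the modal level as the omitted reference."""
    counts = col.value_counts()
    reference = counts.index[0]
    levels = [lev for lev in counts.index if lev != reference]
    out = {}
    for lev in sorted(map(str, levels)):
        out[f"{name}_{lev}".replace(" ", "_")] = (
            col.astype(str) == lev
        ).astype(float)
    logger.info("dummy-encoded %s with reference level %r", name, reference)
    return pd.DataFrame(out, index=col.index)


def rhc_preprocess(raw: pd.DataFrame | str | Path) -> DisparityDataset:
    """Apply the RHC study recipe to the public right-heart-catheterization table.

    Steps:

    1. restrict to black and white patients (Z = 1 for black);
    2. outcome Y = 1 if the patient received RHC (``swang1 == "RHC"``);
    3. SES covariates: education dichotomized at high school or more
       (``edu >= 12``) and income dichotomized at $25K or greater;
    4. health-status covariates: 20 continuous variables plus sex, cancer,
       pooled disease category and DNR status dummy-encoded to 27 columns.

    On the canonical public file this yields 5380 rows (920 minority,
    4460 majority) and 27 health-status columns.
    """
    if not isinstance(raw, pd.DataFrame):
        raw = pd.read_csv(raw)

    needed = (
        ["race", "swang1", "edu", "income"]
        + [c for c in RHC_CONTINUOUS.values() if c != "<constructed>"]
        + list(RHC_CATEGORICAL)
        + list(_COMORBIDITY_HISTORY)
    )
    for col in needed:
        if col not in raw.columns:
            raise SchemaError(f"canonical RHC column missing: {col!r}")

    races = set(raw["race"].astype(str).str.lower().unique())
    unknown = races - _RACE_LEVELS
    if unknown:
        raise ValidationError(f"unexpected race codes in RHC file: {sorted(unknown)}")

    keep = raw["race"].astype(str).str.lower().isin(("black", "white"))
    df = raw.loc[keep].reset_index(drop=True)
    if len(df) == 0:
        raise ValidationError("no black or white patients remain after filtering")

    Z = (df["race"].astype(str).str.lower() == "black").to_numpy(np.int64)
    Y = (df["swang1"].astype(str) == "RHC").to_numpy(float)

    X_s = pd.DataFrame(
        {
            "educ_hs": (pd.to_numeric(df["edu"]) >= 12).astype(np.int64),
            "income_25k": df["income"].astype(str).isin(_INCOME_HIGH).astype(np.int64),
        }
    )

    cont = {}
    for out_name, src in RHC_CONTINUOUS.items():
        if src == "<constructed>":
            cont[out_name] = (
                df[list(_COMORBIDITY_HISTORY)]
                .apply(pd.to_numeric)
                .sum(axis=1)
                .astype(float)
            )
        else:
            cont[out_name] = pd.to_numeric(df[src]).astype(float)
    X_h = pd.DataFrame(cont)

    cats = df[list(RHC_CATEGORICAL)].copy()
    cats["cat1"] = _pool_disease_category(cats["cat1"])
    for name in RHC_CATEGORICAL:
        X_h = pd.concat(
            [X_h, _dummy_most_frequent_reference(cats[name], name)], axis=1
        )

    roles = CovariateRoles(
        group="race",
        minority_level="black",
        outcome="rhc",
        ses=("educ_hs", "income_25k"),
        health=tuple(X_h.columns),
    )
    return DisparityDataset(Z=Z, Y=Y, X_s=X_s, X_h=X_h, roles=roles)
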