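"""Synthetic data with the dependence structure the method assumes.

The generative model factorizes exactly the way the estimands are defined:

1. minority indicator ``Z ~ Bernoulli(p_minority)``;
2. SES cell drawn from a *race-specific* joint table over J binary SES
   variables (race–SES association);
3. K health-status covariates multivariate normal with a mean shifted by
   race and by each SES variable (health depends on both);
4. binary outcome from a logistic model in race, SES and health status.

Because the factorization is explicit, both propensity scores have closed
forms (Bayes' rule over the race-specific densities), so oracle values of
the target estimands can be computed with *true* propensities on a large
simulated population — the estimation pipeline is never consulted.

The default configuration mimics the shape of the right-heart-
catheterization application: two binary SES variables whose race-specific
joint tables reproduce that study's SES marginals (≈19% vs 30% high-school
education, ≈12% vs 26% income ≥$25K, 17.1% minority share), six health
covariates, and an outcome with ≈45% prevalence.  It is a structural
fixture, not a model of the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import CovariateRoles, DisparityDataset
from .errors import ValidationError
from .weights import WeightSet, deweighting_weights

__all__ = [
    "SimulationConfig",
    "OracleTruth",
    "generate",
    "true_propensities",
    "oracle_truth",
    "true_weight_set",
    "synthetic_rhc_raw",
]


def _default_minority_table() -> np.ndarray:
    # (education, income) cells; marginals 18.6% / 11.6%
    return np.array([[0.760, 0.054], [0.124, 0.062]])


def _default_majority_table() -> np.ndarray:
    # marginals 30.4% / 25.8%
    return np.array([[0.630, 0.066], [0.112, 0.192]])


def _ar1(k: int, rho: float = 0.3) -> np.ndarray:
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic disparity-study generator.

    Attributes
    ----------
    n : int
        Sample size.
    p_minority : float
        Marginal minority probability.
    ses_joint_minority, ses_joint_majority : ndarray, shape (2,)*J
        Joint probability tables over the J binary SES variables within
        each race; each must sum to 1 and every cell must be positive in
        both tables (positivity by construction).
    race_shift : ndarray, shape (K,)
        Mean shift of the health covariates for minority subjects.
    ses_shifts : ndarray, shape (J, K)
        Mean shift of the health covariates per SES variable (row j adds
        to the mean when SES variable j equals 1).
    health_cov : ndarray, shape (K, K)
        Covariance of the health covariates (symmetric positive definite,
        shared across race and SES).
    outcome_intercept, outcome_race : float
    outcome_ses : ndarray, shape (J,)
    outcome_health : ndarray, shape (K,)
        Log-odds coefficients of the binary outcome model.
    seed : int
        Default seed when :func:`generate` is called without one.
    """

    n: int = 5000
    p_minority: float = 0.171
    ses_names: tuple[str, ...] = ("educ_hs", "income_25k")
    ses_joint_minority: np.ndarray = field(default_factory=_default_minority_table)
    ses_joint_majority: np.ndarray = field(default_factory=_default_majority_table)
    race_shift: np.ndarray = field(
        default_factory=lambda: np.array([0.40, -0.30, 0.20, 0.00, 0.25, -0.20])
    )
    ses_shifts: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.30, 0.20, 0.00, 0.10, -0.20, 0.00],
                [0.20, 0.00, 0.25, -0.15, 0.00, 0.10],
            ]
        )
    )
    health_cov: np.ndarray = field(default_factory=lambda: _ar1(6, 0.3))
    outcome_intercept: float = -0.35
    outcome_race: float = -0.15
    outcome_ses: np.ndarray = field(default_factory=lambda: np.array([0.35, 0.30]))
    outcome_health: np.ndarray = field(
        default_factory=lambda: np.array([0.25, -0.20, 0.30, 0.15, -0.25, 0.20])
    )
    seed: int = 0

    def __post_init__(self):
        self.ses_joint_minority = np.asarray(self.ses_joint_minority, float)
        self.ses_joint_majority = np.asarray(self.ses_joint_majority, float)
        self.race_shift = np.asarray(self.race_shift, float)
        self.ses_shifts = np.atleast_2d(np.asarray(self.ses_shifts, float))
        self.health_cov = np.asarray(self.health_cov, float)
        self.outcome_ses = np.atleast_1d(np.asarray(self.outcome_ses, float))
        self.outcome_health = np.asarray(self.outcome_health, float)
        self.validate()

    # -- dimensions ------------------------------------------------------
    @property
    def n_ses(self) -> int:
        return self.ses_joint_minority.ndim

    @property
    def n_health(self) -> int:
        return len(self.race_shift)

    def validate(self) -> None:
        J, K = self.n_ses, self.n_health
        if not 0.0 < self.p_minority < 1.0:
            raise ValidationError("p_minority must lie strictly in (0, 1)")
        for name, tab in (
            ("ses_joint_minority", self.ses_joint_minority),
            ("ses_joint_majority", self.ses_joint_majority),
        ):
            if tab.shape != (2,) * J:
                raise ValidationError(f"{name} must have shape {(2,) * J}")
            if not np.isclose(tab.sum(), 1.0, atol=1e-10):
                raise ValidationError(f"{name} must sum to 1 (got {tab.sum():.6f})")
            if np.any(tab <= 0):
                raise ValidationError(
                    f"{name} has a zero-probability SES cell; every cell must "
                    "be positive under both races (positivity by construction)"
                )
        if len(self.ses_names) != J:
            raise ValidationError("ses_names length must match the SES table rank")
        if self.ses_shifts.shape != (J, K):
            raise ValidationError(f"ses_shifts must have shape ({J}, {K})")
        if self.health_cov.shape != (K, K):
            raise ValidationError(f"health_cov must have shape ({K}, {K})")
        if not np.allclose(self.health_cov, self.health_cov.T):
            raise ValidationError("health_cov must be symmetric")
        if np.linalg.eigvalsh(self.health_cov).min() <= 0:
            raise ValidationError("health_cov must be positive definite")
        if self.outcome_ses.shape != (J,) or self.outcome_health.shape != (K,):
            raise ValidationError("outcome coefficient shapes inconsistent")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        arrays = {
            "ses_joint_minority", "ses_joint_majority", "race_shift",
            "ses_shifts", "health_cov", "outcome_ses", "outcome_health",
        }
        kw = {
            k: (np.asarray(v, float) if k in arrays else v)
            for k, v in cfg.items()
        }
        if "ses_names" in kw:
            kw["ses_names"] = tuple(kw["ses_names"])
        return cls(**kw)


def _ses_cells(J: int) -> np.ndarray:
    """All 2^J SES value tuples as an array of shape (2^J, J)."""
    grid = np.indices((2,) * J).reshape(J, -1).T
    return grid


def _draw(config: SimulationConfig, n: int, rng: np.random.Generator):
    """Draw (Z, X_s, X_h, Y) from the generative model."""
    J, K = config.n_ses, config.n_health
    Z = (rng.random(n) < config.p_minority).astype(np.int64)
    cells = _ses_cells(J)
    p1 = config.ses_joint_minority.reshape(-1)
    p0 = config.ses_joint_majority.reshape(-1)
    cell_idx = np.empty(n, dtype=np.int64)
    for z, probs in ((1, p1), (0, p0)):
        m = Z == z
        cell_idx[m] = rng.choice(len(probs), size=int(m.sum()), p=probs)
    X_s = cells[cell_idx]

    mean = Z[:, None] * config.race_shift + X_s @ config.ses_shifts
    L = np.linalg.cholesky(config.health_cov)
    X_h = mean + rng.standard_normal((n, K)) @ L.T

    eta = (
        config.outcome_intercept
        + config.outcome_race * Z
        + X_s @ config.outcome_ses
        + X_h @ config.outcome_health
    )
    Y = (rng.random(n) < expit(eta)).astype(float)
    return Z, X_s, X_h, Y, eta


def generate(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    n: int | None = None,
) -> DisparityDataset:
    """Generate a synthetic :class:`DisparityDataset`.

    Reproducible given ``(config, seed)``; all randomness flows through a
    single ``numpy`` generator seeded here (``seed`` overrides
    ``config.seed``, ``n`` overrides ``config.n``).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n if n is None else n
    Z, X_s, X_h, Y, _ = _draw(config, n, rng)
    roles = CovariateRoles(
        group="group",
        minority_level=1,
        outcome="Y",
        ses=config.ses_names,
        health=tuple(f"h{k + 1}" for k in range(config.n_health)),
    )
    return DisparityDataset(
        Z=Z,
        Y=Y,
        X_s=pd.DataFrame(X_s, columns=list(config.ses_names)),
        X_h=pd.DataFrame(X_h, columns=list(roles.health)),
        roles=roles,
    )


def true_propensities(
    config: SimulationConfig, X_s: np.ndarray, X_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form full and SES-only propensity scores via Bayes' rule.

    With a shared health covariance, the minority/majority density ratio is
    log-linear in the health covariates with slope Σ⁻¹·race_shift, so

        logit e(x)  = logit e(xˢ) + (xʰ − μ₀(s))ᵀ Σ⁻¹ δ − ½ δᵀ Σ⁻¹ δ,
        logit e(xˢ) = log[p₁ π₁(s) / (p₀ π₀(s))],

    where δ is the race shift and μ₀(s) the majority health mean in SES
    cell s.  These are *true* model quantities, independent of any fit.
    """
    X_s = np.asarray(X_s, dtype=np.int64)
    X_h = np.asarray(X_h, dtype=float)
    J = config.n_ses
    flat_idx = np.ravel_multi_index(tuple(X_s.T), (2,) * J)
    pi1 = config.ses_joint_minority.reshape(-1)[flat_idx]
    pi0 = config.ses_joint_majority.reshape(-1)[flat_idx]
    p1 = config.p_minority
    logodds_ses = np.log(p1 * pi1) - np.log((1 - p1) * pi0)

    delta = config.race_shift
    a = np.linalg.solve(config.health_cov, delta)
    mu0 = X_s @ config.ses_shifts
    logodds_full = logodds_ses + (X_h - mu0) @ a - 0.5 * delta @ a
    return expit(logodds_full), expit(logodds_ses)


def true_weight_set(
    config: SimulationConfig, X_s: np.ndarray, X_h: np.ndarray, estimand: str
) -> WeightSet:
    """Deweighting weights computed from the *true* propensity scores."""
    e_full, e_ses = true_propensities(config, X_s, X_h)
    w = deweighting_weights(e_full, e_ses, estimand)
    w.method = "deweighting_true_ps"
    return w


@dataclass
class OracleTruth:
    """Oracle value of a disparity estimand under a generator configuration.

    ``tau`` is the weighted average controlled difference in the target
    population implied by the estimand's tilting function, evaluated by
    weighting *true* conditional outcome means with *true* propensities on
    a large simulated population; ``mc_se`` is the Monte-Carlo standard
    error of that evaluation (scales as 1/√n_oracle).
    """

    tau: float
    mu1: float
    mu0: float
    mc_se: float
    n_oracle: int
    estimand: str


def oracle_truth(
    config: SimulationConfig,
    estimand: str,
    n_oracle: int = 1_000_000,
    seed: int | None = None,
) -> OracleTruth:
    """Monte-Carlo oracle for the deweighted disparity estimand.

    Draws ``n_oracle`` subjects, forms the deweighting weights from the
    closed-form true propensities, and takes Hájek means of the *true*
    conditional outcome probabilities m_z(x) = E[Y | Z=z, X=x] — no
    outcome noise and no estimated model enters.  The MC standard error is
    the linearization SE of the two Hájek means.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    Z, X_s, X_h, _, eta = _draw(config, n_oracle, rng)
    # conditional outcome means at the subject's own group membership
    m = expit(eta)
    w = true_weight_set(config, X_s, X_h, estimand)
    sel1 = Z == 1
    w1, w0 = w.omega1[sel1], w.omega0[~sel1]
    m1, m0 = m[sel1], m[~sel1]
    mu1 = float(np.sum(w1 * m1) / w1.sum())
    mu0 = float(np.sum(w0 * m0) / w0.sum())
    var = (
        np.sum(w1**2 * (m1 - mu1) ** 2) / w1.sum() ** 2
        + np.sum(w0**2 * (m0 - mu0) ** 2) / w0.sum() ** 2
    )
    return OracleTruth(
        tau=mu1 - mu0,
        mu1=mu1,
        mu0=mu0,
        mc_se=float(np.sqrt(var)),
        n_oracle=n_oracle,
        estimand=estimand.lower(),
    )


# ---------------------------------------------------------------------------
# synthetic stand-in for the raw right-heart-catheterization file
# ---------------------------------------------------------------------------

_RHC_INCOME_LEVELS = ("Under $11k", "$11-$25k", "$25-$50k", "> $50k")
_RHC_CAT1_LEVELS = (
    "ARF", "CHF", "MOSF w/Sepsis", "MOSF w/Malignancy", "COPD", "Coma",
    "Cirrhosis", "Lung Cancer", "Colon Cancer",
)


def synthetic_rhc_raw(
    n: int = 800, seed: int = 0, p_other: float = 0.06
) -> pd.DataFrame:
    """SYNTHETIC stand-in for the raw public RHC table (column-compatible).

    Produces a table with the canonical column names and level codings of
    the public right-heart-catheterization file so that the preprocessing
    recipe can be exercised without the real data.  The values are drawn
    from simple independent distributions and carry no scientific content;
    this is a structural fixture only.
    """
    from .data_model import RHC_CONTINUOUS, _COMORBIDITY_HISTORY

    rng = np.random.default_rng(seed)
    race = rng.choice(
        ["black", "white", "other"],
        size=n,
        p=[0.17 * (1 - p_other), 0.83 * (1 - p_other), p_other],
    )
    df = pd.DataFrame({"race": race})
    df["swang1"] = rng.choice(["No RHC", "RHC"], n, p=[0.58, 0.42])
    df["edu"] = rng.integers(6, 19, n)
    df["income"] = rng.choice(_RHC_INCOME_LEVELS, n, p=[0.40, 0.30, 0.20, 0.10])
    df["sex"] = rng.choice(["Male", "Female"], n, p=[0.56, 0.44])
    df["ca"] = rng.choice(["No", "Yes", "Metastatic"], n, p=[0.76, 0.17, 0.07])
    df["cat1"] = rng.choice(_RHC_CAT1_LEVELS, n)
    df["dnr1"] = rng.choice(["No", "Yes"], n, p=[0.885, 0.115])
    for col in _COMORBIDITY_HISTORY:
        df[col] = rng.integers(0, 2, n)
    for out_name, src in RHC_CONTINUOUS.items():
        if src == "<constructed>":
            continue
        df[src] = np.round(rng.normal(50.0, 15.0, n), 3)
    return df
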