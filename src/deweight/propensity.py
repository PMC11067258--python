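"""Propensity-score estimation.

Three propensity scores drive the disparity analysis, all modelling the
probability of minority-group membership:

* the **full PS** ``e(x)`` conditional on SES and health status — fitted
  here *within each SES subgroup* with health-status main effects, giving
  the SES-Stratum-specific Health-Status (SSHS) PS;
* the **SES-PS** ``e(x^s)`` conditional on SES only — saturated, hence the
  closed-form subgroup minority proportion;
* the **health-status PS** ``e(x^h)`` conditional on health status only.

Parameters are estimated either by maximum likelihood (ML) or by the
just-identified covariate balancing propensity score (CBPS), which chooses
the logistic coefficients so that the weighted covariate means balance
exactly in the target population of the requested estimand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.special import expit

from .data_model import DisparityDataset
from .errors import (
    ConvergenceError,
    PositivityError,
    SeparationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityVector",
    "fit_logistic_ml",
    "fit_cbps",
    "fit_ses_ps_saturated",
    "fit_stratified_full_ps",
    "fit_health_status_ps",
    "fit_full_ps_pooled",
]

_PROB_WARN = 1e-6  # warn when fitted probabilities leave [eps, 1-eps]


@dataclass
class StratumFit:
    """Convergence record for one per-stratum (or pooled) fit."""

    stratum: int | None
    n: int
    iterations: int
    residual_norm: float
    dropped_columns: tuple[str, ...] = ()
    fallback_pooled: bool = False


@dataclass
class PropensityVector:
    """Per-subject estimated minority-membership probabilities."""

    values: np.ndarray
    model_kind: str  # {"full", "ses", "health"}
    estimator: str  # {"ml", "cbps", "saturated"}
    stratified: bool = False
    fits: list[StratumFit] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("propensity scores must be finite")
        if np.any((self.values <= 0.0) | (self.values >= 1.0)):
            raise PositivityError(
                "fitted propensity scores outside the open interval (0, 1)"
            )
        n_extreme = int(
            np.sum((self.values < _PROB_WARN) | (self.values > 1 - _PROB_WARN))
        )
        if n_extreme:
            warnings.warn(
                f"{n_extreme} fitted propensity scores are within {_PROB_WARN} "
                "of 0 or 1; balancing weights will be extreme",
                RuntimeWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise if the design is rank deficient, naming the offending columns."""
    n, p = X.shape
    if n <= p:
        raise ValidationError(
            f"design matrix has {p} columns but only {n} rows; "
            "more subjects than parameters are required"
        )
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.max() > 0 else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = [names[j] for j in piv[rank:]]
        raise ValidationError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def _check_separation(Z: np.ndarray, p: np.ndarray) -> None:
    eps = 1e-8
    if np.all(p[Z == 1] > 1 - eps) and np.all(p[Z == 0] < eps):
        raise SeparationError(
            "perfect separation: the design predicts group membership exactly"
        )


def _design(X_h: pd.DataFrame, rows=None) -> tuple[np.ndarray, list[str]]:
    """Intercept + main effects design from a health-covariate frame."""
    sub = X_h if rows is None else X_h.loc[rows]
    X = np.column_stack([np.ones(len(sub)), sub.to_numpy(dtype=float)])
    return X, ["intercept", *map(str, X_h.columns)]


# ---------------------------------------------------------------------------
# maximum-likelihood logistic regression
# ---------------------------------------------------------------------------

def fit_logistic_ml(
    Z: np.ndarray,
    X_design: np.ndarray,
    names: list[str] | None = None,
    maxiter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """ML logistic regression of the group indicator on a design matrix.

    Returns ``(beta, fitted_probabilities, iterations)``.  Raises
    :class:`SeparationError` when the likelihood is monotone and
    :class:`ValidationError` when the design is rank deficient.
    """
    Z = np.asarray(Z, dtype=float)
    X_design = np.asarray(X_design, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X_design.shape[1])]
    _check_rank(X_design, list(names))

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(Z, X_design, family=sm.families.Binomial()).fit(
                maxiter=maxiter, tol=1e-10
            )
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"logistic fit failed ({exc}); the likelihood is monotone "
                "or the information matrix is singular"
            ) from exc
    p = np.asarray(res.predict(X_design), dtype=float)
    _check_separation(Z, p)
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"ML logistic fit did not converge within {maxiter} IRLS steps",
            iterations=maxiter,
        )
    history = getattr(res, "fit_history", None) or {}
    iters = int(history.get("iteration", maxiter))
    return np.asarray(res.params, dtype=float), p, iters


# ---------------------------------------------------------------------------
# just-identified CBPS
# ---------------------------------------------------------------------------

def _cbps_system(estimand: str):
    """Potential, mean-normalized balance equations and Jacobian.

    The balance systems are gradients of strictly concave potentials, so a
    Newton ascent with backtracking converges globally whenever a root
    exists:

    ATE:  (1/N) Σ_i [Z_i/e_i − (1−Z_i)/(1−e_i)] x_i = ∇φ,
          φ = (1/N) Σ_i [(2Z_i−1)η_i − Z_i e^{−η_i} − (1−Z_i) e^{η_i}];
    ATT:  (1/N) Σ_i [Z_i − (1−Z_i) e_i/(1−e_i)] x_i = ∇φ,
          φ = (1/N) Σ_i [Z_i η_i − (1−Z_i) e^{η_i}],

    with η = xβ and e = expit(η).
    """

    def phi_F_J(beta, Z, X):
        eta = np.clip(X @ beta, -600.0, 600.0)
        n = len(Z)
        em, ep = np.exp(-eta), np.exp(eta)
        if estimand == "ate":
            phi = np.sum((2 * Z - 1) * eta - Z * em - (1 - Z) * ep) / n
            c = (2 * Z - 1) + Z * em - (1 - Z) * ep
            w = Z * em + (1 - Z) * ep
        elif estimand == "att":
            phi = np.sum(Z * eta - (1 - Z) * ep) / n
            c = Z - (1 - Z) * ep
            w = (1 - Z) * ep
        else:  # pragma: no cover - guarded by caller
            raise ValueError(estimand)
        F = (X * c[:, None]).sum(axis=0) / n
        J = -(X * w[:, None]).T @ X / n
        return phi, F, J

    return phi_F_J


def fit_cbps(
    Z: np.ndarray,
    X_design: np.ndarray,
    estimand: str = "ate",
    names: list[str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Just-identified CBPS fit of a logistic propensity model.

    Solves the exact-balance estimating equations for the requested
    estimand by damped Newton iteration started at the ML solution.  For
    the overlap (ATO) estimand the ML fit is returned unchanged: overlap
    weights attain exact mean balance at the ML solution, so the balance
    system and the score equations coincide.

    Returns ``(beta, fitted_probabilities, iterations, residual_norm)``
    where the residual is the max-norm of the mean-normalized balance
    system at the solution.
    """
    estimand = estimand.lower()
    if estimand not in ("ate", "att", "ato"):
        raise ValueError(f"unknown estimand: {estimand!r}")
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X_design, dtype=float)

    beta_ml, p_ml, it_ml = fit_logistic_ml(Z, X, names=names)
    if estimand == "ato":
        # score eq Σ (Z−e) x = 0  <=>  Σ Z(1−e)x = Σ (1−Z)e x
        resid = float(np.max(np.abs(((Z - p_ml)[:, None] * X).sum(0) / len(Z))))
        return beta_ml, p_ml, it_ml, resid

    # internal column scaling for conditioning; back-transform at the end
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    Xs = X / scale

    phi_F_J = _cbps_system(estimand)
    beta = beta_ml * scale
    phi, F, J = phi_F_J(beta, Z, Xs)
    norm = np.max(np.abs(F))
    it = 0
    while norm > tol and it < maxiter:
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -F, rcond=None)[0]
        slope = float(step @ F)  # ascent rate of the potential
        lam = 1.0
        while lam > 1e-12:
            cand = beta + lam * step
            phic, Fc, Jc = phi_F_J(cand, Z, Xs)
            if np.isfinite(phic) and phic >= phi + 1e-4 * lam * slope:
                beta, phi, F, J = cand, phic, Fc, Jc
                norm = np.max(np.abs(F))
                break
            lam /= 2.0
        else:
            break  # no ascent possible; report at current residual
        it += 1
    if norm > tol:
        raise ConvergenceError(
            f"CBPS balance equations not solved to tolerance {tol:g} "
            f"(residual max-norm {norm:.3e} after {it} Newton steps)",
            residual_norm=float(norm),
            iterations=it,
        )
    beta_out = beta / scale
    p = expit(X @ beta_out)
    _check_separation(Z, p)
    return beta_out, p, it, float(norm)


# ---------------------------------------------------------------------------
# the three analysis-level propensity scores
# ---------------------------------------------------------------------------

def fit_ses_ps_saturated(data: DisparityDataset) -> PropensityVector:
    """Saturated SES propensity score: the subgroup minority proportion.

    With categorical SES covariates a logistic model with all main effects
    and interactions is saturated, and its ML fit assigns every subject in
    SES subgroup ``r`` the probability ``n1_r / (n1_r + n0_r)``.  A
    subgroup containing no minority or no majority subjects violates
    positivity and raises rather than being clipped.
    """
    values = np.empty(data.n_subjects, dtype=float)
    fits: list[StratumFit] = []
    cat = data.subgroup_catalog()
    for _, row in cat.iterrows():
        r = int(row["subgroup"])
        n1, n0 = int(row["n_minority"]), int(row["n_majority"])
        if n1 == 0 or n0 == 0:
            ses_desc = {c: row[c] for c in data.X_s.columns}
            raise PositivityError(
                f"SES subgroup {r} ({ses_desc}) has n_minority={n1}, "
                f"n_majority={n0}; the SES propensity score is degenerate"
            )
        values[data.G == r] = n1 / (n1 + n0)
        fits.append(StratumFit(stratum=r, n=n1 + n0, iterations=0,
                               residual_norm=0.0))
    return PropensityVector(values, model_kind="ses", estimator="saturated",
                            stratified=True, fits=fits)


def _fit_one(Z, X, names, estimator, estimand):
    if estimator == "ml":
        beta, p, it = fit_logistic_ml(Z, X, names=names)
        resid = float(np.max(np.abs(((Z - p)[:, None] * X).sum(0) / len(Z))))
        return p, it, resid
    elif estimator == "cbps":
        _, p, it, resid = fit_cbps(Z, X, estimand=estimand, names=names)
        return p, it, resid
    raise ValueError(f"unknown estimator: {estimator!r}")


def fit_stratified_full_ps(
    data: DisparityDataset,
    estimator: str = "cbps",
    estimand: str = "ate",
    fallback_pooled: bool = False,
) -> PropensityVector:
    """Full PS fitted separately within each SES subgroup (the SSHS-PS).

    Each per-stratum design holds an intercept plus the main effects of all
    health-status variables; columns constant within a stratum carry no
    information there and are dropped from that stratum's design (recorded
    in the convergence log).  A stratum whose fit fails raises unless
    ``fallback_pooled`` is set, in which case that stratum is scored by a
    pooled main-effects model and the fallback is logged.
    """
    values = np.empty(data.n_subjects, dtype=float)
    fits: list[StratumFit] = []
    pooled = None
    for r in range(1, data.n_subgroups + 1):
        rows = data.G == r
        Zr = data.Z[rows]
        Xh_r = data.X_h.loc[rows]
        keep = [c for c in Xh_r.columns if Xh_r[c].nunique() > 1]
        dropped = tuple(c for c in Xh_r.columns if c not in keep)
        X, names = _design(Xh_r[keep])
        try:
            p, it, resid = _fit_one(Zr, X, names, estimator, estimand)
        except (ConvergenceError, SeparationError, ValidationError) as exc:
            if not fallback_pooled:
                raise type(exc)(
                    f"propensity fit failed in SES subgroup {r}: {exc}"
                ) from exc
            if pooled is None:
                Xp, np_names = _design(data.X_h)
                p_all, it, resid = _fit_one(
                    data.Z, Xp, np_names, estimator, estimand
                )
                pooled = p_all
            logger.warning(
                "subgroup %d fell back to the pooled main-effects model", r
            )
            values[rows] = pooled[rows]
            fits.append(StratumFit(r, int(rows.sum()), 0, np.nan,
                                   dropped, fallback_pooled=True))
            continue
        values[rows] = p
        fits.append(StratumFit(r, int(rows.sum()), it, resid, dropped))
    return PropensityVector(values, model_kind="full", estimator=estimator,
                            stratified=True, fits=fits)


def fit_health_status_ps(
    data: DisparityDataset, estimator: str = "cbps", estimand: str = "ate"
) -> PropensityVector:
    """Health-status PS: pooled fit on health-covariate main effects only."""
    X, names = _design(data.X_h)
    p, it, resid = _fit_one(data.Z, X, names, estimator, estimand)
    return PropensityVector(
        p, model_kind="health", estimator=estimator, stratified=False,
        fits=[StratumFit(None, data.n_subjects, it, resid)],
    )


def fit_full_ps_pooled(
    data: DisparityDataset, estimator: str = "cbps", estimand: str = "ate"
) -> PropensityVector:
    """Pooled full PS: main effects of SES (dummy-encoded) and health status."""
    ses_num = pd.get_dummies(
        data.X_s.astype("category"), drop_first=True, dtype=float
    )
    frame = pd.concat(
        [ses_num.reset_index(drop=True), data.X_h.reset_index(drop=True)], axis=1
    )
    X, names = _design(frame)
    p, it, resid = _fit_one(data.Z, X, names, estimator, estimand)
    return PropensityVector(
        p, model_kind="full", estimator=estimator, stratified=False,
        fits=[StratumFit(None, data.n_subjects, it, resid)],
    )
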