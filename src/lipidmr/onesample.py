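"""One-sample Mendelian randomization on individual-level data.

Two-stage least squares (2SLS) with the genetic risk score as the
instrument and covariates entering both stages; the Durbin-Wu-Hausman
endogeneity test in its augmented-regression form; the statin-interaction
analysis; and the closed-form instrumental-variable power calculation.

Standard errors follow the conventional 2SLS residual definition: the
residual variance is computed at the point estimate using the *observed*
endogenous regressors, while the coefficient covariance uses the
first-stage fitted values.  Confidence intervals use normal quantiles
(``beta -/+ 1.95996 * se``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (CollinearityError, DataError,
                         DegenerateInstrumentError, DomainError,
                         IdentificationError)

Z975 = stats.norm.ppf(0.975)


@dataclass
class IvEstimate:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    first_stage_f: float


@dataclass
class DwhResult:
    statistic: float
    p: float
    df: int


@dataclass
class PowerSpec:
    """Inputs to the instrumental-variable power calculation: sample size,
    instrument strength ``r2_gx`` (variance in exposure explained by the
    score), significance level, target power, and the exposure/outcome
    standard deviations used to express effects in natural units."""
    n: int
    r2_gx: float
    alpha: float = 0.05
    target_power: float = 0.80
    sd_exposure: float = 1.0
    sd_outcome: float = 1.0

    def validate(self):
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise DomainError("alpha and target_power must lie in (0, 1)")
        if not (0 < self.r2_gx < 1):
            raise DomainError("r2_gx must lie in (0, 1)")
        return self


def _design(n, covariates):
    """[intercept | covariates] design block."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _check_rank(M, what="design"):
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise CollinearityError(message=f"rank-deficient {what} matrix")


def _tsls_core(y, X_endog, Z_instr, covariates):
    """General just-identified 2SLS.

    Returns (beta vector for endogenous regressors, their SEs, n, k_total,
    first-stage partial F per instrument).
    """
    y = np.asarray(y, dtype=float)
    X_endog = np.atleast_2d(np.asarray(X_endog, dtype=float).T).T
    Z_instr = np.atleast_2d(np.asarray(Z_instr, dtype=float).T).T
    n = len(y)
    if X_endog.shape[0] != n or Z_instr.shape[0] != n:
        raise DataError("outcome, exposures and instruments must share length")
    k = X_endog.shape[1]
    if Z_instr.shape[1] != k:
        raise IdentificationError(
            f"{Z_instr.shape[1]} instruments for {k} endogenous regressors; "
            "just-identified 2SLS requires equal counts")
    C = _design(n, covariates)
    Z = np.column_stack([Z_instr, C])
    X = np.column_stack([X_endog, C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise IdentificationError("instrument matrix is rank deficient given covariates")
    _check_rank(X, "second-stage")

    # first stage: project each endogenous regressor on [instruments | covariates]
    coef_fs, *_ = np.linalg.lstsq(Z, X_endog, rcond=None)
    X_hat = Z @ coef_fs
    Xh = np.column_stack([X_hat, C])
    XtX = Xh.T @ Xh
    beta_all = np.linalg.solve(XtX, Xh.T @ y)
    # residuals at the point estimate use observed, not fitted, exposure
    resid = y - X @ beta_all
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov)[:k])

    # first-stage partial F of each instrument given covariates
    f_stats = []
    for j in range(k):
        fj = _partial_f(X_endog[:, j], Z_instr[:, j], C)
        f_stats.append(fj)
    return beta_all[:k], se, n, X.shape[1], np.array(f_stats)


def _partial_f(x, z, C):
    """Partial F (= squared t) of a single instrument z in the regression
    of x on [z | C]."""
    D = np.column_stack([z, C])
    coef, *_ = np.linalg.lstsq(D, x, rcond=None)
    resid = x - D @ coef
    dof = len(x) - D.shape[1]
    sigma2 = resid @ resid / dof
    DtD_inv = np.linalg.inv(D.T @ D)
    se_z = math.sqrt(sigma2 * DtD_inv[0, 0])
    if se_z == 0:
        return math.inf
    return (coef[0] / se_z) ** 2


def _estimate(beta, se, n, f):
    p = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else 0.0
    return IvEstimate(beta=float(beta), se=float(se),
                      ci_low=float(beta - Z975 * se),
                      ci_high=float(beta + Z975 * se),
                      p=float(p), n_used=int(n), first_stage_f=float(f))


def tsls(outcome, exposure, instrument, covariates=None) -> IvEstimate:
    """Two-stage least squares with one endogenous exposure and one
    instrument (the GRS), covariates in both stages.

    Emits a weak-instrument warning when the first-stage partial F of the
    instrument is <= 10.
    """
    instrument = np.asarray(instrument, dtype=float)
    if np.var(instrument) == 0:
        raise DegenerateInstrumentError("instrument has zero variance")
    beta, se, n, _, f = _tsls_core(outcome, exposure, instrument, covariates)
    if f[0] <= 10:
        warnings.warn(f"weak instrument: first-stage F = {f[0]:.2f} <= 10",
                      UserWarning, stacklevel=2)
    return _estimate(beta[0], se[0], n, f[0])


def tsls_multi(outcome, exposures, instruments, covariates=None) -> list:
    """Joint just-identified 2SLS with k endogenous exposures and k
    instruments (e.g. all three lipid scores at once).

    ``exposures`` and ``instruments`` are n-by-k arrays (or sequences of k
    vectors).  Returns one :class:`IvEstimate` per exposure, with SEs from
    the joint covariance.
    """
    X = np.column_stack(exposures) if not isinstance(exposures, np.ndarray) else np.atleast_2d(exposures.T).T
    Z = np.column_stack(instruments) if not isinstance(instruments, np.ndarray) else np.atleast_2d(instruments.T).T
    beta, se, n, _, f = _tsls_core(outcome, X, Z, covariates)
    return [_estimate(b, s, n, fj) for b, s, fj in zip(beta, se, f)]


def durbin_wu_hausman(outcome, exposure, instrument, covariates=None) -> DwhResult:
    """Durbin-Wu-Hausman endogeneity test, augmented-regression form.

    Regress the exposure on [instrument | covariates], then add the
    first-stage residuals to the outcome regression; the squared t
    statistic on the residual term is referred to chi-square with 1 df.
    A small p indicates the OLS and IV estimands differ (confounding).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    n = len(y)
    C = _design(n, covariates)
    D1 = np.column_stack([z, C])
    _check_rank(D1, "first-stage")
    coef1, *_ = np.linalg.lstsq(D1, x, rcond=None)
    v_hat = x - D1 @ coef1

    D2 = np.column_stack([x, v_hat, C])
    _check_rank(D2, "augmented")
    coef2, *_ = np.linalg.lstsq(D2, y, rcond=None)
    resid = y - D2 @ coef2
    dof = n - D2.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(D2.T @ D2)
    t_v = coef2[1] / math.sqrt(cov[1, 1])
    stat = float(t_v ** 2)
    return DwhResult(statistic=stat, p=float(stats.chi2.sf(stat, 1)), df=1)


def interaction_test(measured_exposure, standardized_score, statin_flag,
                     covariates=None) -> dict:
    """Statin-use x standardized-GRS interaction on *measured* (untreated-
    unadjusted) exposure.

    Fits ``exposure ~ score + statin + score:statin + covariates`` by OLS
    and reports the product-term coefficient.  A negative interaction
    means statin users' measured lipid rises less steeply with genetic
    score — the attenuation signature of treatment.
    """
    x = np.asarray(measured_exposure, dtype=float)
    z = np.asarray(standardized_score, dtype=float)
    s = np.asarray(statin_flag, dtype=float)
    if s.min() == s.max():
        raise DataError("statin flag is constant: interaction not estimable")
    n = len(x)
    C = _design(n, covariates)
    D = np.column_stack([z, s, z * s, C])
    _check_rank(D, "interaction")
    coef, *_ = np.linalg.lstsq(D, x, rcond=None)
    resid = x - D @ coef
    dof = n - D.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = math.sqrt(cov[2, 2])
    beta = float(coef[2])
    return {"interaction_beta": beta, "se": se,
            "p": float(2 * stats.norm.sf(abs(beta) / se))}


def min_detectable_effect(spec: PowerSpec) -> float:
    """Minimum causal effect detectable at the target power.

    Closed form for a continuous outcome:
    ``beta_std = (z_{1-alpha/2} + z_{power}) / sqrt(n * r2_gx)`` in
    standardized units, returned as
    ``beta_std * sd_outcome / sd_exposure`` in natural units.
    """
    spec.validate()
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_p = stats.norm.ppf(spec.target_power)
    beta_std = (z_a + z_p) / math.sqrt(spec.n * spec.r2_gx)
    return beta_std * spec.sd_outcome / spec.sd_exposure


def power_at_effect(effect: float, spec: PowerSpec) -> float:
    """Power to detect ``effect`` (natural units) at ``spec.alpha`` —
    the inverse of :func:`min_detectable_effect`."""
    spec.validate()
    beta_std = abs(effect) * spec.sd_exposure / spec.sd_outcome
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(beta_std * math.sqrt(spec.n * spec.r2_gx) - z_a))
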