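"""Two-sample Mendelian randomization from GWAS summary statistics.

Implements the full sensitivity suite around the per-variant Wald ratio
``ratio_j = Gamma_j / gamma_j`` (variant-outcome effect over
variant-exposure effect):

* allele harmonization between the exposure and outcome summary sets,
  with palindromic-variant handling;
* inverse-variance-weighted (IVW) estimation — fixed or multiplicative
  random effects, optionally outlier-penalized and/or robust
  (Tukey-bisquare M-estimation);
* MR-Egger regression with the intercept test for directional pleiotropy
  (p < 0.10 flags pleiotropic bias);
* weighted median and weighted mode estimators with parametric-bootstrap
  standard errors;
* multivariable MR for several exposures jointly;
* MR-PRESSO (global residual-sum-of-squares test, per-variant outlier
  test, distortion test);
* the MR-Steiger directionality test.

Every estimator returns a uniform :class:`MrResult` and is invariant to
the input order of variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataError, DegenerateInstrumentError
from .simulate import GWAS_COLUMNS

Z975 = stats.norm.ppf(0.975)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default half-width of the allele-frequency window around 0.5 inside
#: which palindromic variants are considered unresolvable and dropped
PALINDROME_EAF_WINDOW = 0.08
#: Tukey bisquare tuning constant (95% Gaussian efficiency)
TUKEY_C = 4.685
#: multiplier on the per-variant outlier p in the penalized IVW weights
PENALTY_SCALE = 20.0


@dataclass
class MrResult:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    heterogeneity_q: float
    n_variants: int
    extras: dict = field(default_factory=dict)


@dataclass
class PressoResult:
    global_p: float
    outlier_ids: list
    distortion_p: float | None
    beta_raw: float
    beta_outlier_corrected: float | None


@dataclass
class SteigerResult:
    r2_gx: float
    r2_gy: float
    direction_correct: bool | None
    p: float


def _result(method, beta, se, q, j, **extras):
    return MrResult(method=method, beta=float(beta), se=float(se),
                    ci_low=float(beta - Z975 * se),
                    ci_high=float(beta + Z975 * se),
                    p=float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0,
                    heterogeneity_q=float(q), n_variants=int(j), extras=extras)


# ---------------------------------------------------------------- harmonize

def _is_palindromic(a1, a2):
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_eaf_window: float = PALINDROME_EAF_WINDOW) -> pd.DataFrame:
    """Align outcome summary statistics to the exposure's effect alleles.

    Rules, per shared variant: identical coding passes through; swapped
    effect/other alleles flip the outcome beta's sign and complement its
    EAF; strand mismatches are resolved by base complementation for
    non-palindromic variants.  Palindromic (A/T, C/G) variants are aligned
    by allele-frequency concordance, and dropped (flagged, not used in
    estimation) when either EAF lies within ``0.5 +/- window``.  Variants
    whose alleles cannot be reconciled are excluded with a flag rather
    than failing the whole set.

    Returns a DataFrame ordered by variant id with columns ``variant_id,
    gamma, se_gamma, Gamma, se_Gamma, eaf, sign_flipped,
    dropped_palindromic, excluded``; estimators use the rows with
    ``~dropped_palindromic & ~excluded``.
    """
    ex = exposure.set_index("variant_id")
    ou = outcome.set_index("variant_id")
    shared = sorted(set(ex.index) & set(ou.index))
    if not shared:
        raise DataError("no shared variant ids between exposure and outcome sets")
    rows = []
    for vid in shared:
        e, o = ex.loc[vid], ou.loc[vid]
        ea_x, oa_x = str(e["effect_allele"]), str(e["other_allele"])
        ea_y, oa_y = str(o["effect_allele"]), str(o["other_allele"])
        beta_y, eaf_y = float(o["beta"]), float(o["eaf"])
        flipped = dropped = excluded = False

        if _is_palindromic(ea_x, oa_x):
            amb = (abs(float(e["eaf"]) - 0.5) < palindrome_eaf_window or
                   abs(eaf_y - 0.5) < palindrome_eaf_window)
            if amb:
                dropped = True
            elif (float(e["eaf"]) - 0.5) * (eaf_y - 0.5) < 0:
                beta_y, eaf_y, flipped = -beta_y, 1 - eaf_y, True
        else:
            pairs = {(ea_y, oa_y): False,
                     (oa_y, ea_y): True,
                     (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?")): False,
                     (_COMPLEMENT.get(oa_y, "?"), _COMPLEMENT.get(ea_y, "?")): True}
            key = (ea_x, oa_x)
            if key in pairs:
                if pairs[key]:
                    beta_y, eaf_y, flipped = -beta_y, 1 - eaf_y, True
            else:
                excluded = True
        rows.append({
            "variant_id": vid,
            "gamma": float(e["beta"]), "se_gamma": float(e["se"]),
            "Gamma": beta_y, "se_Gamma": float(o["se"]),
            "eaf": float(e["eaf"]), "eaf_outcome": eaf_y,
            "sign_flipped": flipped, "dropped_palindromic": dropped,
            "excluded": excluded,
        })
    return pd.DataFrame(rows)


def _usable(h: pd.DataFrame) -> pd.DataFrame:
    out = h
    for flag in ("dropped_palindromic", "excluded"):
        if flag in out.columns:
            out = out[~out[flag]]
    return out.reset_index(drop=True)


def wald_ratios(h: pd.DataFrame) -> pd.DataFrame:
    """Per-variant ratio estimates ``Gamma/gamma`` with first-order
    (delta-method) SEs ``se_Gamma/|gamma|``; variants with ``gamma == 0``
    are excluded."""
    d = _usable(h)
    d = d[d["gamma"] != 0].reset_index(drop=True)
    if len(d) == 0:
        raise DataError("no variants with nonzero exposure effect")
    return pd.DataFrame({
        "variant_id": d["variant_id"],
        "ratio": d["Gamma"] / d["gamma"],
        "se": d["se_Gamma"] / d["gamma"].abs(),
    })


def _require(h, k, method):
    d = _usable(h)
    if len(d) < k:
        raise DegenerateInstrumentError(
            f"{method} requires >= {k} variants; got {len(d)}")
    return d


# ---------------------------------------------------------------- IVW family

def _ivw_fit(gamma, Gamma, w):
    """Weighted regression through the origin; returns (beta, fixed se, Q)."""
    s_xx = np.sum(w * gamma**2)
    beta = np.sum(w * gamma * Gamma) / s_xx
    se = math.sqrt(1.0 / s_xx)
    q = float(np.sum(w * (Gamma - beta * gamma) ** 2))
    return float(beta), se, q


def ivw(h: pd.DataFrame, mode: str = "multiplicative_random",
        robust: bool = False, penalized: bool = False,
        tukey_c: float = TUKEY_C, penalty_scale: float = PENALTY_SCALE,
        tol: float = 1e-8, max_iter: int = 200) -> MrResult:
    """Inverse-variance-weighted estimate: weighted regression of the
    variant-outcome betas on the variant-exposure betas through the
    origin, weights ``1/se_Gamma^2``.

    ``mode="multiplicative_random"`` inflates the SE by
    ``max(1, sqrt(Q/(J-1)))``; ``penalized`` down-weights variants whose
    heterogeneity contribution is improbable under chi-square(1)
    (weight multiplier ``min(1, 20 q_j)``); ``robust`` replaces least
    squares by Tukey-bisquare M-estimation (tuning 4.685, iterated to
    1e-8).
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ConfigError(f"unknown IVW mode {mode!r}")
    d = _require(h, 2, "IVW")
    gamma = d["gamma"].to_numpy()
    Gamma = d["Gamma"].to_numpy()
    w = 1.0 / d["se_Gamma"].to_numpy() ** 2
    j = len(d)

    beta, se, q = _ivw_fit(gamma, Gamma, w)
    if penalized:
        # per-variant heterogeneity contribution on the ratio scale
        ratio = Gamma / gamma
        v = gamma**2 * w
        q_j = v * (ratio - beta) ** 2
        pen_p = stats.chi2.sf(q_j, 1)
        w = w * np.minimum(1.0, penalty_scale * pen_p)
        beta, se, q = _ivw_fit(gamma, Gamma, w)
    if robust:
        for _ in range(max_iter):
            r = np.sqrt(w) * (Gamma - beta * gamma)
            scale = np.median(np.abs(r - np.median(r))) / 0.6745
            if scale <= 0:
                break
            u = r / (tukey_c * scale)
            m = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            if m.sum() == 0 or np.sum(m * w * gamma**2) == 0:
                break
            beta_new, se, q = _ivw_fit(gamma, Gamma, w * m)
            if abs(beta_new - beta) < tol:
                beta = beta_new
                break
            beta = beta_new
        # Q reported against the original weights for interpretability
        q = float(np.sum((1.0 / d["se_Gamma"].to_numpy() ** 2)
                         * (Gamma - beta * gamma) ** 2))
    if mode == "multiplicative_random" and j > 1:
        se *= max(1.0, math.sqrt(q / (j - 1)))
    name = "ivw"
    if robust or penalized:
        name += "_" + "_".join(n for n, on in
                               (("robust", robust), ("penalized", penalized)) if on)
    return _result(name, beta, se, q, j)


def mr_egger(h: pd.DataFrame, mode: str = "multiplicative_random") -> MrResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas
    *with* an intercept, each variant oriented so its exposure effect is
    positive.  The intercept estimates the average directional pleiotropy;
    its test (p < 0.10 by convention) flags pleiotropic bias.
    """
    d = _require(h, 3, "MR-Egger")
    sign = np.sign(d["gamma"].to_numpy())
    sign[sign == 0] = 1.0
    gamma = d["gamma"].to_numpy() * sign
    Gamma = d["Gamma"].to_numpy() * sign
    w = 1.0 / d["se_Gamma"].to_numpy() ** 2
    j = len(d)

    X = np.column_stack([np.ones(j), gamma])
    W = np.diag(w)
    XtWX = X.T @ W @ X
    coef = np.linalg.solve(XtWX, X.T @ (w * Gamma))
    resid = Gamma - X @ coef
    q = float(np.sum(w * resid**2))
    cov = np.linalg.inv(XtWX)
    scale = max(1.0, math.sqrt(q / (j - 2))) if (mode == "multiplicative_random" and j > 2) else 1.0
    se_int = math.sqrt(cov[0, 0]) * scale
    se_slope = math.sqrt(cov[1, 1]) * scale
    intercept = float(coef[0])
    intercept_p = float(2 * stats.norm.sf(abs(intercept) / se_int)) if se_int > 0 else 0.0
    return _result("mr_egger", coef[1], se_slope, q, j,
                   egger_intercept=intercept,
                   egger_intercept_se=se_int,
                   egger_intercept_p=intercept_p,
                   pleiotropy_flag=intercept_p < 0.10)


# ------------------------------------------------------- median & mode

def _weighted_median_point(ratio, weight):
    # aggregate identical ratio values so the estimate depends only on the
    # normalized weight distribution (duplication-invariant)
    r, inv = np.unique(ratio, return_inverse=True)
    v = np.bincount(inv, weights=weight)
    cum = np.cumsum(v) - v / 2.0
    p = cum / v.sum()
    return float(np.interp(0.5, p, r))


def _parametric_boot(h, point_fn, n_boot, seed):
    d = _usable(h)
    rng = np.random.default_rng(seed)
    gamma = d["gamma"].to_numpy()
    Gamma = d["Gamma"].to_numpy()
    se_g = d["se_gamma"].to_numpy()
    se_G = d["se_Gamma"].to_numpy()
    est = np.empty(n_boot)
    for b in range(n_boot):
        g = rng.normal(gamma, se_g)
        G = rng.normal(Gamma, se_G)
        g = np.where(g == 0, 1e-300, g)
        est[b] = point_fn(G / g, g**2 / se_G**2)
    return float(np.std(est, ddof=1))


def weighted_median(h: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted median of the Wald ratios (inverse-variance weights),
    consistent when at least half the weight comes from valid instruments.
    SE by parametric bootstrap of the summary statistics."""
    d = _require(h, 3, "weighted median")
    wr = wald_ratios(d)
    ratio = wr["ratio"].to_numpy()
    weight = 1.0 / wr["se"].to_numpy() ** 2
    beta = _weighted_median_point(ratio, weight)
    se = _parametric_boot(d, _weighted_median_point, n_boot, seed)
    w_G = 1.0 / d["se_Gamma"].to_numpy() ** 2
    q = float(np.sum(w_G * (d["Gamma"].to_numpy() - beta * d["gamma"].to_numpy()) ** 2))
    return _result("weighted_median", beta, se, q, len(d))


def _silverman_bw(x, weight=None):
    s = np.std(x, ddof=1) if len(x) > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    if spread <= 0:
        return 0.0
    return 0.9 * spread * len(x) ** (-0.2)


def _weighted_mode_point(ratio, weight, phi=1.0, grid_size=512):
    h_bw = phi * _silverman_bw(ratio)
    if h_bw <= 0:
        return float(ratio[0])
    lo, hi = ratio.min() - 3 * h_bw, ratio.max() + 3 * h_bw
    grid = np.linspace(lo, hi, grid_size)
    dens = np.sum(weight[:, None]
                  * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h_bw) ** 2),
                  axis=0)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: pd.DataFrame, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-mode estimate: argmax of a Gaussian kernel density over
    the Wald ratios with inverse-variance weights (bandwidth = factor x
    modified Silverman rule, 512-point grid).  Consistent when the largest
    homogeneous cluster of instruments is valid."""
    d = _require(h, 3, "weighted mode")
    wr = wald_ratios(d)
    ratio = wr["ratio"].to_numpy()
    weight = 1.0 / wr["se"].to_numpy() ** 2
    beta = _weighted_mode_point(ratio, weight, bandwidth_factor)
    se = _parametric_boot(
        d, lambda r, w: _weighted_mode_point(r, w, bandwidth_factor), n_boot, seed)
    w_G = 1.0 / d["se_Gamma"].to_numpy() ** 2
    q = float(np.sum(w_G * (d["Gamma"].to_numpy() - beta * d["gamma"].to_numpy()) ** 2))
    return _result("weighted_mode", beta, se, q, len(d))


# ------------------------------------------------------------------- MVMR

def mvmr(Gamma, se_Gamma, gamma_matrix, exposure_names=None,
         mode: str = "fixed") -> list:
    """Multivariable MR: weighted multiple regression of the variant-
    outcome betas on k columns of variant-exposure betas, no intercept,
    weights ``1/se_Gamma^2``.  With k = 1 this is exactly fixed-effect
    IVW.  ``mode="multiplicative_random"`` applies the usual SE inflation.
    """
    Gamma = np.asarray(Gamma, dtype=float)
    se_Gamma = np.asarray(se_Gamma, dtype=float)
    X = np.asarray(gamma_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    j, k = X.shape
    if j < k + 1:
        raise DegenerateInstrumentError(f"MVMR with {k} exposures needs >= {k + 1} variants")
    if np.linalg.matrix_rank(X) < k:
        raise DataError("exposure beta matrix is rank deficient: exposures not identified")
    names = exposure_names or [f"exposure_{i}" for i in range(k)]
    w = 1.0 / se_Gamma**2
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * Gamma))
    resid = Gamma - X @ coef
    q = float(np.sum(w * resid**2))
    cov = np.linalg.inv(XtWX)
    scale = max(1.0, math.sqrt(q / (j - k))) if (mode == "multiplicative_random" and j > k) else 1.0
    out = []
    for i, name in enumerate(names):
        se = math.sqrt(cov[i, i]) * scale
        out.append(_result(f"mvmr[{name}]", coef[i], se, q, j))
    return out


# ---------------------------------------------------------------- MR-PRESSO

def _loo_ivw_beta(gamma, Gamma, w):
    """Leave-one-out fixed IVW betas, closed form, vectorized.
    Supports stacked 2-d inputs (n_sim x J)."""
    s_xx = np.sum(w * gamma**2, axis=-1, keepdims=True)
    s_xy = np.sum(w * gamma * Gamma, axis=-1, keepdims=True)
    return (s_xy - w * gamma * Gamma) / (s_xx - w * gamma**2)


def mr_presso(h: pd.DataFrame, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR pleiotropy residual sum and outlier (MR-PRESSO) procedure.

    Global test: the observed residual sum of squares, with each variant's
    residual taken against the leave-one-out IVW slope, is compared with
    its parametric null distribution obtained by redrawing the summary
    statistics under the fitted no-pleiotropy model.  Outlier test:
    per-variant simulated p-values, Bonferroni-corrected at
    ``outlier_alpha``.  Distortion test: the relative change in the IVW
    estimate after outlier removal is compared with the distribution of
    changes from removing equally many randomly chosen variants.
    """
    d = _require(h, 4, "MR-PRESSO")
    gamma = d["gamma"].to_numpy()
    Gamma = d["Gamma"].to_numpy()
    se_g = d["se_gamma"].to_numpy()
    se_G = d["se_Gamma"].to_numpy()
    ids = d["variant_id"].to_numpy()
    w = 1.0 / se_G**2
    j = len(d)
    rng = np.random.default_rng(seed)

    beta_loo = np.asarray(_loo_ivw_beta(gamma, Gamma, w)).reshape(-1)
    rss_j_obs = w * (Gamma - gamma * beta_loo) ** 2
    rss_obs = float(rss_j_obs.sum())

    # parametric null: redraw summary stats assuming no pleiotropy
    g_sim = rng.normal(gamma, se_g, size=(n_sim, j))
    G_sim = rng.normal(gamma * beta_loo, se_G, size=(n_sim, j))
    beta_loo_sim = _loo_ivw_beta(g_sim, G_sim, w)
    rss_j_sim = w * (G_sim - g_sim * beta_loo_sim) ** 2
    rss_sim = rss_j_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_j = (1 + np.sum(rss_j_sim >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_mask = p_j * j < outlier_alpha
    outlier_ids = [str(v) for v in ids[outlier_mask]]

    beta_raw, _, _ = _ivw_fit(gamma, Gamma, w)
    if not outlier_ids:
        return PressoResult(global_p=global_p, outlier_ids=[],
                            distortion_p=None, beta_raw=beta_raw,
                            beta_outlier_corrected=None)
    keep = ~outlier_mask
    if keep.sum() < 2:
        raise DataError("all variants flagged as outliers: corrected estimate undefined")
    beta_corr, _, _ = _ivw_fit(gamma[keep], Gamma[keep], w[keep])

    n_out = int(outlier_mask.sum())
    obs_d = (beta_raw - beta_corr) / beta_corr
    # null distortion: drop n_out random variants per draw, vectorized
    order = np.argsort(rng.random((n_sim, j)), axis=1)
    keep_mask = order >= n_out
    s_xx = np.sum(keep_mask * w * gamma**2, axis=1)
    s_xy = np.sum(keep_mask * w * gamma * Gamma, axis=1)
    betas_null = s_xy / s_xx
    null_d = (beta_raw - betas_null) / betas_null
    distortion_p = float((1 + np.sum(np.abs(null_d) >= abs(obs_d))) / (n_sim + 1))
    return PressoResult(global_p=global_p, outlier_ids=outlier_ids,
                        distortion_p=distortion_p, beta_raw=beta_raw,
                        beta_outlier_corrected=beta_corr)


# ----------------------------------------------------------------- Steiger

def steiger(h: pd.DataFrame, n_exposure: int, n_outcome: int,
            var_exposure: float = 1.0, var_outcome: float = 1.0) -> SteigerResult:
    """MR-Steiger directionality test.

    The instruments' variance explained in exposure and outcome is
    ``sum_j 2 eaf_j (1 - eaf_j) beta_j^2 / var`` (variances default to 1,
    i.e. standardized traits); causality X -> Y is supported when
    ``r2_gx > r2_gy``.  The p-value compares the Fisher-transformed
    multiple correlations with variance ``1/(n_exp - 3) + 1/(n_out - 3)``.
    """
    d = _usable(h)
    two_pq = 2 * d["eaf"].to_numpy() * (1 - d["eaf"].to_numpy())
    r2_gx = float(np.sum(two_pq * d["gamma"].to_numpy() ** 2) / var_exposure)
    r2_gy = float(np.sum(two_pq * d["Gamma"].to_numpy() ** 2) / var_outcome)
    for name, v in (("r2_gx", r2_gx), ("r2_gy", r2_gy)):
        if v >= 1:
            raise DataError(f"{name} = {v:.3f} >= 1: inconsistent inputs")
    z_x = np.arctanh(math.sqrt(r2_gx))
    z_y = np.arctanh(math.sqrt(r2_gy))
    denom = math.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = (z_x - z_y) / denom
    p = float(2 * stats.norm.sf(abs(z)))
    direction = None if r2_gx == r2_gy else bool(r2_gx > r2_gy)
    return SteigerResult(r2_gx=r2_gx, r2_gy=r2_gy,
                         direction_correct=direction, p=p)


# ---------------------------------------------------------------- reporting

def scale_per_sd(result: MrResult, sd_exposure: float) -> MrResult:
    """Re-express an estimate per 1-SD increase in the exposure (multiply
    by the exposure SD in the estimate's current units)."""
    if sd_exposure <= 0:
        raise ConfigError("sd_exposure must be positive")
    c = sd_exposure
    return MrResult(method=result.method + "_per_sd",
                    beta=result.beta * c, se=result.se * c,
                    ci_low=result.ci_low * c, ci_high=result.ci_high * c,
                    p=result.p, heterogeneity_q=result.heterogeneity_q,
                    n_variants=result.n_variants, extras=dict(result.extras))
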