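"""Synthetic cohorts and two-sample GWAS summary statistics with known truth.

The generative model is the canonical instrumental-variable setup with a
single latent confounder ``U ~ N(0,1)``:

    X = G @ gamma + a_x * U + eps_x              (exposure, e.g. LDL)
    Y = beta * X + a_y * U + G @ alpha + eps_y   (outcome, e.g. LV mass)

``G`` is an n-by-m dosage matrix drawn under Hardy-Weinberg equilibrium,
``Binomial(2, MAF)`` per variant.  ``alpha`` is nonzero only for the
configured invalid (pleiotropic) fraction of variants.  Per-variant
effects ``gamma`` are rescaled so the true weighted score explains a
target fraction of the exposure variance (defaults mirror the cohort the
generator emulates: ~17,000 individuals, ~101 variants, R^2 of 10.8% for
LDL, with 7.3%/5.0% as the HDL/triglyceride analogues).

Statin use is assigned by a logistic model on the standardized true score,
and statin users' *measured* exposure equals the true exposure divided by
the LDL-reduction factor (1.43), so the preprocessing adjustment is its
exact inverse.  With opposite-signed confounder loadings on exposure and
outcome the observational estimate flips sign relative to the causal
``beta`` — the discordance signature the downstream analyses test for.

All randomness derives from one integer seed via ``numpy`` SeedSequence
spawning (documented order: variants, dosages, confounder, noise,
covariates, statin).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DataError

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GWAS_COLUMNS = ["variant_id", "effect_allele", "other_allele",
                "eaf", "beta", "se", "p", "n"]


@dataclass
class SimulationParams:
    """Ground-truth parameters for one synthetic cohort.

    ``confounder_loadings = (a_x, a_y)`` are the confounder's effects on
    exposure and outcome; the defaults (+1.5, -1.5) make the omitted-
    variable bias ``a_x a_y var(U) / var(X)`` exceed the default causal
    effect in magnitude, so the observational slope is sign-flipped
    against a positive ``causal_beta`` while the IV estimate is not.
    ``target_r2`` is the fraction of exposure variance explained by the
    true score (default 0.108, the LDL anchor; use 0.073 / 0.050 for the
    HDL / triglyceride analogues).
    """
    n_individuals: int = 17000
    n_variants: int = 101
    maf_range: tuple = (0.05, 0.5)
    causal_beta: float = 0.5
    confounder_loadings: tuple = (1.5, -1.5)
    fraction_invalid: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    noise_sd_exposure: float = 1.0
    noise_sd_outcome: float = 1.0
    target_r2: float = 0.108
    statin_intercept: float = -1.7
    statin_slope: float = 0.5
    ldl_reduction_factor: float = 1.43
    palindromic_fraction: float = 0.0
    seed: int = 0

    def validate(self):
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low < high <= 0.5")
        if not (0 < self.target_r2 < 1):
            raise ConfigError("target_r2 must lie in (0, 1)")
        if not (0 <= self.fraction_invalid <= 1):
            raise ConfigError("fraction_invalid must lie in [0, 1]")
        if self.n_variants < 1 or self.n_individuals < 1:
            raise ConfigError("n_variants and n_individuals must be positive")
        return self

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["confounder_loadings"] = list(self.confounder_loadings)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["maf_range"] = tuple(d["maf_range"])
        d["confounder_loadings"] = tuple(d["confounder_loadings"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Individual-level synthetic data plus the generating truth."""
    dosages: np.ndarray            # n x m, entries in {0, 1, 2}
    variants: pd.DataFrame         # variant_id, effect_allele, other_allele, maf, gamma, alpha
    exposure_true: np.ndarray
    exposure_measured: np.ndarray
    outcome: np.ndarray
    confounder: np.ndarray
    covariates: pd.DataFrame
    on_statin: np.ndarray
    params: SimulationParams

    @property
    def n(self):
        return self.dosages.shape[0]

    def true_score(self) -> np.ndarray:
        return self.dosages @ self.variants["gamma"].to_numpy()

    def write(self, prefix):
        """Write cohort CSVs plus a JSON truth sidecar under ``prefix``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pheno = self.covariates.copy()
        pheno.insert(0, "participant_id", np.arange(self.n))
        pheno["exposure_true"] = self.exposure_true
        pheno["exposure_measured"] = self.exposure_measured
        pheno["outcome"] = self.outcome
        pheno["confounder"] = self.confounder
        pheno["on_statin"] = self.on_statin.astype(int)
        pheno.to_csv(f"{prefix}.phenotypes.csv", index=False)
        self.variants.to_csv(f"{prefix}.variants.csv", index=False)
        dos = pd.DataFrame(self.dosages, columns=self.variants["variant_id"])
        dos.to_csv(f"{prefix}.dosages.csv", index=False)
        with open(f"{prefix}.truth.json", "w") as fh:
            json.dump(self.params.to_dict(), fh, indent=2)

    @classmethod
    def read(cls, prefix):
        prefix = Path(prefix)
        pheno = pd.read_csv(f"{prefix}.phenotypes.csv")
        variants = pd.read_csv(f"{prefix}.variants.csv")
        dosages = pd.read_csv(f"{prefix}.dosages.csv").to_numpy(dtype=float)
        with open(f"{prefix}.truth.json") as fh:
            params = SimulationParams.from_dict(json.load(fh))
        cov_cols = [c for c in pheno.columns if c not in
                    ("participant_id", "exposure_true", "exposure_measured",
                     "outcome", "confounder", "on_statin")]
        return cls(
            dosages=dosages, variants=variants,
            exposure_true=pheno["exposure_true"].to_numpy(),
            exposure_measured=pheno["exposure_measured"].to_numpy(),
            outcome=pheno["outcome"].to_numpy(),
            confounder=pheno["confounder"].to_numpy(),
            covariates=pheno[cov_cols],
            on_statin=pheno["on_statin"].to_numpy().astype(bool),
            params=params,
        )


def _spawn(seed, k):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(k)]


def simulate_variants(n_variants: int, maf_range=(0.05, 0.5), effect_sd: float = 1.0,
                      seed: int = 0, palindromic_fraction: float = 0.0,
                      target_r2: float | None = None,
                      residual_var: float = 1.0) -> pd.DataFrame:
    """Draw a biallelic variant panel with per-variant exposure effects.

    MAFs are uniform in ``maf_range``; allele pairs include a configurable
    fraction of palindromic (A/T or C/G) variants so harmonization logic
    can be exercised.  When ``target_r2`` is given, the raw
    ``gamma ~ N(0, effect_sd^2)`` draws are rescaled so the true score's
    variance under Hardy-Weinberg, ``sum 2 p (1-p) gamma^2``, explains
    ``target_r2`` of an exposure whose non-genetic variance is
    ``residual_var``.
    """
    lo, hi = maf_range
    if lo >= hi:
        raise ConfigError("degenerate maf_range: low >= high")
    if n_variants < 1:
        raise ConfigError("n_variants must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    maf = rng.uniform(lo, hi, n_variants)
    gamma = rng.normal(0.0, effect_sd, n_variants)
    if target_r2 is not None:
        v_score = np.sum(2 * maf * (1 - maf) * gamma**2)
        scale = np.sqrt(target_r2 / (1 - target_r2) * residual_var / v_score)
        gamma = gamma * scale

    is_pal = rng.random(n_variants) < palindromic_fraction
    eff = np.empty(n_variants, dtype=object)
    oth = np.empty(n_variants, dtype=object)
    for j in range(n_variants):
        if is_pal[j]:
            a = rng.choice(["A", "C"])
            eff[j], oth[j] = a, _COMPLEMENT[a]
        else:
            a = rng.choice(_BASES)
            choices = [b for b in _BASES if b != a and b != _COMPLEMENT[a]]
            eff[j], oth[j] = a, rng.choice(choices)
    ids = [f"rs{j + 1:05d}" for j in range(n_variants)]
    return pd.DataFrame({
        "variant_id": ids, "effect_allele": eff, "other_allele": oth,
        "maf": maf, "gamma": gamma, "alpha": np.zeros(n_variants),
    })


def _assign_pleiotropy(variants: pd.DataFrame, params: SimulationParams, rng) -> pd.DataFrame:
    variants = variants.copy()
    m = len(variants)
    n_invalid = int(round(params.fraction_invalid * m))
    alpha = np.zeros(m)
    if n_invalid > 0:
        idx = rng.choice(m, size=n_invalid, replace=False)
        alpha[idx] = rng.normal(params.pleiotropy_mean, params.pleiotropy_sd, n_invalid)
    variants["alpha"] = alpha
    return variants


def _default_panel(params: SimulationParams) -> pd.DataFrame:
    """Variant panel (with pleiotropy assignment) implied by ``params``."""
    a_x = params.confounder_loadings[0]
    variants = simulate_variants(
        params.n_variants, params.maf_range, 1.0, seed=params.seed,
        palindromic_fraction=params.palindromic_fraction,
        target_r2=params.target_r2,
        residual_var=a_x**2 + params.noise_sd_exposure**2)
    return _assign_pleiotropy(variants, params,
                              np.random.default_rng(params.seed + 1))


def _draw_covariates(n, rng) -> pd.DataFrame:
    """Plausible covariate distributions for a middle-aged population
    cohort; independent of genotype by construction."""
    sex = rng.integers(0, 2, n)  # 1 = male
    height = np.where(sex == 1, rng.normal(176, 7, n), rng.normal(163, 6, n))
    bmi = np.exp(rng.normal(np.log(27), 0.15, n))
    weight = bmi * (height / 100) ** 2
    met = np.exp(rng.normal(np.log(1200), 0.9, n))
    met[rng.random(n) < 0.05] = 0.0
    return pd.DataFrame({
        "age": rng.normal(57, 8, n).round(1),
        "sex": sex,
        "bmi": bmi,
        "height": height,
        "weight": weight,
        "sbp": rng.normal(138, 18, n),
        "on_antihypertensive": (rng.random(n) < 0.23).astype(int),
        "met_min_week": met,
        "smoking": rng.choice([0, 1, 2], size=n, p=[0.55, 0.35, 0.10]),
        "hba1c": np.exp(rng.normal(np.log(35.5), 0.08, n)),
        "cvd_present": (rng.random(n) < 0.07).astype(int),
        **{f"pc{k}": rng.normal(0, 1, n) for k in range(1, 6)},
    })


def simulate_cohort(params: SimulationParams,
                    variants: pd.DataFrame | None = None) -> SyntheticCohort:
    """Generate one individual-level cohort under the structural model.

    A pre-drawn variant panel may be supplied (for two-sample designs that
    share instruments across cohorts); otherwise one is drawn from
    ``params``.
    """
    params.validate()
    rngs = _spawn(params.seed, 6)
    _, rng_dos, rng_u, rng_noise, rng_cov, rng_statin = rngs

    a_x, a_y = params.confounder_loadings
    if variants is None:
        # the panel is a deterministic function of params.seed, so a
        # cohort and a two-sample design built from the same params share
        # their instruments
        variants = _default_panel(params)
    n, m = params.n_individuals, len(variants)
    maf = variants["maf"].to_numpy()
    gamma = variants["gamma"].to_numpy()
    alpha = variants["alpha"].to_numpy()

    dosages = rng_dos.binomial(2, maf, size=(n, m)).astype(float)
    u = rng_u.normal(0, 1, n)
    eps_x = rng_noise.normal(0, params.noise_sd_exposure, n)
    eps_y = rng_noise.normal(0, params.noise_sd_outcome, n)

    exposure_true = dosages @ gamma + a_x * u + eps_x
    outcome = params.causal_beta * exposure_true + a_y * u + dosages @ alpha + eps_y

    score = dosages @ gamma
    z = (score - score.mean()) / score.std()
    p_statin = 1.0 / (1.0 + np.exp(-(params.statin_intercept + params.statin_slope * z)))
    on_statin = rng_statin.random(n) < p_statin
    exposure_measured = np.where(on_statin,
                                 exposure_true / params.ldl_reduction_factor,
                                 exposure_true)

    covariates = _draw_covariates(n, rng_cov)
    return SyntheticCohort(
        dosages=dosages, variants=variants,
        exposure_true=exposure_true, exposure_measured=exposure_measured,
        outcome=outcome, confounder=u, covariates=covariates,
        on_statin=on_statin, params=params,
    )


def _marginal_gwas(trait: np.ndarray, dosages: np.ndarray,
                   variants: pd.DataFrame) -> pd.DataFrame:
    """Per-variant simple regression of trait on dosage, vectorized."""
    n, m = dosages.shape
    g_c = dosages - dosages.mean(axis=0)
    t_c = trait - trait.mean()
    sxx = np.sum(g_c**2, axis=0)
    beta = (g_c.T @ t_c) / sxx
    resid_var = (np.sum(t_c**2) - beta**2 * sxx) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "variant_id": variants["variant_id"].to_numpy(),
        "effect_allele": variants["effect_allele"].to_numpy(),
        "other_allele": variants["other_allele"].to_numpy(),
        "eaf": dosages.mean(axis=0) / 2.0,
        "beta": beta, "se": se,
        "p": np.clip(p, 1e-300, 1.0), "n": n,
    })


def scramble_coding(summary: pd.DataFrame, seed: int,
                    swap_fraction: float = 0.5,
                    strand_flip_fraction: float = 0.3) -> pd.DataFrame:
    """Randomly swap effect/other alleles (flipping beta, complementing
    eaf) and flip strand labels on non-palindromic variants, to exercise
    harmonization.  The encoded association is unchanged."""
    rng = np.random.default_rng(seed)
    out = summary.copy().reset_index(drop=True)
    for j in range(len(out)):
        ea, oa = out.at[j, "effect_allele"], out.at[j, "other_allele"]
        if _COMPLEMENT[ea] != oa and rng.random() < strand_flip_fraction:
            out.at[j, "effect_allele"] = _COMPLEMENT[ea]
            out.at[j, "other_allele"] = _COMPLEMENT[oa]
        if rng.random() < swap_fraction:
            ea, oa = out.at[j, "effect_allele"], out.at[j, "other_allele"]
            out.at[j, "effect_allele"], out.at[j, "other_allele"] = oa, ea
            out.at[j, "beta"] = -out.at[j, "beta"]
            out.at[j, "eaf"] = 1.0 - out.at[j, "eaf"]
    return out


def simulate_summary_stats(n_variants: int = 101, causal_beta: float = 0.5,
                           gamma_mean: float = 0.1, gamma_sd: float = 0.03,
                           se_gamma: float = 0.005, se_Gamma: float = 0.01,
                           fraction_invalid: float = 0.0,
                           pleiotropy_mean: float = 0.0,
                           pleiotropy_sd: float = 0.0,
                           eaf: float = 0.3,
                           seed: int = 0) -> pd.DataFrame:
    """Draw an already-harmonized summary-statistic set directly.

    Skips the individual-level cohorts: true per-variant exposure effects
    are ``N(gamma_mean, gamma_sd)``, observed effects add independent
    normal noise with the stated SEs, and outcome effects are
    ``causal_beta * gamma_true + alpha_j`` plus noise, with ``alpha``
    nonzero for the invalid fraction.  Useful for estimator calibration
    studies where the genotype layer is irrelevant.

    Returns a DataFrame in the harmonized layout (``gamma, se_gamma,
    Gamma, se_Gamma, eaf``) ready for any two-sample estimator.
    """
    rng = np.random.default_rng(seed)
    g_true = rng.normal(gamma_mean, gamma_sd, n_variants)
    alpha = np.zeros(n_variants)
    n_invalid = int(round(fraction_invalid * n_variants))
    if n_invalid > 0:
        idx = rng.choice(n_variants, size=n_invalid, replace=False)
        alpha[idx] = rng.normal(pleiotropy_mean, pleiotropy_sd, n_invalid)
    return pd.DataFrame({
        "variant_id": [f"rs{j + 1:05d}" for j in range(n_variants)],
        "gamma": rng.normal(g_true, se_gamma),
        "se_gamma": np.full(n_variants, se_gamma),
        "Gamma": rng.normal(causal_beta * g_true + alpha, se_Gamma),
        "se_Gamma": np.full(n_variants, se_Gamma),
        "eaf": np.full(n_variants, float(eaf)),
        "alpha_true": alpha,
    })


def simulate_two_sample(params: SimulationParams,
                        n_exposure: int = 188577, n_outcome: int = 16923,
                        seeds: tuple = (1, 2),
                        analytic: bool = False,
                        analytic_se: float = 1e-8,
                        variants: pd.DataFrame | None = None):
    """Two-sample GWAS summary statistics from non-overlapping cohorts.

    Default sample sizes mirror the consortium setting the generator
    emulates: a large exposure GWAS (n = 188,577) and a smaller outcome
    GWAS (n = 16,923); the large exposure sample keeps per-variant effect
    noise — and hence regression-dilution weak-instrument bias — small.

    Draws one shared variant panel, then two independent cohorts; the
    exposure-sample statistics regress the exposure on dosage, the
    outcome-sample statistics regress the outcome on dosage.  In
    ``analytic`` mode the sampling noise is suppressed: betas equal their
    generative expectations (``gamma_j`` and
    ``beta * gamma_j + alpha_j``) with a tiny nominal SE, so every valid
    Wald ratio equals ``causal_beta`` exactly.

    Returns ``(exposure_summary, outcome_summary, variants)``.
    """
    params.validate()
    s_exp, s_out = seeds
    if s_exp == s_out:
        raise ConfigError("exposure and outcome samples need distinct seeds")
    if variants is None:
        variants = _default_panel(params)

    if analytic:
        gamma = variants["gamma"].to_numpy()
        alpha = variants["alpha"].to_numpy()
        eaf = variants["maf"].to_numpy()
        base = {
            "variant_id": variants["variant_id"].to_numpy(),
            "effect_allele": variants["effect_allele"].to_numpy(),
            "other_allele": variants["other_allele"].to_numpy(),
            "eaf": eaf, "se": np.full(len(variants), analytic_se),
            "p": np.full(len(variants), 1e-300),
        }
        exp_sum = pd.DataFrame({**base, "beta": gamma, "n": n_exposure})[GWAS_COLUMNS]
        out_sum = pd.DataFrame({**base,
                                "beta": params.causal_beta * gamma + alpha,
                                "n": n_outcome})[GWAS_COLUMNS]
        return exp_sum, out_sum, variants

    p_exp = dataclasses.replace(params, n_individuals=n_exposure, seed=s_exp)
    p_out = dataclasses.replace(params, n_individuals=n_outcome, seed=s_out)
    coh_exp = simulate_cohort(p_exp, variants=variants)
    coh_out = simulate_cohort(p_out, variants=variants)
    exp_sum = _marginal_gwas(coh_exp.exposure_true, coh_exp.dosages, variants)
    out_sum = _marginal_gwas(coh_out.outcome, coh_out.dosages, variants)
    return exp_sum, out_sum, variants


def write_gwas_summary(summary: pd.DataFrame, path):
    """Write a GWAS summary-statistic table as TSV."""
    summary[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"summary file lacks columns {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise DataError("all SEs must be positive")
    return df
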