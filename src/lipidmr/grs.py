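"""Genetic-risk-score instrument construction and diagnostics.

A weighted GRS is the sum over selected variants of (effect size x number
of effect alleles).  Variants enter the score after genome-wide
significance filtering (p < 5e-8) and greedy LD clumping (pairwise
r^2 < 0.01); instrument relevance is quantified by the variance the score
explains in the measured exposure and the corresponding F statistic
``F = (n - 2) R^2 / (1 - R^2)`` for the single-score regression, with
F <= 10 flagged as a weak instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (ConfigError, DataError, DegenerateInstrumentError,
                         DomainError)

GWS_P_THRESHOLD = 5e-8
CLUMP_R2_THRESHOLD = 0.01
WEAK_F_THRESHOLD = 10.0


@dataclass
class GrsModel:
    """An instrument definition: ordered variant ids and their weights
    (the variant-exposure betas), with selection provenance."""
    variant_ids: list
    weights: np.ndarray
    effect_alleles: list | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variant_ids) != len(self.weights):
            raise DataError("variant_ids and weights length mismatch")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise DataError("duplicate variant ids in GRS model")
        if not np.all(np.isfinite(self.weights)):
            raise DataError("GRS weights must be finite")

    def to_tsv(self, path):
        ea = self.effect_alleles or ["."] * len(self.variant_ids)
        pd.DataFrame({"variant_id": self.variant_ids,
                      "effect_allele": ea,
                      "weight": self.weights}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path):
        df = pd.read_csv(path, sep="\t")
        return cls(variant_ids=df["variant_id"].tolist(),
                   weights=df["weight"].to_numpy(),
                   effect_alleles=df["effect_allele"].tolist())


@dataclass
class GrsResult:
    """Realized scores plus instrument-strength diagnostics."""
    scores: np.ndarray
    r2: float
    f_stat: float
    n: int
    weak_instrument: bool


def clump_variants(assocs: pd.DataFrame, ld: np.ndarray,
                   p_threshold: float = GWS_P_THRESHOLD,
                   r2_threshold: float = CLUMP_R2_THRESHOLD) -> list:
    """Greedy LD clumping by p-value.

    Drops variants with ``p >= p_threshold``, then repeatedly takes the
    most significant remaining variant as an index and removes everything
    with LD ``r^2 >= r2_threshold`` to it.  Ties on p are broken
    lexicographically by id so the result is order-invariant.

    Parameters
    ----------
    assocs : DataFrame with columns ``variant_id, p`` (row order matches
        ``ld`` rows/columns).
    ld : m-by-m matrix of pairwise r^2 (symmetric, unit diagonal).
    """
    ld = np.asarray(ld, dtype=float)
    m = len(assocs)
    if ld.shape != (m, m):
        raise DataError("ld matrix shape does not match association table")
    if not np.allclose(ld, ld.T, atol=1e-10):
        raise DataError("ld matrix is not symmetric")
    if np.any(ld < 0) or np.any(ld > 1 + 1e-12):
        raise DataError("ld entries must lie in [0, 1]")

    idx = np.arange(m)
    keep_sig = assocs["p"].to_numpy() < p_threshold
    candidates = [(assocs["p"].iat[i], str(assocs["variant_id"].iat[i]), i)
                  for i in idx[keep_sig]]
    candidates.sort()  # ascending p, ties lexicographic by id
    selected, removed = [], set()
    for _, vid, i in candidates:
        if i in removed:
            continue
        selected.append(vid)
        for _, _, j in candidates:
            if j != i and ld[i, j] >= r2_threshold:
                removed.add(j)
    return selected


def compute_grs(dosages: np.ndarray, model: GrsModel,
                missing: str = "mean_impute") -> np.ndarray:
    """Weighted allele score: ``score_i = sum_j w_j * dosage_ij``.

    Missing dosages (NaN) are mean-imputed per variant by default;
    ``missing="complete_case"`` returns NaN scores for affected rows.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != len(model.weights):
        raise DataError(
            f"dosage matrix has {dosages.shape[1] if dosages.ndim == 2 else '?'} "
            f"columns but model defines {len(model.weights)} variants")
    if np.isnan(dosages).any():
        if missing == "mean_impute":
            col_means = np.nanmean(dosages, axis=0)
            dosages = np.where(np.isnan(dosages), col_means, dosages)
        elif missing != "complete_case":
            raise ConfigError(f"unknown missing-dosage policy {missing!r}")
    return dosages @ model.weights


def variance_explained(exposure: np.ndarray, scores: np.ndarray) -> GrsResult:
    """Variance in the exposure explained by the score, with the GRS-level
    F statistic of the simple regression exposure ~ score."""
    exposure = np.asarray(exposure, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if exposure.shape != scores.shape:
        raise DataError("exposure and scores must have equal length")
    n = len(exposure)
    if n < 3:
        raise DataError("need at least 3 observations")
    if np.var(scores) == 0:
        raise DegenerateInstrumentError("score vector has zero variance")
    r = np.corrcoef(scores, exposure)[0, 1]
    r2 = min(float(r * r), 1.0)
    # within rounding of a perfect fit, report the infinite-F sentinel
    f = math.inf if 1.0 - r2 < 1e-12 else (n - 2) * r2 / (1 - r2)
    return GrsResult(scores=scores, r2=r2, f_stat=f, n=n,
                     weak_instrument=f <= WEAK_F_THRESHOLD)


def grs_correlation(score_sets: dict | list):
    """Pairwise Pearson correlations between >= 2 score vectors with
    two-sided p-values from the t transform.

    Returns ``(r, p)`` as labelled DataFrames.
    """
    if isinstance(score_sets, dict):
        names = list(score_sets)
        vecs = [np.asarray(score_sets[k], dtype=float) for k in names]
    else:
        vecs = [np.asarray(v, dtype=float) for v in score_sets]
        names = [f"score_{i}" for i in range(len(vecs))]
    if len(vecs) < 2:
        raise DataError("need at least two score sets")
    n = len(vecs[0])
    for v in vecs:
        if len(v) != n:
            raise DataError("score vectors must have equal length")
        if np.var(v) == 0:
            raise DegenerateInstrumentError("constant score vector: correlation undefined")
    k = len(vecs)
    r = np.eye(k)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = stats.pearsonr(vecs[i], vecs[j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=names, columns=names),
            pd.DataFrame(p, index=names, columns=names))


def restrict_grs(model: GrsModel, exclusion_ids) -> GrsModel:
    """Remove listed (potentially pleiotropic) variants from the model,
    recording them in provenance.  Errors if fewer than 2 remain."""
    excl = set(exclusion_ids)
    keep = [i for i, vid in enumerate(model.variant_ids) if vid not in excl]
    if len(keep) < 2:
        raise DegenerateInstrumentError(
            f"restricted GRS would retain {len(keep)} variant(s); need >= 2")
    prov = dict(model.provenance)
    prov["excluded_ids"] = sorted(excl & set(model.variant_ids))
    return GrsModel(
        variant_ids=[model.variant_ids[i] for i in keep],
        weights=model.weights[keep],
        effect_alleles=([model.effect_alleles[i] for i in keep]
                        if model.effect_alleles else None),
        provenance=prov)
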