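"""Deterministic lipid and covariate preprocessing.

Implements the measurement conventions used throughout the analysis:

* unit conversion between mmol/l and mg/dl for cholesterol
  (molar mass 386.65 g/mol, factor 38.67) and triglycerides (factor 88.57);
* Friedewald derivation of LDL cholesterol, ``LDL = TC - HDL - TG/5``
  (mg/dl), valid only while triglycerides are at or below a ceiling
  (default 155 mg/dl);
* multiplicative statin adjustment of measured LDL (default factor 1.43)
  to approximate the untreated lifetime exposure;
* systolic-blood-pressure correction for antihypertensive use
  (default +15 mm Hg);
* Du Bois body-surface-area formula;
* assembly of the covariate design frame (log transforms, ordinal and
  binary encodings, complete-case mask).

All computation is unrounded; :func:`presentation_round` exists solely for
printing increments the way clinical tables do (half-up to the nearest
integer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError, DomainError

#: mg/dl per mmol/l for cholesterol (molar mass 386.65 g/mol).
CHOLESTEROL_MGDL_PER_MMOL = 38.67
#: mg/dl per mmol/l for triglycerides.
TRIGLYCERIDE_MGDL_PER_MMOL = 88.57

_FACTORS = {
    "cholesterol": CHOLESTEROL_MGDL_PER_MMOL,
    "triglyceride": TRIGLYCERIDE_MGDL_PER_MMOL,
}

DEFAULT_TG_CEILING_MGDL = 155.0
DEFAULT_STATIN_FACTOR = 1.43
DEFAULT_SBP_INCREMENT = 15.0


def convert_units(value, analyte: str, direction: str):
    """Convert a lipid concentration between mmol/l and mg/dl.

    Parameters
    ----------
    value : float or array-like, >= 0
        Concentration to convert.
    analyte : {"cholesterol", "triglyceride"}
    direction : {"mmol_to_mgdl", "mgdl_to_mmol"}

    Returns
    -------
    float or ndarray
        Converted concentration, unrounded.
    """
    if analyte not in _FACTORS:
        raise ConfigError(f"unknown analyte {analyte!r}; expected one of {sorted(_FACTORS)}")
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError("concentration must be non-negative")
    factor = _FACTORS[analyte]
    if direction == "mmol_to_mgdl":
        out = arr * factor
    elif direction == "mgdl_to_mmol":
        out = arr / factor
    else:
        raise ConfigError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def presentation_round(value) -> int:
    """Round half-up to the nearest integer, for table display only.

    ``presentation_round(38.67) == 39``; internal computation never uses
    this helper.
    """
    arr = np.asarray(value, dtype=float)
    out = np.floor(arr + 0.5).astype(int)
    return int(out) if out.ndim == 0 else out


def friedewald_ldl(total_chol: float, hdl: float, triglycerides: float,
                   tg_ceiling: float = DEFAULT_TG_CEILING_MGDL) -> float:
    """Derive LDL cholesterol (mg/dl) by the Friedewald equation.

    Returns ``nan`` (missing) when triglycerides exceed the ceiling, or
    when the computed LDL is negative (an implausible value should not
    silently enter a regression).
    """
    if tg_ceiling <= 0:
        raise ConfigError("tg_ceiling must be positive")
    for name, v in (("total_chol", total_chol), ("hdl", hdl),
                    ("triglycerides", triglycerides)):
        if v < 0:
            raise DomainError(f"{name} must be non-negative")
    if triglycerides > tg_ceiling:
        return math.nan
    ldl = total_chol - hdl - triglycerides / 5.0
    if ldl < 0:
        return math.nan
    return ldl


def adjust_ldl_for_statin(ldl: float, on_statin: bool,
                          factor: float = DEFAULT_STATIN_FACTOR) -> float:
    """Scale measured LDL up by ``factor`` for statin users to estimate the
    untreated concentration; non-users are returned unchanged."""
    if factor <= 0:
        raise ConfigError("statin adjustment factor must be positive")
    if ldl < 0:
        raise DomainError("ldl must be non-negative")
    return ldl * factor if on_statin else ldl


def adjust_sbp(sbp: float, on_antihypertensive: bool,
               increment: float = DEFAULT_SBP_INCREMENT) -> float:
    """Add ``increment`` mm Hg to systolic blood pressure for participants
    on antihypertensive medication."""
    if sbp <= 0:
        raise DomainError("sbp must be positive")
    return sbp + increment if on_antihypertensive else sbp


def bsa_dubois(height_cm: float, weight_kg: float) -> float:
    """Du Bois & Du Bois body surface area (m^2)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be positive")
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


@dataclass
class LipidPanel:
    """One participant's lipid biochemistry in mg/dl.

    ``ldl_direct`` is ``nan`` when no direct assay is available, in which
    case :func:`resolve_ldl` falls back to the Friedewald derivation.
    """
    total_chol: float
    hdl: float
    triglycerides: float
    ldl_direct: float = math.nan
    on_statin: bool = False


def resolve_ldl(panel: LipidPanel,
                tg_ceiling: float = DEFAULT_TG_CEILING_MGDL,
                statin_factor: float = DEFAULT_STATIN_FACTOR,
                apply_statin_adjustment: bool = True):
    """Resolve a participant's LDL value with provenance.

    Preference order: direct assay, then Friedewald derivation, then
    missing.  Statin users' values are scaled by ``statin_factor`` unless
    ``apply_statin_adjustment`` is False.

    Returns
    -------
    (ldl, source) : tuple[float, str]
        ``source`` is one of ``{"direct", "friedewald", "missing"}``.
    """
    if not math.isnan(panel.ldl_direct):
        ldl, source = panel.ldl_direct, "direct"
    else:
        ldl = friedewald_ldl(panel.total_chol, panel.hdl,
                             panel.triglycerides, tg_ceiling)
        source = "missing" if math.isnan(ldl) else "friedewald"
    if source != "missing" and apply_statin_adjustment:
        ldl = adjust_ldl_for_statin(ldl, panel.on_statin, statin_factor)
    return ldl, source


# Deterministic covariate design column order (documented contract).
COVARIATE_COLUMNS = (
    "age", "sex", "log_bmi", "bsa", "sbp_adjusted", "log_met",
    "smoking", "log_hba1c", "cvd_present",
    "pc1", "pc2", "pc3", "pc4", "pc5",
)

_SMOKING_CODES = {"never": 0, "former": 1, "current": 2}
_SEX_CODES = {"male": 1, "female": 0}


def build_covariate_frame(raw: pd.DataFrame,
                          met_offset: float = 1.0,
                          sbp_increment: float = DEFAULT_SBP_INCREMENT):
    """Build the numeric covariate design frame from raw participant data.

    Expects columns ``age, sex, bmi, height, weight, sbp,
    on_antihypertensive, met_min_week, smoking, hba1c, cvd_present,
    pc1..pc5`` (``bsa`` is accepted directly or derived from height and
    weight).  Applies natural logs to BMI and HbA1c, ``log(MET + offset)``
    to physical activity, the antihypertensive SBP correction, and encodes
    sex/smoking/CVD numerically.

    Returns
    -------
    (frame, complete_mask) : tuple[pd.DataFrame, np.ndarray]
        ``frame`` has columns :data:`COVARIATE_COLUMNS` in that order;
        ``complete_mask`` marks rows with no missing covariate.
    """
    if len(raw) == 0:
        raise DataError("covariate table is empty")
    raw = raw.copy()

    def _col(name):
        if name not in raw.columns:
            raise DataError(f"missing required column {name!r}")
        col = pd.to_numeric(raw[name], errors="coerce") if name not in ("sex", "smoking") else raw[name]
        if col.isna().all():
            raise DataError(f"column {name!r} is entirely missing")
        return col

    out = pd.DataFrame(index=raw.index)
    out["age"] = _col("age")
    out["sex"] = _col("sex").map(_SEX_CODES) if raw["sex"].dtype == object else _col("sex")
    bmi = _col("bmi")
    if (bmi.dropna() <= 0).any():
        raise DomainError("bmi must be positive")
    out["log_bmi"] = np.log(bmi)
    if "bsa" in raw.columns and not raw["bsa"].isna().all():
        out["bsa"] = pd.to_numeric(raw["bsa"], errors="coerce")
    else:
        h, w = _col("height"), _col("weight")
        out["bsa"] = 0.007184 * h ** 0.725 * w ** 0.425
    sbp = _col("sbp")
    on_aht = _col("on_antihypertensive").astype(float)
    out["sbp_adjusted"] = sbp + sbp_increment * on_aht
    met = _col("met_min_week")
    if (met.dropna() < 0).any():
        raise DomainError("met_min_week must be non-negative")
    out["log_met"] = np.log(met + met_offset)
    smoking = raw["smoking"]
    out["smoking"] = smoking.map(_SMOKING_CODES) if smoking.dtype == object else pd.to_numeric(smoking, errors="coerce")
    hba1c = _col("hba1c")
    if (hba1c.dropna() <= 0).any():
        raise DomainError("hba1c must be positive")
    out["log_hba1c"] = np.log(hba1c)
    out["cvd_present"] = _col("cvd_present").astype(float)
    for k in range(1, 6):
        out[f"pc{k}"] = _col(f"pc{k}")

    out = out[list(COVARIATE_COLUMNS)]
    complete_mask = ~out.isna().any(axis=1).to_numpy()
    return out, complete_mask


def process_phenotypes(raw: pd.DataFrame,
                       tg_ceiling: float = DEFAULT_TG_CEILING_MGDL,
                       statin_factor: float = DEFAULT_STATIN_FACTOR,
                       sbp_increment: float = DEFAULT_SBP_INCREMENT,
                       apply_statin_adjustment: bool = True) -> pd.DataFrame:
    """Resolve lipids with provenance for a whole phenotype table.

    Input columns: ``total_chol, hdl, triglycerides`` and optionally
    ``ldl_direct, on_statin, sbp, on_antihypertensive`` (mg/dl, mm Hg).
    Output adds ``ldl`` with provenance columns ``ldl_source``
    (direct/friedewald/missing), ``ldl_statin_adjusted`` and
    ``sbp_adjusted`` flags.
    """
    out = raw.copy()
    ldl_vals, sources = [], []
    statin = out["on_statin"].astype(bool) if "on_statin" in out else pd.Series(False, index=out.index)
    ldl_direct = out["ldl_direct"] if "ldl_direct" in out else pd.Series(math.nan, index=out.index)
    for i in out.index:
        panel = LipidPanel(
            total_chol=float(out.at[i, "total_chol"]),
            hdl=float(out.at[i, "hdl"]),
            triglycerides=float(out.at[i, "triglycerides"]),
            ldl_direct=float(ldl_direct[i]) if not pd.isna(ldl_direct[i]) else math.nan,
            on_statin=bool(statin[i]),
        )
        ldl, src = resolve_ldl(panel, tg_ceiling, statin_factor, apply_statin_adjustment)
        ldl_vals.append(ldl)
        sources.append(src)
    out["ldl"] = ldl_vals
    out["ldl_source"] = sources
    out["ldl_statin_adjusted"] = statin.to_numpy() & (np.array(sources) != "missing") & apply_statin_adjustment
    if "sbp" in out.columns:
        on_aht = out.get("on_antihypertensive", pd.Series(False, index=out.index)).astype(bool)
        out["sbp"] = out["sbp"] + sbp_increment * on_aht.astype(float)
        out["sbp_adjusted"] = on_aht.to_numpy()
    return out
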