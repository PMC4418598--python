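"""Derived clinical phenotypes used as network traits.

Implements the insulin-resistance index HOMA-IR, the metabolic-syndrome
(MetS) classification based on the four IDF cardiometabolic risk factors,
and the two-occasion fasting-glycemia diabetes rule.  All functions accept
scalars or array-likes and propagate missing values (NaN) rather than
imputing them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["homa_ir", "mets_classify", "diabetes_classify", "MetSResult", "add_derived_traits"]

# IDF risk-factor thresholds (2005 definition)
TG_THRESHOLD = 1.7  # mmol/L, raised triglycerides (>=)
HDL_THRESHOLD = 1.29  # mmol/L, reduced HDL-cholesterol (strict <)
SBP_THRESHOLD = 130.0  # mmHg (>=)
DBP_THRESHOLD = 85.0  # mmHg (>=)
GLUCOSE_THRESHOLD = 5.6  # mmol/L, raised fasting glucose (>=)

DIABETES_GLYCEMIA = 7.0  # mmol/L, on at least two occasions


def homa_ir(insulin, glucose):
    """Homeostasis-model insulin-resistance index.

    Parameters
    ----------
    insulin : float or array-like
        Fasting insulinemia in uUI/mL (equivalently mUI/L).
    glucose : float or array-like
        Fasting blood glucose in mmol/L.

    Returns
    -------
    float or ndarray
        insulin * glucose / 22.5 (unitless).  NaN inputs propagate.

    Raises
    ------
    ValueError
        If any non-missing input is negative.
    """
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if np.any(ins[~np.isnan(ins)] < 0) or np.any(glu[~np.isnan(glu)] < 0):
        raise ValueError("insulin and glucose must be non-negative")
    out = ins * glu / 22.5
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MetSResult:
    """Outcome of the four-factor cardiometabolic classification."""

    factor_count: int
    mets: bool
    incomplete: bool  # a factor could not be evaluated (missing value, no flag)


def _factor(value, threshold, flag, strict_less=False):
    """Evaluate one risk factor.  Returns (met, evaluable)."""
    if flag:
        return True, True
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False, False
    if strict_less:
        return value < threshold, True
    return value >= threshold, True


def mets_classify(
    tg=None,
    hdl=None,
    sbp=None,
    dbp=None,
    glucose=None,
    *,
    lipid_tx: bool = False,
    htn_tx: bool = False,
    t2d_dx: bool = False,
) -> MetSResult:
    """Classify metabolic syndrome from the four IDF risk factors.

    A subject is in the MetS group with at least two of: raised
    triglycerides (>= 1.7 mmol/L) or lipid treatment; reduced
    HDL-cholesterol (< 1.29 mmol/L) or lipid treatment; raised blood
    pressure (systolic >= 130 or diastolic >= 85 mmHg) or hypertension
    treatment; raised fasting glucose (>= 5.6 mmol/L) or previously
    diagnosed type-2 diabetes.

    Missing values for a factor without its corresponding flag leave the
    factor unmet and set ``incomplete`` on the result.
    """
    tg_met, tg_ok = _factor(tg, TG_THRESHOLD, lipid_tx)
    hdl_met, hdl_ok = _factor(hdl, HDL_THRESHOLD, lipid_tx, strict_less=True)

    if htn_tx:
        bp_met, bp_ok = True, True
    else:
        sbp_met, sbp_ok = _factor(sbp, SBP_THRESHOLD, False)
        dbp_met, dbp_ok = _factor(dbp, DBP_THRESHOLD, False)
        bp_met = sbp_met or dbp_met
        # blood pressure is evaluable if either reading is present
        bp_ok = sbp_ok or dbp_ok

    glu_met, glu_ok = _factor(glucose, GLUCOSE_THRESHOLD, t2d_dx)

    count = int(tg_met) + int(hdl_met) + int(bp_met) + int(glu_met)
    incomplete = not (tg_ok and hdl_ok and bp_ok and glu_ok)
    return MetSResult(factor_count=count, mets=count >= 2, incomplete=incomplete)


def diabetes_classify(antidiabetic_tx: bool, fasting_glycemia) -> bool:
    """Diabetes flag: antidiabetic treatment, or fasting glycemia
    >= 7 mmol/L on at least two different occasions."""
    if antidiabetic_tx:
        return True
    vals = np.asarray(list(fasting_glycemia), dtype=float)
    if vals.size and np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("glycemia measurements must be non-negative")
    return int(np.sum(vals >= DIABETES_GLYCEMIA)) >= 2


def add_derived_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Append `homa_ir`, `mets` and `diabetes` columns to a trait table.

    Expects columns ``insulin`` (uUI/mL) and ``glucose`` (mmol/L); the MetS
    columns (``triglycerides``, ``hdl``, ``sbp``, ``dbp``) and treatment
    flags (``lipid_tx``, ``htn_tx``, ``t2d_dx``, ``antidiabetic_tx``) are
    used when present and treated as absent/False otherwise.
    """
    out = traits.copy()
    out["homa_ir"] = homa_ir(traits["insulin"].to_numpy(), traits["glucose"].to_numpy())

    def _get(row, col, default=np.nan):
        return row[col] if col in row.index and pd.notna(row[col]) else default

    mets_flags, diab_flags = [], []
    for _, row in traits.iterrows():
        res = mets_classify(
            tg=_get(row, "triglycerides"),
            hdl=_get(row, "hdl"),
            sbp=_get(row, "sbp"),
            dbp=_get(row, "dbp"),
            glucose=_get(row, "glucose"),
            lipid_tx=bool(_get(row, "lipid_tx", False)),
            htn_tx=bool(_get(row, "htn_tx", False)),
            t2d_dx=bool(_get(row, "t2d_dx", False)),
        )
        mets_flags.append(res.mets)
        glyc = [row["glucose"]] if "glucose" in row.index and pd.notna(row["glucose"]) else []
        diab_flags.append(diabetes_classify(bool(_get(row, "antidiabetic_tx", False)), glyc))
    out["mets"] = mets_flags
    out["diabetes"] = diab_flags
    return out
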