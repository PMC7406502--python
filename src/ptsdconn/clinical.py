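"""Treatment-outcome quantities derived from pre/post CAPS totals.

Two outcome measures coexist and serve different stages:

* the *residual change score* — the sign-flipped residual of regressing
  post-treatment CAPS on pre-treatment CAPS, i.e. improvement independent
  of initial severity (used as the continuous outcome in the subnetwork
  association analysis), and
* the binary *responder* label — at least a 50% reduction in CAPS total
  (used for the group splits and the outcome-prediction stage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Fraction of symptom reduction that defines a treatment responder.
RESPONDER_THRESHOLD = 0.5

CLINICAL_COLUMNS = [
    "subject_id",
    "group",
    "caps_pre",
    "caps_post",
    "age",
    "sex",
    "dass_depression",
    "dass_anxiety",
    "dass_stress",
    "ssri",
]


def residual_change_scores(
    caps_pre: np.ndarray,
    caps_post: np.ndarray,
    predict_post_from_pre: bool = True,
) -> np.ndarray:
    """Residualised change: improvement independent of initial severity.

    Fits a least-squares line predicting post from pre (the residualised
    gain convention) and returns ``-(observed - predicted)`` so that
    higher scores mean greater improvement.  In-sample the scores have
    exactly zero mean and zero correlation with the predictor.

    Set ``predict_post_from_pre=False`` for the transposed regression
    (pre on post, residuals sign-kept), retained for comparability.
    """
    pre = np.asarray(caps_pre, dtype=float)
    post = np.asarray(caps_post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("caps_pre and caps_post must be equal-length vectors")
    if pre.size < 3:
        raise InputError("need at least 3 patients for the change regression")
    if not (np.isfinite(pre).all() and np.isfinite(post).all()):
        raise InputError("CAPS vectors contain non-finite values")
    x, y = (pre, post) if predict_post_from_pre else (post, pre)
    if np.ptp(x) == 0:
        raise InputError("degenerate fit: predictor CAPS scores are constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return -resid if predict_post_from_pre else resid


def classify_response(caps_pre: float, caps_post: float) -> bool:
    """Responder iff symptom reduction is at least 50% (inclusive)."""
    if caps_pre <= 0:
        raise InputError("caps_pre must be positive to compute % improvement")
    return (caps_pre - caps_post) / caps_pre >= RESPONDER_THRESHOLD


def derive_outcomes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append ``residual_change`` and ``responder`` columns for patients.

    Controls (and patients missing either CAPS value) get NA in both
    derived columns; existing columns are never overwritten — derived
    columns are recomputed and replaced as a unit.
    """
    out = cohort.copy()
    is_patient = out["group"].eq("patient")
    have_both = is_patient & out["caps_pre"].notna() & out["caps_post"].notna()
    out["residual_change"] = np.nan
    out["responder"] = pd.array([pd.NA] * len(out), dtype="boolean")
    if have_both.sum() >= 3:
        pre = out.loc[have_both, "caps_pre"].to_numpy(dtype=float)
        post = out.loc[have_both, "caps_post"].to_numpy(dtype=float)
        out.loc[have_both, "residual_change"] = residual_change_scores(pre, post)
        out.loc[have_both, "responder"] = [
            classify_response(a, b) for a, b in zip(pre, post)
        ]
    elif have_both.any():
        logger.warning("fewer than 3 complete patients; outcome columns left NA")
    return out


def response_groups(cohort: pd.DataFrame) -> pd.Series:
    """Three-level group label: responder / nonresponder / control."""
    def label(row):
        if row["group"] == "control":
            return "control"
        if pd.isna(row.get("responder")):
            return pd.NA
        return "responder" if row["responder"] else "nonresponder"

    return cohort.apply(label, axis=1)


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Participant-characteristics table (counts, percentages, mean +/- SD).

    Binary columns are summarised as ``n (pct)`` with the percentage to
    one decimal; continuous columns as mean and SD.  Percentages are over
    patients only for patient-only fields (CAPS, DASS, SSRI).
    """
    patients = cohort[cohort["group"] == "patient"]
    rows = []
    n_pat = len(patients)
    for col in ("ssri",):
        if col in patients:
            n_yes = int(patients[col].fillna(False).astype(bool).sum())
            rows.append(
                {
                    "measure": col,
                    "n": n_yes,
                    "pct": round(100.0 * n_yes / n_pat, 1) if n_pat else np.nan,
                }
            )
    for col in ("age", "caps_pre", "caps_post", "dass_depression", "dass_anxiety", "dass_stress"):
        if col in patients:
            vals = patients[col].dropna()
            rows.append(
                {
                    "measure": col,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
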