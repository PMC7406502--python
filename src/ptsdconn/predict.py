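"""Leave-one-out cross-validated prediction of treatment response.

Quantifies whether the composite connectivity signature adds predictive
value for the binary responder label beyond demographic and clinical
measures.  The classifier is an L2-regularised logistic regression;
features are standardised with training-fold statistics only, so the
held-out subject never influences its own prediction.  Models are
compared with a paired permutation test on per-subject correctness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import InputError

logger = logging.getLogger(__name__)

#: Inverse regularisation strength of the logistic model (weak penalty).
LOGISTIC_C = 1.0


@dataclass
class PredictionResult:
    """Per-fold LOOCV predictions and aggregate confusion metrics."""

    predicted: np.ndarray  # bool per subject
    probability: np.ndarray  # P(responder) per subject
    true_labels: np.ndarray
    accuracy: float  # percentages, one decimal
    sensitivity: float
    specificity: float
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return len(self.true_labels)


def confusion_metrics(predicted, true) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as percentages to one decimal.

    Sensitivity is the true-positive rate on the responder (True) class;
    specificity the true-negative rate.  A rate whose class is absent
    from the true labels is NaN (not applicable).
    """
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(true, dtype=bool)
    if pred.shape != true.shape or pred.size == 0:
        raise InputError("prediction and truth must be equal-length, nonempty")
    acc = 100.0 * np.mean(pred == true)
    pos = true
    neg = ~true
    sens = 100.0 * np.mean(pred[pos]) if pos.any() else np.nan
    spec = 100.0 * np.mean(~pred[neg]) if neg.any() else np.nan
    r1 = lambda v: float(round(v, 1)) if np.isfinite(v) else float("nan")
    return r1(acc), r1(sens), r1(spec)


def _fit_predict_one(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, seed: int
) -> float:
    """Probability of the positive class for one held-out subject."""
    if len(np.unique(y_train)) < 2:
        # one-class fold: predict the (only) training class
        logger.warning("training fold has a single class; predicting it")
        return 1.0 if y_train[0] else 0.0
    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=LOGISTIC_C, solver="lbfgs",
                           max_iter=1000, random_state=seed),
    )
    model.fit(x_train, y_train.astype(int))
    return float(model.predict_proba(x_test)[0, 1])


def loocv_predict(
    features: pd.DataFrame | np.ndarray,
    labels,
    seed: int = 0,
) -> PredictionResult:
    """Leave-one-out cross-validated logistic prediction.

    One fold per subject; each model is trained on the remaining n-1
    subjects (standardisation refit per fold) and the held-out subject is
    classified at probability cutoff 0.5.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(x.shape[1])]
    y = np.asarray(labels, dtype=bool)
    n = x.shape[0]
    if n < 6:
        raise InputError("need at least 6 subjects for LOOCV")
    if y.all() or not y.any():
        raise InputError("both classes must be present")
    if not np.isfinite(x).all():
        raise InputError("features contain non-finite values")

    proba = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        proba[i] = _fit_predict_one(x[keep], y[keep], x[i : i + 1], seed)
    pred = proba >= 0.5
    acc, sens, spec = confusion_metrics(pred, y)
    return PredictionResult(
        predicted=pred,
        probability=proba,
        true_labels=y,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        feature_names=names,
        seed=seed,
    )


def compare_models(
    base: PredictionResult,
    augmented: PredictionResult,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Paired permutation p for the accuracy difference between models.

    Per-subject correctness indicators are randomly swapped between the
    two models (sign-flip test on the paired differences); two-sided p
    with the plus-one convention.  Identical correctness vectors give
    p = 1.
    """
    if not np.array_equal(base.true_labels, augmented.true_labels):
        raise InputError("models must be evaluated on the same subjects")
    cb = base.predicted == base.true_labels
    ca = augmented.predicted == augmented.true_labels
    diff = ca.astype(int) - cb.astype(int)
    if not np.any(diff):
        return 1.0
    obs = abs(diff.sum())
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, len(diff))) * 2 - 1
    null = np.abs((flips * diff).sum(axis=1))
    return float((1 + np.count_nonzero(null >= obs)) / (1 + n_perm))


BASE_FEATURES = [
    "age",
    "sex",
    "caps_pre",
    "dass_depression",
    "dass_anxiety",
    "dass_stress",
]


def feature_table(
    cohort: pd.DataFrame,
    composite: pd.Series | None = None,
    base_features: list[str] = BASE_FEATURES,
) -> pd.DataFrame:
    """Assemble the demographic/clinical feature matrix for patients.

    ``composite`` (per-subject composite connectivity, indexed like the
    cohort) is appended when given, forming the augmented feature set.
    Sex is coded 0/1.
    """
    pats = cohort[cohort["group"] == "patient"].copy()
    x = pats[base_features].copy()
    if x["sex"].dtype == object:
        x["sex"] = (pats["sex"].astype(str).str.lower().isin(["m", "male", "1"])).astype(float)
    if composite is not None:
        x["composite_z"] = np.asarray(composite, dtype=float)
    return x.astype(float)
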