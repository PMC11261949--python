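"""HRD ground-truth labeling, SVM training, calibrated prediction, metrics.

Training samples are labeled HRD when their genomic-instability scar score
reaches the tissue threshold (42 for breast, 63 for ovarian) or when BRCA1/2
is altered (pathogenic germline/somatic variant or promoter methylation);
otherwise HRP. The classifier is a linear-kernel SVM with L2 regularization
on the six standardized features. The regularization strength is chosen by
mean 10-fold cross-validated AUC; per-fold feature weights are retained (the
reported weight vector is their mean), the final model is refit on all
training data, and probabilities come from a Platt-style logistic
calibration fitted on out-of-fold decision values. Samples with calibrated
HRD probability >= 0.50 are called HRD.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES, FeatureVector
from .io import Assay

HRD_SCORE_THRESHOLDS: Mapping[str, float] = {"breast": 42.0, "ovarian": 63.0}
CALL_THRESHOLD = 0.50
DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class GroundTruthLabel:
    sample_id: str
    hrd_score: float | None
    brca_altered: bool
    tissue: str
    label: str  # "HRD" | "HRP"


def annotate_ground_truth(
    sample_id: str,
    hrd_score: float | None,
    brca_altered: bool | None,
    tissue: str,
) -> GroundTruthLabel:
    """Label a sample HRD/HRP from its scar score and BRCA1/2 status.

    HRD iff the scar score reaches the tissue threshold (inclusive) OR
    BRCA1/2 is altered. A missing score with no BRCA alteration is
    insufficient evidence and raises rather than defaulting to HRP.
    """
    if tissue not in HRD_SCORE_THRESHOLDS:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {sorted(HRD_SCORE_THRESHOLDS)}")
    if hrd_score is None and brca_altered is None:
        raise ValueError(f"{sample_id}: no HRD score and no BRCA status provided")
    brca = bool(brca_altered) if brca_altered is not None else False
    if hrd_score is None and not brca:
        raise ValueError(
            f"{sample_id}: HRD score missing and BRCA1/2 not altered - insufficient evidence"
        )
    label = "HRD" if brca or (hrd_score is not None and hrd_score >= HRD_SCORE_THRESHOLDS[tissue]) else "HRP"
    return GroundTruthLabel(
        sample_id=sample_id,
        hrd_score=hrd_score,
        brca_altered=brca,
        tissue=tissue,
        label=label,
    )


# ---------------------------------------------------------------------------
# standardization


@dataclass
class ScalerParams:
    mean: np.ndarray
    sd: np.ndarray


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Per-feature mean/SD; a zero-variance feature gets SD 1 with a warning."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples to fit the scaler")
    scaler = StandardScaler().fit(X)
    sd = np.sqrt(scaler.var_)
    if (sd == 0).any():
        warnings.warn("zero-variance feature(s); SD set to 1", stacklevel=2)
        sd = np.where(sd == 0, 1.0, sd)
    return ScalerParams(mean=np.asarray(scaler.mean_), sd=sd)


def standardize(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.mean) / params.sd


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    tissue: str
    assay: Assay
    feature_order: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    weights: np.ndarray  # refit-on-all-data decision weights
    bias: float
    calib_a: float
    calib_b: float
    cv_weights: np.ndarray  # folds x 6
    c_value: float
    c_grid: tuple[float, ...]
    cv_auc: float
    folds: int
    seed: int
    version: str = "1"

    @property
    def mean_cv_weights(self) -> np.ndarray:
        """The reported feature-weight vector: mean of the per-fold weights."""
        return self.cv_weights.mean(axis=0)

    def to_json(self) -> str:
        doc = {
            "format": "hrdkit-model",
            "version": self.version,
            "tissue": self.tissue,
            "assay": self.assay.value,
            "feature_order": list(self.feature_order),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "calib_a": self.calib_a,
            "calib_b": self.calib_b,
            "cv_weights": self.cv_weights.tolist(),
            "c_value": self.c_value,
            "c_grid": list(self.c_grid),
            "cv_auc": self.cv_auc,
            "folds": self.folds,
            "seed": self.seed,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        doc = json.loads(text)
        if doc.get("format") != "hrdkit-model":
            raise ValueError("not a serialized hrdkit model")
        return cls(
            tissue=doc["tissue"],
            assay=Assay(doc["assay"]),
            feature_order=tuple(doc["feature_order"]),
            scaler_mean=np.array(doc["scaler_mean"]),
            scaler_sd=np.array(doc["scaler_sd"]),
            weights=np.array(doc["weights"]),
            bias=float(doc["bias"]),
            calib_a=float(doc["calib_a"]),
            calib_b=float(doc["calib_b"]),
            cv_weights=np.array(doc["cv_weights"]),
            c_value=float(doc["c_value"]),
            c_grid=tuple(doc["c_grid"]),
            cv_auc=float(doc["cv_auc"]),
            folds=int(doc["folds"]),
            seed=int(doc["seed"]),
            version=str(doc.get("version", "1")),
        )


def _as_xy(
    features: Sequence[FeatureVector], labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    sample_ids = [f.sample_id for f in features]
    X = np.vstack([f.as_array() for f in features])
    y = np.array([1 if labels[s] == "HRD" else 0 for s in sample_ids])
    return X, y, sample_ids


def train(
    features: Sequence[FeatureVector],
    labels: Mapping[str, str],
    tissue: str = "breast",
    folds: int = 10,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
) -> TrainedModel:
    """Fit the linear SVM with stratified 10-fold CV model selection.

    For each regularization strength in ``c_grid`` the mean out-of-fold AUC
    is computed; at the best strength (ties -> smaller C) the per-fold
    weights are recorded, the final model is refit on all data, and a
    logistic calibration is fitted on the out-of-fold decision values.
    """
    X, y, _ = _as_xy(features, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both HRD and HRP samples")
    if len(y) < folds:
        raise ValueError(f"n={len(y)} samples < {folds} folds")
    if min(np.bincount(y)) < folds:
        raise ValueError("each class needs at least one sample per stratified fold")
    assay = features[0].assay

    scaler = fit_scaler(X)
    Xs = standardize(X, scaler)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))

    best_c, best_auc, best_oof = None, -np.inf, None
    for c in c_grid:
        oof = np.zeros(len(y))
        aucs = []
        for train_idx, test_idx in splits:
            clf = SVC(kernel="linear", C=c)
            clf.fit(Xs[train_idx], y[train_idx])
            d = clf.decision_function(Xs[test_idx])
            oof[test_idx] = d
            aucs.append(roc_auc_score(y[test_idx], d))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:
            best_c, best_auc, best_oof = c, mean_auc, oof

    cv_weights = np.zeros((folds, X.shape[1]))
    for k, (train_idx, _) in enumerate(splits):
        clf = SVC(kernel="linear", C=best_c)
        clf.fit(Xs[train_idx], y[train_idx])
        cv_weights[k] = clf.coef_[0]

    final = SVC(kernel="linear", C=best_c)
    final.fit(Xs, y)

    # Platt-style sigmoid on the out-of-fold decision values
    platt = LogisticRegression(C=1e10, solver="lbfgs", max_iter=10_000)
    platt.fit(best_oof.reshape(-1, 1), y)
    calib_a = float(platt.coef_[0, 0])
    calib_b = float(platt.intercept_[0])

    return TrainedModel(
        tissue=tissue,
        assay=assay,
        feature_order=FEATURE_NAMES,
        scaler_mean=scaler.mean,
        scaler_sd=scaler.sd,
        weights=final.coef_[0].copy(),
        bias=float(final.intercept_[0]),
        calib_a=calib_a,
        calib_b=calib_b,
        cv_weights=cv_weights,
        c_value=float(best_c),
        c_grid=tuple(float(c) for c in c_grid),
        cv_auc=best_auc,
        folds=folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# prediction


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    probability: float
    call: str  # "HRD" | "HRP"
    decision_value: float


def predict(model: TrainedModel, features: Sequence[FeatureVector]) -> list[PredictionResult]:
    """Calibrated HRD probabilities and calls (>= 0.50 is HRD, inclusive)."""
    if tuple(model.feature_order) != FEATURE_NAMES:
        missing = set(model.feature_order) ^ set(FEATURE_NAMES)
        raise ValueError(f"feature order mismatch: {sorted(missing)}")
    results = []
    for f in features:
        x = (f.as_array() - model.scaler_mean) / model.scaler_sd
        d = float(np.dot(model.weights, x) + model.bias)
        p = float(1.0 / (1.0 + np.exp(-(model.calib_a * d + model.calib_b))))
        results.append(
            PredictionResult(
                sample_id=f.sample_id,
                probability=p,
                call="HRD" if p >= CALL_THRESHOLD else "HRP",
                decision_value=d,
            )
        )
    return results


# ---------------------------------------------------------------------------
# evaluation


def evaluate(
    predictions: Sequence[PredictionResult], truth: Mapping[str, str]
) -> dict[str, float | None | dict[str, int]]:
    """AUC (rank statistic, ties half), sensitivity, precision, F1 and the
    confusion matrix against HRD/HRP truth labels. Undefined ratios are
    reported as None, never coerced to 0."""
    y_true = np.array([1 if truth[p.sample_id] == "HRD" else 0 for p in predictions])
    y_prob = np.array([p.probability for p in predictions])
    y_call = np.array([1 if p.call == "HRD" else 0 for p in predictions])

    tp = int(((y_call == 1) & (y_true == 1)).sum())
    fp = int(((y_call == 1) & (y_true == 0)).sum())
    fn = int(((y_call == 0) & (y_true == 1)).sum())
    tn = int(((y_call == 0) & (y_true == 0)).sum())

    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class truth: AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(y_true, y_prob))

    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if sensitivity is not None and precision is not None and (sensitivity + precision) > 0:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    else:
        f1 = None
    return {
        "auc": auc,
        "sensitivity": sensitivity,
        "precision": precision,
        "f1": f1,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }
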