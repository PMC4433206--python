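"""Risk modelling on reconstructed features.

The Oral Cancer Risk Index (OCRI) is the calibrated probability of the OSCC
class emitted by a radial-kernel SVM trained on normal-vs-OSCC feature
vectors. Training preprocessing is median centering and column scaling,
fitted on the training set and frozen. The misclassification cost C is
selected by leave-one-out cross-validation over the nine-value geometric
grid 2^-2 ... 2^6 (ties broken toward the smaller cost); the kernel width
sigma comes from the median-pairwise-squared-distance heuristic on the
training data. OSCC is the positive class throughout.

``benchmark_models`` compares six classifier families (SVM, random forest,
penalized logistic regression, one-hidden-layer neural network, k-nearest
neighbours, CART) under a shared 10-fold x 5-repeat resampling with
identical folds, ranking by median ROC AUC, then sensitivity, then
specificity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    GridSearchCV,
    LeaveOneOut,
    RepeatedStratifiedKFold,
    cross_val_score,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import DEFAULT_CONFIG, RunConfig
from .exceptions import ValidationError
from .io import FeatureMatrix

__all__ = [
    "Preprocessing",
    "RiskModel",
    "OCRIResult",
    "EvaluationReport",
    "fit_preprocessing",
    "rbf_sigma_heuristic",
    "tune_and_train_svm",
    "compute_ocri",
    "score_matrix",
    "stratify_cohort",
    "benchmark_models",
    "MODEL_NAMES",
]

POSITIVE_CLASS = "oscc"
NEGATIVE_CLASS = "normal"
MODEL_NAMES = ("svm", "rrf", "plr", "nnet", "knn", "cart")


@dataclasses.dataclass
class Preprocessing:
    """Frozen per-bin median centers and standard-deviation scales."""

    center: np.ndarray
    scale: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) / self.scale


@dataclasses.dataclass
class RiskModel:
    preprocessing: Preprocessing
    svc: CalibratedClassifierCV  # Platt-calibrated radial-kernel SVC
    cost: float
    sigma: float
    cost_grid: tuple[float, ...]
    loocv_accuracy: dict[float, float]
    seed: int
    classes: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class OCRIResult:
    case_id: str
    ocri: float
    above_threshold: bool


@dataclasses.dataclass
class EvaluationReport:
    """Per-model, per-resample ROC/sensitivity/specificity."""

    records: pd.DataFrame  # columns: model, resample, roc, sensitivity, specificity
    medians: pd.DataFrame  # indexed by model
    ranking: list[str]
    seed: int
    n_resamples: int
    fold_test_indices: list[np.ndarray]


def _require_two_classes(labels) -> np.ndarray:
    y = np.asarray([str(v) for v in labels])
    present = set(y)
    if not present <= {NEGATIVE_CLASS, POSITIVE_CLASS}:
        raise ValidationError(
            f"risk model training expects labels in "
            f"{{{NEGATIVE_CLASS!r}, {POSITIVE_CLASS!r}}}, got {sorted(present)}"
        )
    if len(present) < 2:
        raise ValidationError(f"training data has a single class: {sorted(present)}")
    return y


def fit_preprocessing(
    train: FeatureMatrix, config: RunConfig = DEFAULT_CONFIG
) -> Preprocessing:
    """Per-bin median center and standard-deviation scale (floored)."""
    if len(train) < 2:
        raise ValidationError("need at least 2 training cases")
    _require_two_classes(train.labels)
    center = np.median(train.values, axis=0)
    scale = np.maximum(np.std(train.values, axis=0, ddof=1), config.scale_floor)
    return Preprocessing(center=center, scale=scale)


def rbf_sigma_heuristic(x: np.ndarray) -> float:
    """sigma = 1 / median(squared pairwise distances); kernel
    exp(-sigma * ||x - y||^2), i.e. scikit-learn's gamma."""
    d2 = pdist(np.asarray(x, dtype=float), "sqeuclidean")
    med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def tune_and_train_svm(
    train: FeatureMatrix,
    seed: int = 0,
    config: RunConfig = DEFAULT_CONFIG,
) -> RiskModel:
    """LOOCV cost selection on the nine-value grid, then a calibrated fit."""
    if len(train) < 10:
        raise ValidationError(
            f"need >= 10 training cases for leave-one-out tuning, got {len(train)}"
        )
    y = _require_two_classes(train.labels)
    prep = fit_preprocessing(train, config=config)
    x = prep.transform(train.values)
    sigma = rbf_sigma_heuristic(x)

    accuracies: dict[float, float] = {}
    for cost in config.cost_grid:
        scores = cross_val_score(
            SVC(C=cost, kernel="rbf", gamma=sigma), x, y, cv=LeaveOneOut()
        )
        accuracies[cost] = float(scores.mean())
    best = max(accuracies, key=lambda c: (accuracies[c], -c))
    # Platt-type sigmoid calibration fitted on internal training folds
    svc = CalibratedClassifierCV(
        SVC(C=best, kernel="rbf", gamma=sigma),
        method="sigmoid",
        cv=5,
        ensemble=False,
    )
    svc.fit(x, y)
    return RiskModel(
        preprocessing=prep,
        svc=svc,
        cost=float(best),
        sigma=float(sigma),
        cost_grid=tuple(config.cost_grid),
        loocv_accuracy=accuracies,
        seed=int(seed),
        classes=tuple(svc.classes_),
    )


def compute_ocri(model: RiskModel, case_features) -> OCRIResult:
    """OCRI of one case: calibrated P(OSCC) after frozen preprocessing."""
    bins = np.asarray(case_features.bins, dtype=float)
    if bins.shape != (16,):
        raise ValidationError(f"feature vector must have 16 bins, got {bins.shape}")
    x = model.preprocessing.transform(bins[None, :])
    idx = list(model.svc.classes_).index(POSITIVE_CLASS)
    p = float(model.svc.predict_proba(x)[0, idx])
    return OCRIResult(
        case_id=case_features.case_id, ocri=p, above_threshold=p > 0.5
    )


def score_matrix(model: RiskModel, matrix: FeatureMatrix) -> np.ndarray:
    """OCRI for every row of a feature matrix."""
    x = model.preprocessing.transform(matrix.values)
    idx = list(model.svc.classes_).index(POSITIVE_CLASS)
    return model.svc.predict_proba(x)[:, idx]


def stratify_cohort(model: RiskModel, matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-case OCRI, sorted descending; empty input gives an empty table."""
    if len(matrix) == 0:
        return pd.DataFrame(
            columns=["case_id", "label", "ocri", "above_threshold"]
        )
    ocri = score_matrix(model, matrix)
    table = pd.DataFrame(
        {
            "case_id": matrix.case_ids,
            "label": matrix.labels,
            "ocri": ocri,
            "above_threshold": ocri > 0.5,
        }
    )
    return table.sort_values("ocri", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _model_factories(seed: int) -> dict:
    """The six benchmarked families: defaults with light internal grids."""
    seed = int(seed) % (2**31)
    return {
        "svm": lambda: GridSearchCV(
            CalibratedClassifierCV(
                SVC(kernel="rbf", gamma="scale"),
                method="sigmoid",
                cv=3,
                ensemble=False,
            ),
            {"estimator__C": [0.25, 1.0, 4.0, 16.0, 64.0]},
            cv=3,
        ),
        "rrf": lambda: RandomForestClassifier(n_estimators=200, random_state=seed),
        "plr": lambda: GridSearchCV(
            LogisticRegression(max_iter=5000),  # L2 (ridge) path over C
            {"C": [0.01, 0.1, 1.0, 10.0]},
            cv=3,
        ),
        "nnet": lambda: MLPClassifier(
            hidden_layer_sizes=(8,),
            alpha=1e-3,
            max_iter=2000,
            random_state=seed,
        ),
        "knn": lambda: GridSearchCV(
            KNeighborsClassifier(), {"n_neighbors": [3, 5, 7, 9]}, cv=3
        ),
        "cart": lambda: GridSearchCV(
            DecisionTreeClassifier(random_state=seed),
            {"ccp_alpha": [0.0, 0.005, 0.01, 0.02]},
            cv=3,
        ),
    }


def benchmark_models(
    features: FeatureMatrix,
    seed: int = 0,
    models: tuple[str, ...] = MODEL_NAMES,
    config: RunConfig = DEFAULT_CONFIG,
) -> EvaluationReport:
    """10-fold x 5-repeat resampling with identical folds for every model.

    Per resample, preprocessing is refitted on the training folds only.
    Sensitivity and specificity use the 0.5 probability cutoff with OSCC
    positive. Models are ranked by median ROC AUC, then sensitivity, then
    specificity.
    """
    if len(features) < 40:
        raise ValidationError(f"need >= 40 cases to benchmark, got {len(features)}")
    y = _require_two_classes(features.labels)
    for cls in (NEGATIVE_CLASS, POSITIVE_CLASS):
        if int((y == cls).sum()) < 10:
            raise ValidationError(f"class {cls!r} has fewer than 10 cases")
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ValidationError(f"unknown model names: {sorted(unknown)}")

    x_raw = features.values
    cv = RepeatedStratifiedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.cv_repeats,
        random_state=int(seed) % (2**31),
    )
    folds = list(cv.split(x_raw, y))
    factories = _model_factories(seed)

    rows = []
    for resample, (train_idx, test_idx) in enumerate(folds):
        sub = FeatureMatrix(
            case_ids=[features.case_ids[i] for i in train_idx],
            labels=[features.labels[i] for i in train_idx],
            values=x_raw[train_idx],
        )
        prep = fit_preprocessing(sub, config=config)
        x_train, x_test = prep.transform(x_raw[train_idx]), prep.transform(
            x_raw[test_idx]
        )
        y_train, y_test = y[train_idx], y[test_idx]
        for name in models:
            clf = factories[name]()
            clf.fit(x_train, y_train)
            idx = list(clf.classes_).index(POSITIVE_CLASS)
            prob = clf.predict_proba(x_test)[:, idx]
            is_pos = y_test == POSITIVE_CLASS
            pred_pos = prob > 0.5
            rows.append(
                {
                    "model": name,
                    "resample": resample,
                    "roc": float(roc_auc_score(is_pos, prob)),
                    "sensitivity": float(pred_pos[is_pos].mean()),
                    "specificity": float((~pred_pos[~is_pos]).mean()),
                }
            )
    records = pd.DataFrame(rows)
    medians = (
        records.groupby("model")[["roc", "sensitivity", "specificity"]]
        .median()
        .loc[list(models)]
    )
    ranking = list(
        medians.sort_values(
            ["roc", "sensitivity", "specificity"], ascending=False
        ).index
    )
    return EvaluationReport(
        records=records,
        medians=medians,
        ranking=ranking,
        seed=int(seed),
        n_resamples=len(folds),
        fold_test_indices=[test for _, test in folds],
    )
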