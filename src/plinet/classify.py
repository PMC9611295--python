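"""Cross-validated condition classification from PLI features.

One sample = one recording; the default feature vector concatenates the
window-averaged PLI of every edge in every band (60·59/2 × 4 = 7080
values for the four rhythms).  Models: RBF SVM (C = 1), random forest
(500 trees), k-nearest-neighbors (k = 5), each inside a pipeline whose
standardization is fitted on the training folds only, evaluated with
stratified 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODELS = ("svm", "rf", "knn")


@dataclass(frozen=True)
class ClassificationReport:
    model: str
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    sd_accuracy: float
    seed: int
    feature_description: str = ""


def _make_model(model: str, seed: int):
    if model == "svm":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if model == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed)
    if model == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def crossval_classify(
    X: np.ndarray,
    y: np.ndarray,
    model: str = "svm",
    folds: int = 10,
    seed: int = 0,
    feature_description: str = "",
) -> ClassificationReport:
    """Stratified k-fold accuracy of one model; deterministic given seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"{folds}-fold CV needs at least {folds} samples per class "
            f"(smallest class has {counts.min()})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pipe = make_pipeline(StandardScaler(), _make_model(model, seed))
    accs = cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
    return ClassificationReport(
        model=model,
        fold_accuracies=tuple(float(a) for a in accs),
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)),
        seed=seed,
        feature_description=feature_description,
    )


def feature_matrix_from_mean_connectivity(
    mean_conn_per_recording: list[dict[str, np.ndarray]],
    bands: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Rows = recordings, columns = upper-triangle PLI of each band."""
    if not mean_conn_per_recording:
        raise ValueError("no recordings")
    first = mean_conn_per_recording[0]
    bands = tuple(first) if bands is None else bands
    n_ch = first[bands[0]].shape[0]
    iu, ju = np.triu_indices(n_ch, k=1)
    rows = [
        np.concatenate([mc[b][iu, ju] for b in bands])
        for mc in mean_conn_per_recording
    ]
    return np.vstack(rows)
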