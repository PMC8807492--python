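"""Stroma-rich / stroma-poor pixel classification from texture maps.

Pixels are labeled rich (proportion > 50%) or poor (< 50%); exactly-50%
pixels are excluded.  A fraction of all pixels is sampled, split 50/50 into
train and test, the train half is balanced by undersampling the majority
class, and an SVM with standardized features is trained with stratified
20-fold cross-validation.  Evaluation reports the confusion matrix with
"rich" as the positive class and renders predicted / evaluation maps.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .types import FEATURE_NAMES, StromalProportionMap, TextureMapStack

POOR, RICH = 0, 1
EXCLUDED = -1
DEFAULT_THRESHOLD = 50.0
COORD_AXES = ("z", "y", "x")


def label_pixels(
    prop: StromalProportionMap, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Class raster: 1 = rich (> threshold), 0 = poor (< threshold),
    -1 = excluded (invalid pixel or exactly at the threshold)."""
    if not 0 < threshold < 100:
        raise ValueError("threshold must lie in (0, 100)")
    out = np.full(prop.shape, EXCLUDED, dtype=np.int8)
    out[prop.mask & (prop.proportion > threshold)] = RICH
    out[prop.mask & (prop.proportion < threshold)] = POOR
    return out


def build_feature_table(
    stack: TextureMapStack,
    prop: StromalProportionMap,
    threshold: float = DEFAULT_THRESHOLD,
    tumor_id: int = 0,
    with_si: bool = False,
) -> pd.DataFrame:
    """Flat table of valid pixels x (features, class label, tumor id, coords).

    Default inputs are the 13 texture features; ``with_si`` adds the signal
    intensity column.  Rows with any non-finite feature are dropped.
    """
    if stack.shape != prop.shape:
        raise ValueError("misaligned grids")
    classes = label_pixels(prop, threshold)
    valid = stack.mask & (classes != EXCLUDED)
    n_at_threshold = int((prop.mask & stack.mask).sum() - valid.sum())
    feature_cols = list(FEATURE_NAMES)
    if with_si:
        if "si" not in stack.maps:
            raise ValueError("stack carries no 'si' map")
        feature_cols = ["si"] + feature_cols
    coords = np.nonzero(valid)
    data = {name: stack[name][valid] for name in feature_cols}
    table = pd.DataFrame(data)
    table["label"] = classes[valid].astype(np.int64)
    table["tumor_id"] = tumor_id
    for ax_name, ax_idx in zip(COORD_AXES[-len(stack.shape):], coords):
        table[ax_name] = ax_idx
    finite = np.isfinite(table[feature_cols].to_numpy()).all(axis=1)
    table = table.loc[finite].reset_index(drop=True)
    table.attrs["feature_cols"] = feature_cols
    table.attrs["n_excluded_at_threshold"] = n_at_threshold
    return table


def sample_and_split(
    table: pd.DataFrame,
    sample_frac: float = 0.30,
    train_frac: float = 0.50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample pixels across tumors, split into disjoint train/test halves,
    and balance the train half by undersampling the majority class.

    The test half is left at its natural class balance.
    """
    if not 0 < sample_frac <= 1 or not 0 < train_frac < 1:
        raise ValueError("fractions out of range")
    labels = table["label"].to_numpy()
    if not ((labels == RICH).any() and (labels == POOR).any()):
        raise ValueError(
            "both classes must be present "
            f"(rich={int((labels == RICH).sum())}, poor={int((labels == POOR).sum())})"
        )
    rng = np.random.default_rng(seed)
    n = len(table)
    n_sample = int(round(n * sample_frac))
    picked = rng.choice(n, size=n_sample, replace=False)
    rng.shuffle(picked)
    n_train = int(round(n_sample * train_frac))
    train = table.iloc[picked[:n_train]]
    test = table.iloc[picked[n_train:]]
    for part, name in ((train, "train"), (test, "test")):
        counts = part["label"].value_counts()
        if len(counts) < 2:
            raise ValueError(f"a class is absent from the {name} split; "
                             f"counts: {counts.to_dict()}")
    # Balance training classes by random undersampling.
    by_class = [np.flatnonzero(train["label"].to_numpy() == c) for c in (POOR, RICH)]
    n_min = min(len(ix) for ix in by_class)
    keep = np.concatenate(
        [rng.choice(ix, size=n_min, replace=False) for ix in by_class]
    )
    keep.sort()
    train = train.iloc[keep]
    train = train.copy()
    test = test.copy()
    train.attrs.update(table.attrs)
    test.attrs.update(table.attrs)
    return train.reset_index(drop=True), test.reset_index(drop=True)


@dataclass
class ClassificationResult:
    model: Pipeline | None
    feature_cols: list[str]
    cv_accuracy: float = np.nan
    seed: int = 0
    confusion: dict[str, int] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)


def _feature_matrix(table: pd.DataFrame, feature_cols: list[str]) -> np.ndarray:
    return table[feature_cols].to_numpy(dtype=np.float64)


def train_svm(
    train: pd.DataFrame,
    folds: int = 20,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
) -> ClassificationResult:
    """Fit a standardized SVM and report stratified k-fold CV accuracy.

    Zero-variance features are dropped with a warning.  The final model is
    refit on the full training set.
    """
    feature_cols = list(train.attrs.get("feature_cols", FEATURE_NAMES))
    X = _feature_matrix(train, feature_cols)
    y = train["label"].to_numpy()
    if len(train) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} rows for {folds}-fold CV")
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(feature_cols, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
        feature_cols = [c for c, k in zip(feature_cols, keep) if k]
        X = X[:, keep]
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=kernel, C=C, gamma="scale", random_state=seed)),
        ]
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(model, X, y, cv=cv, n_jobs=1)
    model.fit(X, y)
    return ClassificationResult(
        model=model,
        feature_cols=feature_cols,
        cv_accuracy=float(scores.mean()) * 100.0,
        seed=seed,
    )


def confusion_rates(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy / TPR / TNR / FPR / FNR in percent; NaN where undefined.

    FNR and FPR are computed as complements of TPR and TNR (identical in
    exact arithmetic), so ``tpr + fnr == 100`` and ``tnr + fpr == 100`` hold
    exactly in floating point as well.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be nonnegative")
    pos, neg = tp + fn, tn + fp
    total = pos + neg

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    tpr = pct(tp, pos)
    tnr = pct(tn, neg)
    return {
        "accuracy": pct(tp + tn, total),
        "tpr": tpr,
        "tnr": tnr,
        "fpr": 100.0 - tnr if neg else float("nan"),
        "fnr": 100.0 - tpr if pos else float("nan"),
    }


def evaluate(result: ClassificationResult, test: pd.DataFrame) -> ClassificationResult:
    """Confusion counts and rates on held-out pixels (rich = positive)."""
    X = _feature_matrix(test, result.feature_cols)
    y = test["label"].to_numpy()
    pred = result.model.predict(X)
    tp = int(((y == RICH) & (pred == RICH)).sum())
    fn = int(((y == RICH) & (pred == POOR)).sum())
    tn = int(((y == POOR) & (pred == POOR)).sum())
    fp = int(((y == POOR) & (pred == RICH)).sum())
    out = ClassificationResult(
        model=result.model,
        feature_cols=result.feature_cols,
        cv_accuracy=result.cv_accuracy,
        seed=result.seed,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        rates=confusion_rates(tp, fn, tn, fp),
    )
    return out


def predict_map(
    result: ClassificationResult,
    stack: TextureMapStack,
    prop: StromalProportionMap,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Classify every valid pixel of one specimen.

    Returns the predicted class raster (1 rich / 0 poor / -1 invalid), the
    evaluation raster (1 correct / 0 incorrect / -1 invalid) against the
    histology-derived classes, and the per-specimen rates.
    """
    for col in result.feature_cols:
        if col not in stack.maps:
            raise ValueError(f"stack is missing feature {col!r} used by the model")
    classes = label_pixels(prop, threshold)
    valid = stack.mask & (classes != EXCLUDED)
    X = np.column_stack([stack[c][valid] for c in result.feature_cols])
    finite = np.isfinite(X).all(axis=1)
    predicted = np.full(stack.shape, EXCLUDED, dtype=np.int8)
    evaluation = np.full(stack.shape, EXCLUDED, dtype=np.int8)
    coords = tuple(ix[finite] for ix in np.nonzero(valid))
    pred = result.model.predict(X[finite])
    predicted[coords] = pred.astype(np.int8)
    truth = classes[coords]
    evaluation[coords] = (pred == truth).astype(np.int8)
    tp = int(((truth == RICH) & (pred == RICH)).sum())
    fn = int(((truth == RICH) & (pred == POOR)).sum())
    tn = int(((truth == POOR) & (pred == POOR)).sum())
    fp = int(((truth == POOR) & (pred == RICH)).sum())
    return predicted, evaluation, confusion_rates(tp, fn, tn, fp)
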