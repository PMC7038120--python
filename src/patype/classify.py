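"""Random-forest activity classification and evaluation.

Builds general (all five sensor positions, 425 accelerometer columns) and
individual (85 columns) design matrices, optionally appending the two GPS
features once; trains random forests; and evaluates them with
leave-one-subject-out (L1SO) cross-validation — the realistic protocol in
which a subject's own data never inform the model that classifies them —
or with segment-level stratified k-fold cross-validation, which leaks
within-subject structure and is included precisely to demonstrate its
optimism.

Metrics: per class (one-vs-rest) precision = TP / (TP + FP) over the
predicted row, recall = TP / (TP + FN) over the true column, and
F1 = 2 * precision * recall / (beta^2 * precision + recall) with beta = 1;
overall accuracy is the confusion-matrix trace over its total.  Reported
metrics are percentages rounded half-up to integers; full precision is
retained internally.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .core import GROUPED_CLASSES, POSITIONS
from .features import FEATURE_NAMES, GPS_FEATURE_NAMES

log = logging.getLogger(__name__)

SCENARIO_TRAIN_PROTOCOLS = {
    "S1_semi_structured": ("semi_structured",),
    "S2_combined": ("semi_structured", "real_life"),
}


@dataclass
class ModelSpec:
    """What to train: scope (general or one position), feature set,
    training scenario, window size and forest hyper-parameters."""

    scope: str = "general"  # 'general' or a sensor position
    feature_set: str = "acc"  # 'acc' | 'acc_gps'
    scenario: str = "S2_combined"
    window_s: float = 10.0
    n_trees: int = 500
    mtry: str | int = "sqrt"
    seed: int = 0
    gps_missing_policy: str = "exclude"  # 'exclude' | 'zero'

    def __post_init__(self) -> None:
        if self.scope != "general" and self.scope not in POSITIONS:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.feature_set not in ("acc", "acc_gps"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.scenario not in SCENARIO_TRAIN_PROTOCOLS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class ConfusionMatrix:
    """counts[predicted, true] over a fixed class order."""

    classes: tuple
    counts: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=GROUPED_CLASSES) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for yt, yp in zip(y_true, y_pred):
            counts[index[yp], index[yt]] += 1
        return cls(classes=tuple(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class EvaluationReport:
    """Pooled confusion matrix plus per-class and overall metrics (%)."""

    confusion: ConfusionMatrix
    accuracy: float  # %
    per_class: pd.DataFrame  # index class, columns recall/precision/f1 (%)
    per_subject: dict = field(default_factory=dict)  # subject -> accuracy %
    method: str = ""

    def rounded(self) -> pd.DataFrame:
        """Display metrics: integer percentages, half-up."""
        return self.per_class.map(round_half_up)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accuracy_pct": self.accuracy,
            "per_class_pct": {c: {k: float(v) for k, v in row.items()}
                              for c, row in self.per_class.iterrows()},
            "per_subject_accuracy_pct": self.per_subject,
            "confusion_counts_pred_by_true": self.confusion.counts.tolist(),
            "classes": list(self.confusion.classes),
        }


def compute_metrics(cm: ConfusionMatrix, beta: float = 1.0, method: str = "") -> EvaluationReport:
    """Per-class recall/precision/F-beta and overall accuracy from counts."""
    counts = np.asarray(cm.counts, float)
    if (counts < 0).any():
        raise ValueError("confusion counts must be non-negative")
    diag = np.diag(counts)
    row = counts.sum(axis=1)  # predicted totals -> precision denominator
    col = counts.sum(axis=0)  # true totals -> recall denominator
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        recall = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        denom = beta**2 * precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    per_class = pd.DataFrame(
        {"recall": recall * 100, "precision": precision * 100, "f1": f1 * 100},
        index=list(cm.classes),
    )
    accuracy = 100.0 * diag.sum() / counts.sum() if counts.sum() else 0.0
    return EvaluationReport(confusion=cm, accuracy=float(accuracy), per_class=per_class, method=method)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def feature_columns(spec: ModelSpec) -> list:
    positions = POSITIONS if spec.scope == "general" else (spec.scope,)
    cols = [f"{p}__{name}" for p in positions for name in FEATURE_NAMES]
    if spec.feature_set == "acc_gps":
        cols += list(GPS_FEATURE_NAMES)
    return cols


def build_design_matrix(features: pd.DataFrame, spec: ModelSpec):
    """Select the spec's columns from the wide feature table.

    `features` has one row per (subject, window), columns
    '<position>__<feature>' for all five positions, the two GPS columns,
    and metadata (subject, protocol, environment, t_start, t_end, label).
    Returns (X, y, subject_ids, meta) with GPS-missing rows handled per the
    spec's policy.
    """
    cols = feature_columns(spec)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks required columns, e.g. {missing[:3]}")
    df = features
    if spec.feature_set == "acc_gps":
        has_gps = df[list(GPS_FEATURE_NAMES)].notna().all(axis=1)
        if spec.gps_missing_policy == "exclude":
            dropped = int((~has_gps).sum())
            if dropped:
                log.info("dropping %d GPS-missing rows for acc_gps model", dropped)
            df = df[has_gps]
        elif spec.gps_missing_policy == "zero":
            df = df.copy()
            df[list(GPS_FEATURE_NAMES)] = df[list(GPS_FEATURE_NAMES)].fillna(0.0)
        else:
            raise ValueError(f"unknown gps_missing_policy {spec.gps_missing_policy!r}")
    X = df[cols]
    y = df["label"].to_numpy()
    subjects = df["subject"].to_numpy()
    meta = df[[c for c in ("subject", "protocol", "environment", "t_start", "t_end", "label") if c in df.columns]]
    return X, y, subjects, meta


def train_rf(X, y, n_trees: int = 500, mtry="sqrt", seed: int = 0) -> RandomForestClassifier:
    """Fit a random forest; deterministic given the seed."""
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )
    model.fit(X, y)
    return model


def feature_importance_report(model: RandomForestClassifier, feature_names, top_n: int = 10) -> list:
    """Feature names ranked by impurity importance, descending."""
    order = np.argsort(-model.feature_importances_, kind="stable")[:top_n]
    return [feature_names[i] for i in order]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _scenario_train_mask(features: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    return features["protocol"].isin(SCENARIO_TRAIN_PROTOCOLS[spec.scenario]).to_numpy()


def loso_cv(features: pd.DataFrame, spec: ModelSpec, test_on: str = "training_protocol") -> EvaluationReport:
    """Leave-one-subject-out evaluation.

    For each subject: train on every *other* subject's scenario-training
    rows; test on the held-out subject's rows filtered to `test_on`
    ('training_protocol' = the scenario's own protocols, or 'real_life').
    No held-out-subject data of any protocol ever enters training.
    """
    X, y, subjects, meta = build_design_matrix(features, spec)
    train_mask = meta["protocol"].isin(SCENARIO_TRAIN_PROTOCOLS[spec.scenario]).to_numpy()
    if test_on == "training_protocol":
        test_mask = train_mask.copy()
    elif test_on == "real_life":
        test_mask = (meta["protocol"] == "real_life").to_numpy()
    else:
        raise ValueError(f"unknown test_on {test_on!r}")
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("L1SO needs at least 2 subjects")
    y_true_all, y_pred_all = [], []
    per_subject = {}
    for held in uniq:
        tr = train_mask & (subjects != held)
        te = test_mask & (subjects == held)
        if not te.any():
            log.warning("subject %s has no test rows — skipped", held)
            continue
        model = train_rf(X[tr], y[tr], spec.n_trees, spec.mtry, spec.seed)
        pred = model.predict(X[te])
        y_true_all.append(y[te])
        y_pred_all.append(pred)
        per_subject[str(held)] = float(100.0 * (pred == y[te]).mean())
    cm = ConfusionMatrix.from_predictions(np.concatenate(y_true_all), np.concatenate(y_pred_all))
    report = compute_metrics(cm, method=f"loso/{spec.scenario}/{test_on}/{spec.scope}/{spec.feature_set}")
    report.per_subject = per_subject
    return report


def kfold_cv(features: pd.DataFrame, spec: ModelSpec, k: int = 10, seed: int = 0) -> EvaluationReport:
    """Segment-level stratified k-fold CV, ignoring subject identity.

    Folds mix each subject's segments between train and test — exactly the
    within-subject leakage that inflates scores relative to L1SO.
    """
    X, y, subjects, meta = build_design_matrix(features, spec)
    mask = meta["protocol"].isin(SCENARIO_TRAIN_PROTOCOLS[spec.scenario]).to_numpy()
    Xs, ys = X[mask], y[mask]
    if k > len(ys):
        raise ValueError("k exceeds number of segments")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true_all, y_pred_all = [], []
    for tr, te in skf.split(Xs, ys):
        model = train_rf(Xs.iloc[tr], ys[tr], spec.n_trees, spec.mtry, spec.seed)
        y_true_all.append(ys[te])
        y_pred_all.append(model.predict(Xs.iloc[te]))
    cm = ConfusionMatrix.from_predictions(np.concatenate(y_true_all), np.concatenate(y_pred_all))
    report = compute_metrics(cm, method=f"kfold{k}/{spec.scenario}/{spec.scope}/{spec.feature_set}")
    return report


def segment_size_sensitivity(
    participants,
    spec: ModelSpec,
    sizes=(2, 5, 10, 20, 30, 60),
    overlap: float = 0.5,
    test_on: str = "training_protocol",
) -> pd.DataFrame:
    """L1SO overall accuracy of the spec's model at each segment size.

    Re-segments and re-extracts features from the raw streams per size.
    Returns a DataFrame indexed by window size with an accuracy_pct column.
    """
    from .pipeline import build_feature_table

    rows = []
    for size in sizes:
        feats = build_feature_table(participants, window_s=float(size), overlap=overlap)
        report = loso_cv(feats, replace(spec, window_s=float(size)), test_on=test_on)
        rows.append({"window_s": size, "accuracy_pct": report.accuracy})
    return pd.DataFrame(rows).set_index("window_s")
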