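"""Dataset splitting, classifier training, cross-validation and metrics.

Six classifier families (SVM, LR, RF, ET, KNN, MLP) are trained on a
standardized feature matrix behind a shared contract: every model stores
the exact ordered feature-name list it expects and emits scores in
[0, 1] comparable at a common decision threshold (the SVM uses internal
Platt-style probability calibration for this).  Evaluation reports
sensitivity, specificity and accuracy in percent, the Matthews
correlation coefficient, and the trapezoidal AUROC, each tied to the
confusion counts it derives from.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .seqio import NEGATIVE, POSITIVE, LabeledDataset

MODEL_KINDS = ("SVM", "LR", "RF", "ET", "KNN", "MLP")

# short hyperparameter codes used throughout: C (cost), g (gamma), k (kernel),
# ne (n_estimators), nn (n_neighbors), al (algorithm), w (weights),
# a (activation), HL (hidden layer size), s (solver), m (max_iter)
_LEGAL_PARAMS = {
    "SVM": {"C", "g", "k"},
    "LR": {"C", "m"},
    "RF": {"ne"},
    "ET": {"ne"},
    "KNN": {"nn", "al", "w"},
    "MLP": {"a", "HL", "s", "m"},
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameters and seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        illegal = set(self.params) - _LEGAL_PARAMS[self.kind]
        if illegal:
            raise ValueError(f"{self.kind}: illegal hyperparameters {sorted(illegal)}")

    def build(self):
        p = self.params
        if self.kind == "SVM":
            return SVC(
                C=p.get("C", 2.0),
                gamma=p.get("g", 1.0),
                kernel=p.get("k", "rbf"),
                probability=True,
                random_state=self.seed,
            )
        if self.kind == "LR":
            return LogisticRegression(
                C=p.get("C", 1.0), max_iter=p.get("m", 2000), random_state=self.seed
            )
        if self.kind == "RF":
            return RandomForestClassifier(
                n_estimators=p.get("ne", 90), random_state=self.seed
            )
        if self.kind == "ET":
            return ExtraTreesClassifier(
                n_estimators=p.get("ne", 30), random_state=self.seed
            )
        if self.kind == "KNN":
            algo = p.get("al", "auto").replace("-", "_")
            return KNeighborsClassifier(
                n_neighbors=p.get("nn", 10),
                algorithm=algo,
                weights=p.get("w", "distance"),
            )
        if self.kind == "MLP":
            return MLPClassifier(
                activation=p.get("a", "identity"),
                hidden_layer_sizes=(p.get("HL", 3),),
                solver=p.get("s", "adam"),
                max_iter=p.get("m", 100),
                random_state=self.seed,
            )
        raise AssertionError(self.kind)


#: Default hyperparameter grids per family; each grid is a superset of the
#: settings that work well on the curated defensin datasets.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [1, 2, 5], "g": [0.01, 0.1, 0.5, 1], "k": ["rbf"]},
    "LR": {"C": [0.1, 1, 10]},
    "RF": {"ne": [30, 50, 70, 90]},
    "ET": {"ne": [30, 40, 50]},
    "KNN": {"nn": [9, 10], "al": ["ball_tree", "brute"], "w": ["distance"]},
    "MLP": {"a": ["identity", "tanh"], "HL": [3, 10, 15, 17], "s": ["adam"], "m": [100]},
}


def labels_to_binary(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        bad = set(arr) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


# --------------------------------------------------------------------------
# splitting

def split_dataset(
    ds: LabeledDataset, train_frac: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/validation split.

    Per class, round((1 - train_frac) * class size) records go to the
    validation set; membership is a deterministic function of the seed.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_recs, val_recs = [], []
    for label in (POSITIVE, NEGATIVE):
        class_recs = [(p, l) for p, l in ds.records if l == label]
        if len(class_recs) < 5:
            raise ValueError(f"class {label!r} has < 5 members; cannot split")
        n_val = round((1 - train_frac) * len(class_recs))
        order = rng.permutation(len(class_recs))
        val_idx = set(order[:n_val].tolist())
        for i, rec in enumerate(class_recs):
            (val_recs if i in val_idx else train_recs).append(rec)
    return (
        LabeledDataset(train_recs, name=f"{ds.name}_train"),
        LabeledDataset(val_recs, name=f"{ds.name}_validation"),
    )


def kfold(y: Sequence, k: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold assignment over label vector ``y``.

    Returns (train_indices, test_indices) per fold; every sample appears
    in exactly one test fold and per-class fold sizes differ by at most 1.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    yb = labels_to_binary(y)
    if np.bincount(yb, minlength=2).min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(yb)), yb)]


# --------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def confusion(scores: Sequence[float], y: Sequence, threshold: float = 0.5) -> ConfusionMatrix:
    yb = labels_to_binary(y)
    pred = np.asarray(scores) >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (yb == 1))),
        fp=int(np.sum(pred & (yb == 0))),
        tn=int(np.sum(~pred & (yb == 0))),
        fn=int(np.sum(~pred & (yb == 1))),
    )


def sensitivity(cm: ConfusionMatrix) -> float:
    return 100.0 * cm.tp / cm.positives if cm.positives else 0.0


def specificity(cm: ConfusionMatrix) -> float:
    return 100.0 * cm.tn / cm.negatives if cm.negatives else 0.0


def accuracy(cm: ConfusionMatrix) -> float:
    total = cm.positives + cm.negatives
    return 100.0 * (cm.tp + cm.tn) / total if total else 0.0


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = cm.tp * cm.tn - cm.fp * cm.fn
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    return num / math.sqrt(denom) if denom else 0.0


def auroc(scores: Sequence[float], y: Sequence) -> float:
    """Area under the ROC curve (sensitivity vs 1 - specificity),
    trapezoidal over all distinct score thresholds; equals the fraction of
    positive/negative pairs correctly ordered with half credit for ties."""
    yb = labels_to_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("AUROC undefined for single-class labels")
    return float(roc_auc_score(yb, np.asarray(scores)))


@dataclass
class EvalEntry:
    """Metrics at one threshold plus the confusion counts behind them."""

    cm: ConfusionMatrix
    sens: float
    spec: float
    acc: float
    mcc: float
    auroc: float | None
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "TP": self.cm.tp, "FP": self.cm.fp, "TN": self.cm.tn, "FN": self.cm.fn,
            "Sens": self.sens, "Spec": self.spec, "Acc": self.acc,
            "MCC": self.mcc, "AUROC": self.auroc, "threshold": self.threshold,
        }


def evaluate(scores: Sequence[float], y: Sequence, threshold: float = 0.5) -> EvalEntry:
    """Full metric set at a threshold.  With single-class labels the
    threshold metrics are still computed but AUROC is None (warned)."""
    cm = confusion(scores, y, threshold)
    yb = labels_to_binary(y)
    if len(np.unique(yb)) < 2:
        warnings.warn("single-class labels: AUROC undefined, reported as None")
        auc = None
    else:
        auc = auroc(scores, y)
    return EvalEntry(
        cm=cm,
        sens=sensitivity(cm),
        spec=specificity(cm),
        acc=accuracy(cm),
        mcc=mcc(cm),
        auroc=auc,
        threshold=threshold,
    )


# --------------------------------------------------------------------------
# training / prediction

@dataclass
class TrainedModel:
    """A fitted classifier plus the scaler and ordered feature contract."""

    spec: ModelSpec
    feature_names: list[str]
    scaler: StandardScaler
    classifier: object
    threshold: float = 0.5

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                "feature matrix columns do not match the model's contract "
                "(names and order must be identical)"
            )
        return self.scaler.transform(X.to_numpy())


def train(X: pd.DataFrame, y: Sequence, spec: ModelSpec) -> TrainedModel:
    """Standardize ``X`` and fit the classifier described by ``spec``."""
    yb = labels_to_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("training requires both classes")
    scaler = StandardScaler().fit(X.to_numpy())
    clf = spec.build()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        clf.fit(scaler.transform(X.to_numpy()), yb)
    return TrainedModel(
        spec=spec, feature_names=list(X.columns), scaler=scaler, classifier=clf
    )


def predict_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Positive-class scores in [0, 1] for each row of ``X``.

    Column names and order must match the model's feature contract
    exactly; mismatches are a hard error, never silently reordered.
    """
    values = model._check(X)
    return model.classifier.predict_proba(values)[:, 1]


# --------------------------------------------------------------------------
# cross-validation / grid search

@dataclass
class EvalReport:
    """Per-fold metrics, their arithmetic mean, and split provenance."""

    folds: list[EvalEntry]
    aggregate: dict
    provenance: dict = field(default_factory=dict)

    @staticmethod
    def aggregate_folds(folds: list[EvalEntry]) -> dict:
        keys = ("sens", "spec", "acc", "mcc", "auroc")
        agg = {}
        for key in keys:
            vals = [getattr(f, key) for f in folds]
            agg[key] = None if any(v is None for v in vals) else float(np.mean(vals))
        return agg

    def table(self) -> pd.DataFrame:
        rows = [f.as_dict() for f in self.folds]
        df = pd.DataFrame(rows)
        df.index = [f"fold{i+1}" for i in range(len(rows))]
        return df


def cross_validate(
    X: pd.DataFrame, y: Sequence, spec: ModelSpec, k: int = 5, seed: int = 0,
    threshold: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of one model spec.

    Scaling is refit inside each fold (the scaler lives in
    :func:`train`), so no test-fold statistics leak into training.
    """
    yb = labels_to_binary(y)
    folds = kfold(yb, k=k, seed=seed)
    entries, assignment = [], []
    for tr, te in folds:
        model = train(X.iloc[tr], yb[tr], spec)
        scores = predict_scores(model, X.iloc[te])
        entries.append(evaluate(scores, yb[te], threshold))
        assignment.append({"train": tr.tolist(), "test": te.tolist()})
    return EvalReport(
        folds=entries,
        aggregate=EvalReport.aggregate_folds(entries),
        provenance={"k": k, "seed": seed, "fold_indices": assignment,
                    "spec": {"kind": spec.kind, "params": dict(spec.params)}},
    )


def expand_grid(kind: str, grid: dict[str, list] | None = None, seed: int = 0) -> list[ModelSpec]:
    """All hyperparameter combinations of a grid, in declared order."""
    grid = grid if grid is not None else DEFAULT_GRIDS[kind]
    if not grid:
        raise ValueError("empty grid")
    keys = list(grid)
    specs = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        specs.append(ModelSpec(kind, dict(zip(keys, combo)), seed=seed))
    return specs


def grid_search(
    X: pd.DataFrame,
    y: Sequence,
    kind: str,
    grid: dict[str, list] | None = None,
    k: int = 5,
    criterion: str = "auroc",
    seed: int = 0,
) -> tuple[ModelSpec, float]:
    """Pick the spec maximizing the mean CV criterion; ties go to the
    earlier grid point."""
    specs = expand_grid(kind, grid, seed=seed)
    best_spec, best_score = None, -np.inf
    for spec in specs:
        report = cross_validate(X, y, spec, k=k, seed=seed)
        score = report.aggregate[criterion]
        if score is not None and score > best_score:
            best_spec, best_score = spec, score
    assert best_spec is not None
    return best_spec, float(best_score)
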