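"""Evaluation protocol for signature-based peptide classification.

Mirrors the published protocol: a stratified 70/30 train/test split,
seven classifier families (kNN, SVM, neural network, gradient boosting,
logistic regression, decision tree, random forest) configured with the
stated hyperparameters, run in triplicate with recorded seeds, and
reported as replicate-averaged AUC / CA / F1 / precision / recall plus
per-class accuracy and a confusion matrix per model.

Model roster and defaults (scikit-learn estimators):

* kNN — 3 neighbours, Manhattan metric, distance weighting;
* SVM — linear kernel, C = 1.0, tol = 1e-3;
* neural network — one hidden layer of 300 ReLU units, Adam,
  alpha = 1e-3, 200 iterations;
* gradient boosting — 100 trees, learning rate 0.1, depth 3,
  min split 2, subsample 1.0;
* logistic regression — ridge (L2), C = 1;
* decision tree — min 2 instances per leaf, min split 5, depth 100;
* random forest — 10 trees, min split 5.

AUC is macro-averaged one-vs-rest over predicted class probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LabeledDataset",
    "EvalReport",
    "ModelReport",
    "MODEL_FAMILIES",
    "make_models",
    "split_dataset",
    "confusion_matrix",
    "evaluate_models",
    "run_protocol",
]

MODEL_FAMILIES = (
    "knn",
    "svm",
    "neural_network",
    "gradient_boosting",
    "logistic_regression",
    "decision_tree",
    "random_forest",
)


@dataclass
class LabeledDataset:
    """Signature vectors with class labels; ids are unique peptide ids."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    schema: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if not (len(self.ids) == self.X.shape[0] == self.y.shape[0]):
            raise ValueError("ids, X and y must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate peptide ids")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def classes(self) -> list[str]:
        return sorted(set(map(str, self.y)))

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            schema=self.schema,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = list(self.schema) if self.schema else [
            f"f{i}" for i in range(self.X.shape[1])
        ]
        frame = pd.DataFrame(self.X, index=pd.Index(self.ids, name="id"), columns=cols)
        frame["label"] = self.y
        return frame


def split_dataset(
    d: LabeledDataset, train_fraction: float = 0.70, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified-by-class random split.

    The aggregate train size is ``round(train_fraction * n)``, allocated
    across classes by largest remainder.  A class with fewer than 2
    members is kept whole in the training split with a warning.
    """
    if len(d) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    labels = np.asarray([str(v) for v in d.y])
    classes = sorted(set(labels))
    n_train_target = int(round(train_fraction * len(d)))

    per_class: dict[str, np.ndarray] = {}
    singles: list[str] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        per_class[cls] = idx
        if len(idx) < 2:
            singles.append(cls)
    if singles:
        warnings.warn(f"classes with <2 members kept whole in train: {singles}")

    # largest-remainder allocation of the train quota over the strata
    quota: dict[str, int] = {}
    remainders: list[tuple[float, str]] = []
    allocated = 0
    for cls in classes:
        n_cls = len(per_class[cls])
        if cls in singles:
            quota[cls] = n_cls
            allocated += n_cls
            continue
        exact = train_fraction * n_cls
        base = int(np.floor(exact))
        quota[cls] = base
        allocated += base
        remainders.append((exact - base, cls))
    remainders.sort(key=lambda t: (-t[0], t[1]))
    for _, cls in remainders:
        if allocated >= n_train_target:
            break
        if quota[cls] < len(per_class[cls]):
            quota[cls] += 1
            allocated += 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in classes:
        idx = per_class[cls]
        k = quota[cls]
        train_idx.extend(idx[:k].tolist())
        test_idx.extend(idx[k:].tolist())
    return d.subset(train_idx), d.subset(test_idx)


def make_models(seed: int = 0) -> dict[str, object]:
    """Instantiate the seven classifier families with the default settings.

    The margin- and gradient-based learners (SVM, neural network,
    logistic regression) are fit on standardized features — raw
    cumulative pair counts span orders of magnitude, which stalls Adam
    and distorts margins.  Distance- and tree-based learners see the raw
    counts, preserving the Manhattan-distance semantics of the kNN.
    """
    return {
        "knn": KNeighborsClassifier(
            n_neighbors=3, metric="manhattan", weights="distance"
        ),
        "svm": make_pipeline(
            StandardScaler(),
            SVC(C=1.0, kernel="linear", tol=1e-3, random_state=seed),
        ),
        "neural_network": make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(300,),
                activation="relu",
                solver="adam",
                alpha=1e-3,
                max_iter=200,
                random_state=seed,
            ),
        ),
        "gradient_boosting": GradientBoostingClassifier(
            n_estimators=100,
            learning_rate=0.1,
            max_depth=3,
            min_samples_split=2,
            subsample=1.0,
            random_state=seed,
        ),
        # ridge (L2) regularization is the estimator default
        "logistic_regression": make_pipeline(
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=1000, random_state=seed),
        ),
        "decision_tree": DecisionTreeClassifier(
            min_samples_leaf=2,
            min_samples_split=5,
            max_depth=100,
            random_state=seed,
        ),
        "random_forest": RandomForestClassifier(
            n_estimators=10, min_samples_split=5, random_state=seed
        ),
    }


def confusion_matrix(
    truth: Sequence, predicted: Sequence, class_order: Sequence[str]
) -> np.ndarray:
    """Confusion matrix, rows = truth, columns = predicted."""
    truth = [str(v) for v in truth]
    predicted = [str(v) for v in predicted]
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted lengths differ")
    index = {cls: i for i, cls in enumerate(class_order)}
    for label in truth + predicted:
        if label not in index:
            raise ValueError(f"label {label!r} outside class universe")
    mat = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(truth, predicted):
        mat[index[t], index[p]] += 1
    return mat


@dataclass
class ModelReport:
    """Replicate-averaged metrics for one classifier family."""

    auc: float
    ca: float
    f1: float
    precision: float
    recall: float
    per_class_accuracy: dict[str, float]  # percent, by class
    confusion: np.ndarray  # summed over replicates

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ca": self.ca,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "per_class_accuracy": self.per_class_accuracy,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class EvalReport:
    models: dict[str, ModelReport]
    classes: list[str]
    replicate_seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "replicate_seeds": self.replicate_seeds,
            "models": {k: v.to_dict() for k, v in self.models.items()},
        }


def _class_scores(model, X) -> np.ndarray:
    """Per-class score matrix for AUC: probabilities, or softmaxed margins
    for margin classifiers without calibrated probabilities (SVM)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    margin = model.decision_function(X)
    if margin.ndim == 1:
        margin = np.column_stack([-margin, margin])
    shifted = margin - margin.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _score_split(model, train: LabeledDataset, test: LabeledDataset, classes):
    y_train = np.asarray([str(v) for v in train.y])
    y_test = np.asarray([str(v) for v in test.y])
    model.fit(train.X, y_train)
    pred = model.predict(test.X)
    scores = _class_scores(model, test.X)
    if len(classes) == 2:
        auc = roc_auc_score(y_test, scores[:, list(model.classes_).index(classes[1])])
    else:
        auc = roc_auc_score(
            y_test, scores, multi_class="ovr", average="macro",
            labels=list(model.classes_),
        )
    conf = confusion_matrix(y_test, pred, classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # undefined P/R for unpredicted classes
        metrics = dict(
            auc=float(auc),
            ca=float(accuracy_score(y_test, pred)),
            f1=float(f1_score(y_test, pred, average="macro", zero_division=0)),
            precision=float(
                precision_score(y_test, pred, average="macro", zero_division=0)
            ),
            recall=float(
                recall_score(y_test, pred, average="macro", zero_division=0)
            ),
        )
    return metrics, conf


def evaluate_models(
    train: LabeledDataset,
    test: LabeledDataset,
    model_names: Sequence[str] = MODEL_FAMILIES,
    replicates: int = 3,
    seeds: Sequence[int] = (1, 2, 3),
) -> EvalReport:
    """Fit and score on one fixed split, replicated over model seeds.

    Replicates re-initialize the stochastic learners with
    ``seeds[:replicates]``; metrics are replicate averages, confusion
    matrices replicate sums.
    """
    classes = sorted(set(map(str, train.y)) | set(map(str, test.y)))
    if len(set(map(str, train.y))) < 2:
        raise ValueError("training split has fewer than 2 classes")
    seeds = list(seeds)[:replicates]
    reports: dict[str, ModelReport] = {}
    for name in model_names:
        if name not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {name!r}")
        per_rep = []
        conf_sum = np.zeros((len(classes), len(classes)), dtype=int)
        for seed in seeds:
            model = make_models(seed)[name]
            metrics, conf = _score_split(model, train, test, classes)
            per_rep.append(metrics)
            conf_sum += conf
        reports[name] = _aggregate(per_rep, conf_sum, classes)
    return EvalReport(models=reports, classes=classes, replicate_seeds=seeds)


def run_protocol(
    d: LabeledDataset,
    model_names: Sequence[str] = MODEL_FAMILIES,
    train_fraction: float = 0.70,
    replicates: int = 3,
    seeds: Sequence[int] = (1, 2, 3),
) -> EvalReport:
    """The full triplicate protocol: re-split, re-fit and average.

    Each replicate draws a fresh stratified 70/30 split with its own
    seed, fits every requested family, and the report averages the
    metrics over replicates.
    """
    seeds = list(seeds)[:replicates]
    classes = sorted(set(map(str, d.y)))
    per_model: dict[str, list[dict]] = {name: [] for name in model_names}
    conf_sums = {
        name: np.zeros((len(classes), len(classes)), dtype=int)
        for name in model_names
    }
    for seed in seeds:
        train, test = split_dataset(d, train_fraction, seed=seed)
        for name in model_names:
            model = make_models(seed)[name]
            metrics, conf = _score_split(model, train, test, classes)
            per_model[name].append(metrics)
            conf_sums[name] += conf
    reports = {
        name: _aggregate(per_model[name], conf_sums[name], classes)
        for name in model_names
    }
    return EvalReport(models=reports, classes=classes, replicate_seeds=seeds)


def _aggregate(
    per_rep: list[dict], conf_sum: np.ndarray, classes: list[str]
) -> ModelReport:
    mean = {k: float(np.mean([m[k] for m in per_rep])) for k in per_rep[0]}
    row_sums = conf_sum.sum(axis=1)
    per_class = {
        cls: (100.0 * conf_sum[i, i] / row_sums[i] if row_sums[i] else float("nan"))
        for i, cls in enumerate(classes)
    }
    return ModelReport(
        auc=mean["auc"],
        ca=mean["ca"],
        f1=mean["f1"],
        precision=mean["precision"],
        recall=mean["recall"],
        per_class_accuracy=per_class,
        confusion=conf_sum,
    )
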