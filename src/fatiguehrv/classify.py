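"""From-scratch LVQ1 classifier plus the evaluation harness.

LVQ (learning vector quantization) keeps a small codebook of labelled
prototype vectors in the input space.  For every presented training
sample the nearest prototype (Euclidean) is the competition winner: it
moves toward the sample when its class matches and away otherwise, with
a linearly decaying learning rate.  Prediction assigns the class of the
nearest prototype.  Defaults follow the 5-input / 13-prototype / 3-class
configuration with initial learning rate 0.01, at most 1000 training
epochs, and early stop when the one-hot output MSE drops to 0.1.

The evaluation report carries the 3x3 confusion matrix, per-class and
overall accuracy, macro precision/recall, and two F1 variants: the
standard harmonic mean of precision and recall, and a variant that
substitutes overall accuracy for recall (``f1_accuracy_variant``), which
some reports print.  One-vs-rest ROC curves use the negative distance to
the nearest prototype of each class as the class score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "LVQConfig", "LVQModel", "EvaluationReport", "CVResult",
    "train_lvq", "predict_lvq", "class_scores", "select_competitive_size",
    "evaluate", "f1_accuracy_variant", "f1_standard", "roc_one_vs_rest",
    "train_baselines",
]

N_CLASSES = 3


@dataclass(frozen=True)
class LVQConfig:
    n_prototypes: int = 13
    learning_rate: float = 0.01
    max_iterations: int = 1000     # epochs
    target_error: float = 0.1      # one-hot MSE early-stop threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_prototypes < N_CLASSES:
            raise ValueError("need at least one prototype per class")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning_rate must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class LVQModel:
    codebook: np.ndarray           # (n_prototypes, n_features)
    proto_class: np.ndarray        # (n_prototypes,)
    config: LVQConfig
    mse_trace: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {"codebook": self.codebook.tolist(),
                   "proto_class": self.proto_class.tolist(),
                   "config": {"n_prototypes": self.config.n_prototypes,
                              "learning_rate": self.config.learning_rate,
                              "max_iterations": self.config.max_iterations,
                              "target_error": self.config.target_error,
                              "seed": self.config.seed},
                   "mse_trace": self.mse_trace}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LVQModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(codebook=np.asarray(d["codebook"]),
                   proto_class=np.asarray(d["proto_class"], dtype=int),
                   config=LVQConfig(**d["config"]), mse_trace=d["mse_trace"])


def _allocate_prototypes(n_prototypes: int, class_counts: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation proportional to class frequency;
    every class gets at least one prototype.  A balanced 3-class problem
    with 13 prototypes allocates 5/4/4."""
    frac = class_counts / class_counts.sum() * n_prototypes
    alloc = np.maximum(np.floor(frac).astype(int), 1)
    while alloc.sum() > n_prototypes:
        alloc[np.argmax(alloc)] -= 1
    rema = frac - np.floor(frac)
    order = np.argsort(-rema)
    i = 0
    while alloc.sum() < n_prototypes:
        alloc[order[i % len(order)]] += 1
        i += 1
    return alloc


def _one_hot_mse(pred: np.ndarray, true: np.ndarray) -> float:
    """MSE between one-hot encodings of predicted and true labels.

    Equals (2/3) * error-rate for 3 classes."""
    eye = np.eye(N_CLASSES)
    return float(np.mean((eye[pred] - eye[true]) ** 2))


def train_lvq(x: np.ndarray, y: np.ndarray, config: LVQConfig | None = None) -> LVQModel:
    """LVQ1 training with class-stratified random-sample initialization."""
    config = config or LVQConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if not set(classes).issubset(set(range(N_CLASSES))):
        raise ValueError("labels must lie in {0, 1, 2}")
    if len(classes) < N_CLASSES:
        missing = sorted(set(range(N_CLASSES)) - set(classes))
        raise ValueError(f"class(es) {missing} absent from training data")
    rng = np.random.default_rng(config.seed)
    counts_full = np.array([np.sum(y == c) for c in range(N_CLASSES)])
    alloc = _allocate_prototypes(config.n_prototypes, counts_full)
    codebook_rows = []
    proto_class = []
    for c in range(N_CLASSES):
        idx = np.flatnonzero(y == c)
        pick = rng.choice(idx, size=alloc[c], replace=alloc[c] > idx.size)
        codebook_rows.append(x[pick])
        proto_class.extend([c] * alloc[c])
    codebook = np.vstack(codebook_rows).astype(float)
    proto_class = np.asarray(proto_class, dtype=int)

    n = x.shape[0]
    mse_trace: list = []
    for epoch in range(config.max_iterations):
        lr = config.learning_rate * (1.0 - epoch / config.max_iterations)
        order = rng.permutation(n)
        for i in order:
            xi = x[i]
            d2 = np.einsum("ij,ij->i", codebook - xi, codebook - xi)
            w = int(np.argmin(d2))
            step = lr * (xi - codebook[w])
            codebook[w] += step if proto_class[w] == y[i] else -step
        pred = predict_from_codebook(codebook, proto_class, x)
        mse = _one_hot_mse(pred, y)
        mse_trace.append(mse)
        if mse <= config.target_error:
            break
    return LVQModel(codebook=codebook, proto_class=proto_class,
                    config=config, mse_trace=mse_trace)


def predict_from_codebook(codebook: np.ndarray, proto_class: np.ndarray,
                          x: np.ndarray) -> np.ndarray:
    """Nearest-prototype labels; argmin breaks ties at the lowest index."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d2 = ((x[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return proto_class[np.argmin(d2, axis=1)]


def predict_lvq(model: LVQModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.codebook.shape[1]} "
            f"features, got {x.shape[1]}")
    return predict_from_codebook(model.codebook, model.proto_class, x)


def class_scores(model: LVQModel, x: np.ndarray) -> np.ndarray:
    """(n, 3) score matrix: negative distance to the nearest prototype of
    each class; higher is more class-like."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d2 = ((x[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    scores = np.empty((x.shape[0], N_CLASSES))
    for c in range(N_CLASSES):
        scores[:, c] = -np.sqrt(d2[:, model.proto_class == c].min(axis=1))
    return scores


@dataclass
class CVResult:
    candidates: list
    mean_accuracy: list
    mean_mse: list
    chosen: int


def select_competitive_size(x: np.ndarray, y: np.ndarray, candidates,
                            k: int = 10, seed: int = 0,
                            base_config: LVQConfig | None = None) -> CVResult:
    """Stratified k-fold CV over candidate codebook sizes.

    Chosen size maximizes mean held-out accuracy; ties go to the
    smallest size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    candidates = list(candidates)
    if any(c < N_CLASSES for c in candidates):
        raise ValueError("every candidate size must be >= the number of classes")
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    base = base_config or LVQConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs, mses = [], []
    for size in candidates:
        fold_acc, fold_mse = [], []
        for f, (tr, te) in enumerate(skf.split(x, y)):
            cfg = LVQConfig(n_prototypes=size, learning_rate=base.learning_rate,
                            max_iterations=base.max_iterations,
                            target_error=base.target_error, seed=seed + f)
            model = train_lvq(x[tr], y[tr], cfg)
            pred = predict_lvq(model, x[te])
            fold_acc.append(float(np.mean(pred == y[te])))
            fold_mse.append(_one_hot_mse(pred, y[te]))
        accs.append(float(np.mean(fold_acc)))
        mses.append(float(np.mean(fold_mse)))
    best = int(np.argmax(accs))
    # ties -> smallest candidate size
    best_acc = accs[best]
    chosen = min(c for c, a in zip(candidates, accs) if a == best_acc)
    return CVResult(candidates=candidates, mean_accuracy=accs,
                    mean_mse=mses, chosen=chosen)


def f1_standard(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent in, percent out)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def f1_accuracy_variant(precision: float, accuracy: float) -> float:
    """F1 variant substituting overall accuracy for recall:
    2 * P * A / (P + A).  Percent in, percent out."""
    if precision + accuracy == 0:
        return 0.0
    return 2.0 * precision * accuracy / (precision + accuracy)


@dataclass
class EvaluationReport:
    confusion: np.ndarray               # rows true, cols predicted
    n: int
    accuracy: float                     # overall, percent
    per_class_accuracy: np.ndarray      # row-normalized diagonal, percent
    precision: np.ndarray               # per class, percent
    recall: np.ndarray                  # per class, percent
    macro_precision: float
    macro_recall: float
    f1_std: float
    f1_acc_variant: float

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(), "n": self.n,
                "accuracy": self.accuracy,
                "per_class_accuracy": self.per_class_accuracy.tolist(),
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "f1_standard": self.f1_std,
                "f1_accuracy_variant": self.f1_acc_variant}


def confusion_matrix(true: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(true, predicted):
        cm[t, p] += 1
    return cm


def evaluate_confusion(cm: np.ndarray) -> EvaluationReport:
    """All metrics from a 3x3 confusion matrix (rows = true class)."""
    cm = np.asarray(cm, dtype=int)
    n = int(cm.sum())
    diag = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, diag / row, 0.0) * 100.0
        precision = np.where(col > 0, diag / col, 0.0) * 100.0
    accuracy = 100.0 * diag.sum() / n
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    return EvaluationReport(
        confusion=cm, n=n, accuracy=float(accuracy),
        per_class_accuracy=recall.copy(), precision=precision, recall=recall,
        macro_precision=macro_p, macro_recall=macro_r,
        f1_std=f1_standard(macro_p, macro_r),
        f1_acc_variant=f1_accuracy_variant(macro_p, float(accuracy)))


def evaluate(true, predicted) -> EvaluationReport:
    """Confusion matrix and derived metrics for 3-class predictions."""
    true = np.asarray(true, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if true.size != predicted.size:
        raise ValueError("label vectors must have equal length")
    for arr in (true, predicted):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError("labels must lie in {0, 1, 2}")
    return evaluate_confusion(confusion_matrix(true, predicted))


def roc_one_vs_rest(scores: np.ndarray, true: np.ndarray) -> dict:
    """Per-class one-vs-rest ROC curves and AUCs from a (n, 3) score
    matrix; classes absent from the truth get a None AUC flag."""
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true, dtype=int)
    out = {}
    for c in range(N_CLASSES):
        pos = (true == c).astype(int)
        if pos.min() == pos.max():
            out[c] = {"fpr": None, "tpr": None, "auc": None}
            continue
        fpr, tpr, _ = roc_curve(pos, scores[:, c])
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": float(sk_auc(fpr, tpr))}
    defined = [v["auc"] for v in out.values() if v["auc"] is not None]
    out["macro_auc"] = float(np.mean(defined)) if defined else None
    return out


def train_baselines(x_train, y_train, x_test, y_test, seed: int = 0) -> dict:
    """Multilayer-perceptron and RBF-kernel max-margin baselines trained
    and evaluated on the same split as the LVQ model."""
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    out = {}
    mlp = MLPClassifier(hidden_layer_sizes=(13,), max_iter=2000,
                        random_state=seed)
    mlp.fit(x_train, y_train)
    out["bpnn"] = {"model": mlp,
                   "report": evaluate(y_test, mlp.predict(x_test)),
                   "scores": mlp.predict_proba(x_test)}
    svm = SVC(kernel="rbf", random_state=seed, decision_function_shape="ovr")
    svm.fit(x_train, y_train)
    out["svm"] = {"model": svm,
                  "report": evaluate(y_test, svm.predict(x_test)),
                  "scores": svm.decision_function(x_test)}
    return out
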