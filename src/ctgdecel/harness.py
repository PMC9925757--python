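"""Cross-validated classifier harness over deceleration feature sets.

Four classifiers are compared under stratified 5-fold cross-validation with
a fixed seed: a 100-tree random forest, a 2-hidden-layer perceptron, a
Gaussian naive Bayes, and a boosted additive logistic regression ("simple
logistic").  Out-of-fold predictions are pooled into one confusion matrix
per run, from which the full evaluation report is derived.

A second harness reproduces the six-feature neural-network baseline: the
six *time* features only (deceleration start/nadir/end, contraction
start/peak/end), a deep narrow network (four hidden layers) with a single
output per class (one-vs-rest, argmax over the per-class runs), evaluated
on a stratified train/test split with per-class percent-correct tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io import FEATURE_COLUMNS
from .metrics import CLASS_ORDER, ConfusionMatrix, EvaluationReport, report_from_confusion
from .simple_logistic import SimpleLogistic

__all__ = [
    "CLASSIFIERS",
    "WARRICK_FEATURES",
    "HarnessConfig",
    "WarrickReport",
    "train_eval",
    "warrick_nn",
]

CLASSIFIERS = ("random_forest", "mlp", "naive_bayes", "simple_logistic")

#: the six time features of the reduced baseline feature set
WARRICK_FEATURES = (
    "D_st_time", "D_n_time", "D_e_time",
    "U_st_time", "U_p_time", "U_e_time",
)

#: default hyperparameters, named after the conventions of the toolkit the
#: values come from; batch_size is recorded for fidelity and treated as an
#: upper bound on the mini-batch size
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {"batch_size": 100, "bag_size": 100, "iterations": 100},
    "mlp": {"batch_size": 100, "hidden_layers": 2, "learning_rate": 0.4},
    "naive_bayes": {"batch_size": 100},
    "simple_logistic": {
        "batch_size": 100,
        "heuristic_stop": 50,
        "max_boosting_iterations": 400,
    },
}


@dataclass
class HarnessConfig:
    """Configuration of one cross-validation run."""

    classifier: str = "mlp"
    folds: int = 5
    seed: int = 1
    feature_subset: str = "full13"  #: "full13" or "warrick6"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.folds < 2:
            raise ValueError("folds must be ≥ 2")
        if self.feature_subset not in ("full13", "warrick6"):
            raise ValueError(f"unknown feature subset {self.feature_subset!r}")
        merged = dict(DEFAULT_HYPERPARAMETERS[self.classifier])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    @property
    def feature_columns(self) -> tuple[str, ...]:
        return FEATURE_COLUMNS if self.feature_subset == "full13" else WARRICK_FEATURES


def _as_matrix(rows, columns: tuple[str, ...]):
    """LabeledFeatureVector list (or (X, y) pair) → feature matrix + labels."""
    if isinstance(rows, tuple) and len(rows) == 2:
        X, y = rows
        return np.asarray(X, dtype=float), np.asarray(y)
    X = np.array([[getattr(r, c) for c in columns] for r in rows], dtype=float)
    y = np.array([r.label for r in rows])
    return X, y


def _make_classifier(config: HarnessConfig, n_features: int, n_classes: int):
    hp = config.hyperparameters
    if config.classifier == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("iterations", 100)),
            max_samples=None if hp.get("bag_size", 100) >= 100 else hp["bag_size"] / 100.0,
            random_state=config.seed,
        )
    if config.classifier == "mlp":
        width = max(2, (n_features + n_classes) // 2)
        layers = tuple([width] * int(hp.get("hidden_layers", 2)))
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPClassifier(
                        hidden_layer_sizes=layers,
                        solver="sgd",
                        learning_rate_init=float(hp.get("learning_rate", 0.4)),
                        momentum=0.2,
                        batch_size=min(int(hp.get("batch_size", 100)), 100),
                        max_iter=1000,
                        random_state=config.seed,
                    ),
                ),
            ]
        )
    if config.classifier == "naive_bayes":
        return GaussianNB()
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "sl",
                SimpleLogistic(
                    max_iter=int(hp.get("max_boosting_iterations", 400)),
                    patience=int(hp.get("heuristic_stop", 50)),
                    random_state=config.seed,
                ),
            ),
        ]
    )


def train_eval(rows, config: HarnessConfig) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    Returns one :class:`EvaluationReport` built from the single pooled
    confusion matrix; identical seeds give identical folds, predictions and
    reports.
    """
    X, y = _as_matrix(rows, config.feature_columns)
    labels = tuple(lbl for lbl in CLASS_ORDER if lbl in set(y)) or tuple(
        sorted(set(map(str, y)))
    )
    if len(labels) < 2:
        raise ValueError("training data must contain at least two classes")
    counts = {lbl: int(np.sum(y == lbl)) for lbl in labels}
    folds = config.folds
    min_count = min(counts.values())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} members; reducing folds "
            f"{folds} → {min_count}",
            stacklevel=2,
        )
        folds = max(2, min_count)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    lbl_index = {lbl: i for i, lbl in enumerate(labels)}
    y_idx = np.array([lbl_index[lbl] for lbl in y])
    oof_pred = np.empty(len(y), dtype=int)
    oof_proba = np.zeros((len(y), len(labels)))
    for train, test in cv.split(X, y_idx):
        clf = _make_classifier(config, X.shape[1], len(labels))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-converged MLP folds are fine
            clf.fit(X[train], y_idx[train])
            proba = clf.predict_proba(X[test])
        # classifier may have seen a subset of classes in this fold
        present = list(getattr(clf, "classes_", None) if hasattr(clf, "classes_") else clf[-1].classes_)
        full = np.zeros((len(test), len(labels)))
        for col, cls in enumerate(present):
            full[:, int(cls)] = proba[:, col]
        oof_proba[test] = full
        oof_pred[test] = np.argmax(full, axis=1)
    cm = ConfusionMatrix.from_predictions(
        [labels[i] for i in y_idx], [labels[i] for i in oof_pred], labels=labels
    )
    return report_from_confusion(cm, probabilities=oof_proba, true_indices=y_idx)


@dataclass
class WarrickReport:
    """Train/test per-class percent-correct of the six-feature NN baseline."""

    train_percent_correct: dict[str, float]
    test_percent_correct: dict[str, float]
    report: EvaluationReport  #: full metrics on the test split
    labels: tuple[str, ...]


def warrick_nn(
    rows,
    seed: int = 1,
    test_size: float = 0.3,
    hidden_layer_sizes: tuple[int, ...] = (8, 8, 8, 8),
) -> WarrickReport:
    """Six-feature, four-hidden-layer NN baseline with a single output.

    Multiclass labels are handled one-vs-rest: one single-output network per
    class, final label by argmax of the per-class outputs.  Evaluated on a
    stratified train/test split; per-class percent-correct is reported for
    both splits.
    """
    X, y = _as_matrix(rows, WARRICK_FEATURES)
    labels = tuple(lbl for lbl in CLASS_ORDER if lbl in set(y)) or tuple(
        sorted(set(map(str, y)))
    )
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    lbl_index = {lbl: i for i, lbl in enumerate(labels)}
    y_idx = np.array([lbl_index[lbl] for lbl in y])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y_idx, test_size=test_size, random_state=seed, stratify=y_idx
    )
    scaler = StandardScaler().fit(X_tr)
    X_tr_s, X_te_s = scaler.transform(X_tr), scaler.transform(X_te)

    def _scores(X_part: np.ndarray, nets: list) -> np.ndarray:
        return np.column_stack([net.predict_proba(X_part)[:, 1] for net in nets])

    nets = []
    for i in range(len(labels)):
        net = MLPClassifier(
            hidden_layer_sizes=hidden_layer_sizes,
            max_iter=2000,
            random_state=seed,
        )
        target = (y_tr == i).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(np.unique(target)) < 2:
                # degenerate: class absent from training split; constant net
                net = _ConstantScore(float(target.mean()))
                net.fit(X_tr_s, target)
            else:
                net.fit(X_tr_s, target)
        nets.append(net)

    pred_tr = np.argmax(_scores(X_tr_s, nets), axis=1)
    score_te = _scores(X_te_s, nets)
    pred_te = np.argmax(score_te, axis=1)

    def _percent_correct(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
        out = {}
        for i, lbl in enumerate(labels):
            mask = y_true == i
            out[lbl] = float(100.0 * np.mean(y_pred[mask] == i)) if mask.any() else 0.0
        return out

    cm = ConfusionMatrix.from_predictions(
        [labels[i] for i in y_te], [labels[i] for i in pred_te], labels=labels
    )
    proba_te = score_te / np.clip(score_te.sum(axis=1, keepdims=True), 1e-12, None)
    return WarrickReport(
        train_percent_correct=_percent_correct(y_tr, pred_tr),
        test_percent_correct=_percent_correct(y_te, pred_te),
        report=report_from_confusion(cm, probabilities=proba_te, true_indices=y_te),
        labels=labels,
    )


class _ConstantScore:
    """Fallback scorer for a class with a single-valued training target."""

    def __init__(self, rate: float) -> None:
        self.rate = rate
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p = np.full(len(X), self.rate)
        return np.column_stack([1 - p, p])
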