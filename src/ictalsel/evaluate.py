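"""5x2 cross-validated evaluation with stepwise feature elimination.

Classifiers are standard scikit-learn estimators with fixed configurations
(no grid search): decision tree, RBF-kernel SVM, k-nearest neighbors,
random forest and a 100/50/1 multilayer perceptron.  Evaluation is 5
repetitions of stratified 2-fold cross-validation with per-fold min-max
scaling fitted on the training fold only; performance is summarized as
error rate, F1 (positive class = ictal), sensitivity and accuracy.

Two classifier/ranking configurations are compared with the combined 5x2cv
F-test: F = (sum of the 10 squared fold differences) / (2 * sum of the 5
per-repetition variances), referred to F(10, 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .fsm import Ranking

__all__ = [
    "ClassifierConfig",
    "EvalResult",
    "CLASSIFIER_CONFIGS",
    "build_classifier",
    "minmax_scale",
    "elimination_schedule",
    "classification_metrics",
    "run_5x2cv",
    "f_test_5x2cv",
    "simulate_null_ftest",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Fixed classifier configuration (kind + parameters + seed)."""

    kind: str                       # DT | SVM | KNN | RF | ANN
    params: dict = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=seed)


#: frozen configurations per feature set (selected values, no grid search)
CLASSIFIER_CONFIGS: dict[str, dict[str, ClassifierConfig]] = {
    "FS1": {
        "DT": ClassifierConfig("DT", {"min_samples_split": 8}),
        "SVM": ClassifierConfig("SVM", {"C": 2.0, "gamma": "scale"}),
        "KNN": ClassifierConfig("KNN", {"n_neighbors": 15, "metric": "manhattan", "weights": "uniform"}),
        "RF": ClassifierConfig("RF", {"n_estimators": 150, "min_samples_split": 4}),
        "ANN": ClassifierConfig("ANN", {"hidden_layer_sizes": (100, 50), "max_iter": 200}),
    },
    "FS2": {
        "DT": ClassifierConfig("DT", {"min_samples_split": 2}),
        "SVM": ClassifierConfig("SVM", {"C": 2.0, "gamma": "scale"}),
        "KNN": ClassifierConfig("KNN", {"n_neighbors": 10, "metric": "euclidean", "weights": "distance"}),
        "RF": ClassifierConfig("RF", {"n_estimators": 150, "min_samples_split": 4}),
        "ANN": ClassifierConfig("ANN", {"hidden_layer_sizes": (100, 50), "max_iter": 200}),
    },
}


def build_classifier(config: ClassifierConfig):
    """Instantiate the scikit-learn estimator for a configuration."""
    p = config.params
    if config.kind == "DT":
        return DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=p.get("min_samples_split", 8),
            random_state=config.seed,
        )
    if config.kind == "SVM":
        return SVC(
            kernel="rbf", C=p.get("C", 2.0), gamma=p.get("gamma", "scale"),
            probability=True, random_state=config.seed,
        )
    if config.kind == "KNN":
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 15),
            metric=p.get("metric", "manhattan"),
            weights=p.get("weights", "uniform"),
        )
    if config.kind == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 150),
            min_samples_split=p.get("min_samples_split", 4),
            criterion="gini",
            random_state=config.seed,
        )
    if config.kind == "ANN":
        # fixed 200-epoch run: tol=0 and a matching patience disable the
        # loss-plateau stopping rule
        return MLPClassifier(
            hidden_layer_sizes=p.get("hidden_layer_sizes", (100, 50)),
            activation="relu", solver="adam",
            max_iter=p.get("max_iter", 200),
            n_iter_no_change=p.get("max_iter", 200),
            tol=0.0,
            random_state=config.seed,
        )
    raise ValueError(f"unknown classifier kind {config.kind!r}")


def minmax_scale(
    train_X: np.ndarray, test_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature affine map to [0,1] fitted on the training rows only.

    Test values outside the training range map outside [0,1] (no
    clipping); a constant training feature maps to 0 everywhere.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    lo = train_X.min(axis=0)
    span = train_X.max(axis=0) - lo
    scale = np.where(span > 0, 1.0 / np.where(span > 0, span, 1.0), 0.0)
    return (train_X - lo) * scale, (test_X - lo) * scale


def elimination_schedule(n_features: int) -> list[int]:
    """Descending feature counts: n, multiples of 50 below n, 25, 12, 6, 1."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    counts = [n_features]
    counts.extend(range((n_features - 1) // 50 * 50, 0, -50))
    counts.extend([25, 12, 6, 1])
    seen: set[int] = set()
    out = []
    for c in counts:
        if 1 <= c <= n_features and c not in seen:
            seen.add(c)
            out.append(c)
    return sorted(out, reverse=True)


def classification_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """F1 / sensitivity / accuracy from confusion counts (0 on 0/0)."""
    total = tp + fp + fn + tn
    if total <= 0 or min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative with positive total")
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return {"f1": f1, "sensitivity": sens, "accuracy": (tp + tn) / total}


@dataclass
class EvalResult:
    """Outcome of one (classifier, ranking, feature count) 5x2cv run."""

    classifier: str
    fsm: str
    n_features: int
    fold_errors: np.ndarray        # (5, 2)
    f1: float
    sensitivity: float
    accuracy: float

    def __post_init__(self) -> None:
        self.fold_errors = np.asarray(self.fold_errors, dtype=np.float64)
        if self.fold_errors.shape != (5, 2):
            raise ValueError("fold_errors must be 5x2")


def run_5x2cv(
    fm: FeatureMatrix,
    ranking: Ranking | None,
    k: int,
    clf_config: ClassifierConfig,
    seed: int = 0,
    n_repetitions: int = 5,
) -> EvalResult:
    """Train/evaluate on the top-k ranked features under 5x2 CV.

    Each repetition reshuffles and splits the epochs into two stratified
    folds; the model is trained on each fold and tested on the other.
    Min-max scaling is fitted per training fold.  ``ranking=None`` keeps
    all features in matrix order (no elimination).
    """
    if ranking is None:
        names = fm.feature_names[:k]
        method = "none"
    else:
        if set(ranking.feature_names) != set(fm.feature_names):
            raise ValueError("ranking does not cover the feature matrix")
        names = ranking.top(k)
        method = ranking.method
    if k > fm.n_features:
        raise ValueError(f"k={k} exceeds {fm.n_features} features")
    sub = fm.select(names)
    X, y = sub.values, sub.labels

    errors = np.zeros((n_repetitions, 2))
    counts = np.zeros(4)           # tp, fp, fn, tn accumulated over folds
    for rep in range(n_repetitions):
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed + rep)
        for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            Xtr, Xte = minmax_scale(X[train_idx], X[test_idx])
            ytr, yte = y[train_idx], y[test_idx]
            clf = build_classifier(clf_config.with_seed(seed + rep))
            clf.fit(Xtr, ytr)
            pred = clf.predict(Xte)
            errors[rep, fold] = float(np.mean(pred != yte))
            counts += [
                np.sum((pred == 1) & (yte == 1)),
                np.sum((pred == 1) & (yte == 0)),
                np.sum((pred == 0) & (yte == 1)),
                np.sum((pred == 0) & (yte == 0)),
            ]
    metrics = classification_metrics(*(int(c) for c in counts))
    return EvalResult(
        classifier=clf_config.kind,
        fsm=method,
        n_features=k,
        fold_errors=errors,
        f1=metrics["f1"],
        sensitivity=metrics["sensitivity"],
        accuracy=metrics["accuracy"],
    )


def f_test_5x2cv(
    errors_a: np.ndarray, errors_b: np.ndarray, alpha: float = 0.05
) -> dict:
    """Combined 5x2cv F-test on two 5x2 fold-error grids.

    d_ij = errA_ij - errB_ij; s_i^2 = variance of the two differences in
    repetition i; F = sum(d_ij^2) / (2 * sum(s_i^2)) ~ F(10, 5) under the
    null of equal error rates.  Degenerate cases: all differences zero ->
    F = 0, p = 1; zero variance with nonzero differences -> F = inf, p = 0
    flagged as degenerate.
    """
    a = np.asarray(errors_a, dtype=np.float64)
    b = np.asarray(errors_b, dtype=np.float64)
    if a.shape != (5, 2) or b.shape != (5, 2):
        raise ValueError("error grids must be 5x2")
    d = a - b
    numerator = float(np.sum(d**2))
    s2 = ((d[:, 0] - d[:, 1]) ** 2) / 2.0     # two-value sample variance
    denominator = 2.0 * float(np.sum(s2))
    if numerator == 0.0:
        return {"F": 0.0, "p": 1.0, "significant": False, "degenerate": False}
    if denominator == 0.0:
        return {"F": float("inf"), "p": 0.0, "significant": True, "degenerate": True}
    F = numerator / denominator
    p = float(stats.f.sf(F, 10, 5))
    return {"F": F, "p": p, "significant": p < alpha, "degenerate": False}


def simulate_null_ftest(
    n_simulations: int = 500,
    n_per_dataset: int = 120,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Type-I-error study of the 5x2cv F-test under an equal-accuracy null.

    Each simulated dataset has two Gaussian classes with diagonal
    covariance; Gaussian naive Bayes and LDA (both correctly specified,
    hence asymptotically equal-accuracy) are compared on the same fold
    partitions.  Returns the fraction of simulations rejecting at
    ``alpha``.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.naive_bayes import GaussianNB

    rng = np.random.default_rng(seed)
    rejections = 0
    for sim in range(n_simulations):
        n = n_per_dataset
        y = rng.integers(0, 2, size=n)
        X = rng.standard_normal((n, 4)) + y[:, None] * 0.8
        errs_a = np.zeros((5, 2))
        errs_b = np.zeros((5, 2))
        for rep in range(5):
            skf = StratifiedKFold(
                n_splits=2, shuffle=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            for fold, (tr, te) in enumerate(skf.split(X, y)):
                pred_a = GaussianNB().fit(X[tr], y[tr]).predict(X[te])
                pred_b = LinearDiscriminantAnalysis().fit(X[tr], y[tr]).predict(X[te])
                errs_a[rep, fold] = np.mean(pred_a != y[te])
                errs_b[rep, fold] = np.mean(pred_b != y[te])
        if f_test_5x2cv(errs_a, errs_b, alpha)["significant"]:
            rejections += 1
    return rejections / n_simulations
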