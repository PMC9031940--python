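"""Feature-importance ranking methods (FSMs).

Six rankers over a labeled feature matrix:

* ``dt``   — Gini importance of a single CART decision tree: the
  node-probability-weighted impurity decrease summed over the nodes that
  split on each feature, normalized to sum 1.
* ``svm``  — absolute hyperplane weights |w| of a linear soft-margin SVM.
* ``lime`` — local linear surrogates: perturb each explained instance,
  weight perturbations by an exponential kernel on distance, fit a weighted
  ridge surrogate to the model's positive-class score, and average the
  absolute coefficients across instances.
* ``shap`` — kernel SHAP: additive attributions solved from a Shapley-
  kernel-weighted least squares over feature coalitions, with absent
  features imputed from a k-means background set; exact Shapley values
  under full coalition enumeration.
* ``erf``  — permutation importance of a small random forest measured on a
  held-out set: mean increase in misclassification rate when one feature
  is permuted.
* ``rr``   — reciprocal rank fusion of the other five rankings:
  r(f) = 1 / sum_j 1/r_j(f), smaller fused value = better.

Conventions shared by all methods: scores are non-negative (absolute
values are taken where a method can produce signs), per-instance
attributions are aggregated abs-first then averaged, and rank ties break
stably by original column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Ridge
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "Ranking",
    "LimeConfig",
    "ShapConfig",
    "ErfConfig",
    "FsmConfig",
    "FSM_METHODS",
    "rank_dt_gini",
    "rank_svm_weights",
    "rank_lime",
    "rank_kernel_shap",
    "rank_erf_permutation",
    "reciprocal_rank_fusion",
    "aggregate_instance_importance",
    "ranking_subsample",
    "kmeans_background",
]

FSM_METHODS = ("dt", "svm", "lime", "shap", "erf", "rr")


@dataclass
class Ranking:
    """Per-feature non-negative importances and the induced order.

    ``order`` lists feature names by descending score; ties keep the
    original column order (stable sort by index).
    """

    feature_names: list[str]
    scores: np.ndarray
    method: str
    tie_policy: str = "stable-by-column-index"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.scores) != len(self.feature_names):
            raise ValueError("scores length must match feature_names")
        if np.any(self.scores < 0):
            raise ValueError("scores must be non-negative")

    @property
    def order(self) -> list[str]:
        idx = np.argsort(-self.scores, kind="stable")
        return [self.feature_names[i] for i in idx]

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def positions(self) -> dict[str, int]:
        """1-based rank position per feature."""
        return {name: i + 1 for i, name in enumerate(self.order)}

    def to_frame(self) -> pd.DataFrame:
        pos = self.positions()
        return pd.DataFrame(
            {
                "feature_name": self.feature_names,
                "score": self.scores,
                "rank": [pos[n] for n in self.feature_names],
            }
        ).sort_values("rank", ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class LimeConfig:
    n_samples: int = 1000          # perturbations per explained instance
    kernel_width: float | None = None   # default 0.75 * sqrt(M)
    ridge_alpha: float = 1.0
    n_explain: int | None = None   # None = explain every instance
    seed: int = 0


@dataclass(frozen=True)
class ShapConfig:
    background_size: int = 50      # k of the k-means background
    enum_limit: int = 12           # full coalition enumeration up to this M
    n_coalitions: int | None = None   # default 2M + 2048 when sampling
    n_explain: int | None = None
    seed: int = 0


@dataclass(frozen=True)
class ErfConfig:
    n_trees: int = 10
    min_samples_split: int = 2
    n_repeats: int = 5
    seed: int = 0


@dataclass(frozen=True)
class FsmConfig:
    dt_min_samples: int = 4
    svm_c: float = 1.0
    lime: LimeConfig = field(default_factory=LimeConfig)
    shap: ShapConfig = field(default_factory=ShapConfig)
    erf: ErfConfig = field(default_factory=ErfConfig)
    ranking_subsample_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ranking_subsample_fraction <= 1:
            raise ValueError("ranking_subsample_fraction must lie in (0, 1]")


def _require_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires at least two classes in y")


def _positive_score(model, X: np.ndarray) -> np.ndarray:
    """Positive-class probability (or decision score) of a fitted model."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=np.float64)
    raise TypeError(
        f"{type(model).__name__} exposes neither predict_proba nor "
        "decision_function; cannot be explained"
    )


def ranking_subsample(
    X: np.ndarray, y: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified subsample used for ranking-time model training."""
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n = max(1, round(fraction * len(idx)))
        keep.append(rng.choice(idx, size=n, replace=False))
    sel = np.sort(np.concatenate(keep))
    return X[sel], y[sel]


# ---------------------------------------------------------------------------
# the six rankers

def rank_dt_gini(
    X: np.ndarray, y: np.ndarray, feature_names: list[str],
    config: FsmConfig = FsmConfig(),
) -> Ranking:
    """Gini importance of a single decision tree, normalized to sum 1."""
    _require_two_classes(y)
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=config.dt_min_samples,
        random_state=config.seed,
    ).fit(X, y)
    return Ranking(list(feature_names), tree.feature_importances_, method="dt")


def rank_svm_weights(
    X: np.ndarray, y: np.ndarray, feature_names: list[str],
    config: FsmConfig = FsmConfig(),
) -> Ranking:
    """Absolute hyperplane weights of a linear soft-margin SVM (C=1)."""
    _require_two_classes(y)
    svm = SVC(kernel="linear", C=config.svm_c, random_state=config.seed).fit(X, y)
    return Ranking(list(feature_names), np.abs(svm.coef_.ravel()), method="svm")


def aggregate_instance_importance(per_instance: np.ndarray) -> np.ndarray:
    """Abs-first mean across instances (rows) of per-instance attributions."""
    per_instance = np.atleast_2d(np.asarray(per_instance, dtype=np.float64))
    if per_instance.size == 0:
        raise ValueError("empty per-instance matrix")
    return np.abs(per_instance).mean(axis=0)


def _explain_subset(n: int, n_explain: int | None, rng: np.random.Generator) -> np.ndarray:
    if n_explain is None or n_explain >= n:
        return np.arange(n)
    return np.sort(rng.choice(n, size=n_explain, replace=False))


def rank_lime(
    X: np.ndarray, y: np.ndarray, model, feature_names: list[str],
    config: FsmConfig = FsmConfig(),
) -> Ranking:
    """Local linear surrogates averaged over instances.

    Perturbations around instance x are x + eps*sd (eps standard normal,
    sd the per-feature standard deviation of X); sample weights are
    exp(-d^2/width^2) with d the Euclidean norm of eps and width
    0.75*sqrt(M) unless overridden.  The surrogate is a weighted ridge fit
    on the standardized perturbations to the model's positive-class score,
    so coefficients are comparable across features.
    """
    cfg = config.lime
    rng = np.random.default_rng(cfg.seed)
    X = np.asarray(X, dtype=np.float64)
    n, M = X.shape
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    width = cfg.kernel_width if cfg.kernel_width is not None else 0.75 * np.sqrt(M)
    coefs = []
    for i in _explain_subset(n, cfg.n_explain, rng):
        eps = rng.standard_normal((cfg.n_samples, M))
        eps[0] = 0.0                       # the instance itself
        z = X[i] + eps * sd
        target = _positive_score(model, z)
        d2 = np.sum(eps**2, axis=1)
        w = np.exp(-d2 / width**2)
        surrogate = Ridge(alpha=cfg.ridge_alpha).fit(eps, target, sample_weight=w)
        coefs.append(surrogate.coef_)
    scores = aggregate_instance_importance(np.vstack(coefs))
    return Ranking(list(feature_names), scores, method="lime")


def kmeans_background(
    X: np.ndarray, k: int = 50, seed: int = 0
) -> np.ndarray:
    """k-means centroids summarizing a training subset as SHAP background."""
    X = np.asarray(X, dtype=np.float64)
    k = min(k, X.shape[0])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return km.cluster_centers_


def _shapley_kernel_weight(M: int, s: np.ndarray) -> np.ndarray:
    """pi(z') = (M-1) / (C(M,|z'|) * |z'| * (M-|z'|)) for 0 < |z'| < M."""
    from scipy.special import comb

    return (M - 1) / (comb(M, s) * s * (M - s))


def _enumerate_coalitions(M: int) -> np.ndarray:
    z = np.array(list(product((0.0, 1.0), repeat=M)))
    sizes = z.sum(axis=1)
    return z[(sizes > 0) & (sizes < M)]


def _sample_coalitions(M: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw coalitions from the Shapley kernel distribution over sizes.

    All size-1 and size-(M-1) coalitions are always included (they carry
    most of the kernel mass); the remainder is sampled by size with
    probability proportional to the kernel, then uniformly within size.
    """
    base = np.vstack([np.eye(M), 1.0 - np.eye(M)])
    n_rest = max(0, n - len(base))
    if M <= 3 or n_rest == 0:
        return base
    sizes = np.arange(2, M - 1)
    p = 1.0 / (sizes * (M - sizes))
    p = p / p.sum()
    drawn_sizes = rng.choice(sizes, size=n_rest, p=p)
    rows = np.zeros((n_rest, M))
    for r, s in enumerate(drawn_sizes):
        rows[r, rng.choice(M, size=s, replace=False)] = 1.0
    return np.vstack([base, rows])


def _coalition_values(
    x: np.ndarray, z: np.ndarray, background: np.ndarray, model
) -> np.ndarray:
    """v(z') = model output with absent features imputed from the background.

    Present features take the explained instance's values; absent ones are
    replaced by each background centroid in turn and the model output is
    averaged over the centroids (deterministic imputation).
    """
    n_z, M = z.shape
    n_bg = background.shape[0]
    synth = np.broadcast_to(background, (n_z, n_bg, M)).copy()
    mask = z[:, None, :].astype(bool)
    synth[np.broadcast_to(mask, synth.shape)] = np.broadcast_to(
        x, (n_z, n_bg, M)
    )[np.broadcast_to(mask, synth.shape)]
    out = _positive_score(model, synth.reshape(n_z * n_bg, M))
    return out.reshape(n_z, n_bg).mean(axis=1)


def shap_values_instance(
    x: np.ndarray, model, background: np.ndarray,
    enum_limit: int = 12, n_coalitions: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Kernel SHAP attributions for one instance.

    Solves the Shapley-kernel-weighted least squares under the additive
    (local accuracy) constraint sum(phi) = f(x) - E_bg[f], eliminating the
    last coefficient.  With M <= ``enum_limit`` all 2^M - 2 proper
    coalitions are enumerated and the result equals exact Shapley values
    of the imputation value function.
    """
    if background.size == 0:
        raise ValueError("background set is empty")
    rng = rng or np.random.default_rng(0)
    M = len(x)
    if M <= enum_limit:
        z = _enumerate_coalitions(M)
        w = _shapley_kernel_weight(M, z.sum(axis=1))
    else:
        n = n_coalitions if n_coalitions is not None else 2 * M + 2048
        z = _sample_coalitions(M, n, rng)
        # sampled coalitions are drawn from the kernel distribution, so the
        # regression is unweighted within the sampled set
        w = np.ones(len(z))
    phi0 = float(np.mean(_positive_score(model, background)))
    fx = float(_positive_score(model, x[None, :])[0])
    v = _coalition_values(x, z, background, model)
    y_adj = v - phi0 - z[:, -1] * (fx - phi0)
    A = z[:, :-1] - z[:, -1:]
    Aw = A * w[:, None]
    beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y_adj, rcond=None)
    phi = np.empty(M)
    phi[:-1] = beta
    phi[-1] = (fx - phi0) - beta.sum()
    return phi


def rank_kernel_shap(
    X: np.ndarray, y: np.ndarray, model, feature_names: list[str],
    config: FsmConfig = FsmConfig(),
    background: np.ndarray | None = None,
) -> Ranking:
    """Kernel SHAP attributions aggregated abs-first over instances."""
    cfg = config.shap
    rng = np.random.default_rng(cfg.seed)
    X = np.asarray(X, dtype=np.float64)
    if background is None:
        background = kmeans_background(X, cfg.background_size, cfg.seed)
    rows = [
        shap_values_instance(
            X[i], model, background, cfg.enum_limit, cfg.n_coalitions, rng
        )
        for i in _explain_subset(X.shape[0], cfg.n_explain, rng)
    ]
    scores = aggregate_instance_importance(np.vstack(rows))
    return Ranking(list(feature_names), scores, method="shap")


def rank_erf_permutation(
    X: np.ndarray, y: np.ndarray, feature_names: list[str],
    X_holdout: np.ndarray, y_holdout: np.ndarray,
    config: FsmConfig = FsmConfig(),
) -> Ranking:
    """Permutation importance of a 10-tree random forest on a held-out set.

    score(feature) = mean over repeats of (holdout error with the feature
    permuted - baseline holdout error); the absolute-value convention is
    applied so small negative estimates do not violate the score contract.
    """
    _require_two_classes(y)
    if len(np.unique(y_holdout)) < 2:
        raise ValueError("holdout set must contain both classes")
    cfg = config.erf
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        min_samples_split=cfg.min_samples_split,
        criterion="gini",
        random_state=cfg.seed,
    ).fit(X, y)
    result = permutation_importance(
        rf, X_holdout, y_holdout,
        scoring="accuracy", n_repeats=cfg.n_repeats, random_state=cfg.seed,
    )
    # decrease in accuracy == increase in misclassification rate
    return Ranking(list(feature_names), np.abs(result.importances_mean), method="erf")


def reciprocal_rank_fusion(rankings: list[Ranking]) -> Ranking:
    """Fuse ranked lists: r(f) = 1 / sum_j 1/r_j(f), ascending r(f) wins.

    The returned Ranking stores sum_j 1/r_j(f) (= 1/r(f)) as its score so
    the descending-score ordering convention is preserved.
    """
    if not rankings:
        raise ValueError("need at least one ranking to fuse")
    universe = rankings[0].feature_names
    for r in rankings[1:]:
        if set(r.feature_names) != set(universe):
            raise ValueError("rankings cover different feature sets")
    scores = np.zeros(len(universe))
    for r in rankings:
        pos = r.positions()
        scores += np.array([1.0 / pos[f] for f in universe])
    return Ranking(list(universe), scores, method="rr")
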