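"""Agreement between selected feature subsets and top-feature reports.

Feature-set stability across ranking methods is measured with the Jaccard
index |A intersect B| / |A union B| over each method's top-k features.
Printed values are floored to two decimals (matching the convention of the
published similarity heatmaps); full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fsm import Ranking

__all__ = [
    "SimilarityMatrix",
    "jaccard",
    "present_jaccard",
    "pairwise_similarity",
    "top_features_report",
]


def jaccard(a: set[str], b: set[str]) -> float:
    """|a intersect b| / |a union b|; undefined (error) for two empty sets."""
    union = set(a) | set(b)
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(set(a) & set(b)) / len(union)


def present_jaccard(value: float) -> float:
    """Presentation rounding: floor to two decimals."""
    return math.floor(value * 100 + 1e-12) / 100


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Jaccard indices at one subset size k."""

    methods: list[str]
    k: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        m = len(self.methods)
        if self.values.shape != (m, m):
            raise ValueError("values must be square over methods")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("diagonal must be exactly 1")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")

    def to_frame(self, presentation: bool = False) -> pd.DataFrame:
        vals = self.values
        if presentation:
            vals = np.vectorize(present_jaccard)(vals)
        return pd.DataFrame(vals, index=self.methods, columns=self.methods)

    def to_csv(self, path, presentation: bool = False) -> None:
        self.to_frame(presentation).to_csv(path)


def pairwise_similarity(rankings: list[Ranking], k: int) -> SimilarityMatrix:
    """Jaccard indices between the top-k feature sets of each ranking."""
    if not rankings:
        raise ValueError("need at least one ranking")
    universe = set(rankings[0].feature_names)
    for r in rankings[1:]:
        if set(r.feature_names) != universe:
            raise ValueError("rankings cover different feature universes")
    if k > len(universe):
        raise ValueError(f"k={k} exceeds universe size {len(universe)}")
    tops = [set(r.top(k)) for r in rankings]
    m = len(rankings)
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = jaccard(tops[i], tops[j])
    return SimilarityMatrix(
        methods=[r.method for r in rankings], k=k, values=values
    )


def top_features_report(ranking: Ranking, n: int = 10) -> pd.DataFrame:
    """Top-n features with their raw (unnormalized) importance values."""
    if n > len(ranking.feature_names):
        raise ValueError(f"n={n} exceeds {len(ranking.feature_names)} features")
    score = dict(zip(ranking.feature_names, ranking.scores))
    names = ranking.top(n)
    return pd.DataFrame(
        {"feature_name": names, "importance": [score[f] for f in names]}
    )
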