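"""Per-epoch EEG descriptors and the named feature matrix.

Two fixed 8-metric sets are computed per channel and frequency band:

* **FS1** — median frequency, variance, skewness, kurtosis, peak frequency,
  root mean square, range, number of zero crossings.
* **FS2** — minimum, Hjorth complexity, Hjorth mobility, interquartile
  range, median absolute deviation, sample entropy (m=2, r=0.2*sd), mean,
  standard deviation.

Columns are named ``band_channel_metric`` (e.g. ``alpha_FP1-F3_skew``) in
deterministic band-major order, and highly correlated columns (|Pearson r|
above 0.95) can be pruned greedily.

Degenerate-input conventions (all chosen to keep the matrix finite):
skewness/kurtosis of a constant epoch are 0; kurtosis is excess kurtosis;
a zero-power epoch has both spectral metrics 0; Hjorth parameters of a
constant epoch are 0; sample entropy of a constant epoch is 0 and is capped
at ln(n) when no template pair matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .preprocess import EpochSet

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "PruneRecord",
    "FS1_METRICS",
    "FS2_METRICS",
    "amplitude_stats",
    "spectral_metrics",
    "hjorth",
    "sample_entropy",
    "extract_features",
    "prune_correlated",
]

FS1_METRICS = ("medfreq", "var", "skew", "kurt", "peakfreq", "rms", "range", "zc")
FS2_METRICS = ("min", "complexity", "mobility", "iqr", "mad", "sampen", "mean", "sd")


@dataclass(frozen=True)
class FeatureConfig:
    feature_set: str = "FS1"            # "FS1" | "FS2"
    sampen_m: int = 2
    sampen_r_coeff: float = 0.2         # tolerance = coeff * epoch sd
    corr_threshold: float = 0.95
    psd_window: str = "hann"

    def __post_init__(self) -> None:
        if self.feature_set not in ("FS1", "FS2"):
            raise ValueError("feature_set must be 'FS1' or 'FS2'")
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")

    @property
    def metrics(self) -> tuple[str, ...]:
        return FS1_METRICS if self.feature_set == "FS1" else FS2_METRICS


@dataclass
class FeatureMatrix:
    values: np.ndarray            # (n_epochs, n_features)
    feature_names: list[str]
    labels: np.ndarray            # (n_epochs,), 1 = ictal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), self.labels.copy())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=np.float64), list(df.columns), labels)


# ---------------------------------------------------------------------------
# scalar metrics (1-D epoch convenience forms; extraction uses the
# vectorized internals below)

def amplitude_stats(x: np.ndarray) -> dict[str, float]:
    """Time-domain amplitude statistics of one epoch."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("epoch must have at least 2 samples")
    stats = _amplitude_stats_nd(x[None, :])
    return {k: float(v[0]) for k, v in stats.items()}


def spectral_metrics(x: np.ndarray, fs: float, window: str = "hann") -> dict[str, float]:
    """Median and peak frequency of a single-epoch periodogram."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError("epoch must have at least 4 samples")
    med, peak = _spectral_nd(x[None, :], fs, window)
    return {"median_frequency": float(med[0]), "peak_frequency": float(peak[0])}


def hjorth(x: np.ndarray) -> dict[str, float]:
    """Hjorth mobility and complexity.

    mobility = sqrt(var(dx)/var(x)); complexity = mobility(dx)/mobility(x).
    A constant epoch returns (0, 0) by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    mob, comp = _hjorth_nd(x[None, :])
    return {"mobility": float(mob[0]), "complexity": float(comp[0])}


def sample_entropy(x: np.ndarray, m: int = 2, r_coeff: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) with r = r_coeff * sd(x).

    -ln(A/B) with A (resp. B) the number of template pairs of length m+1
    (resp. m) whose Chebyshev distance is within r, self-matches excluded.
    Conventions: sd = 0 makes the tolerance 0 and equal samples matching,
    so a constant epoch returns 0; if A or B is 0 the value is capped at
    ln(n).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"epoch length {n} too short for m={m}")
    r = r_coeff * x.std()
    n_templates = n - m
    idx = np.arange(n_templates)[:, None] + np.arange(m + 1)[None, :]
    templates = x[idx]                      # (n-m, m+1)
    b = int(np.count_nonzero(pdist(templates[:, :m], "chebyshev") <= r))
    a = int(np.count_nonzero(pdist(templates, "chebyshev") <= r))
    if a == 0 or b == 0:
        return float(np.log(n))
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# vectorized internals: each takes (n, samples) and returns per-row values

def _amplitude_stats_nd(x: np.ndarray) -> dict[str, np.ndarray]:
    mean = x.mean(axis=-1)
    sd = x.std(axis=-1)
    var = x.var(axis=-1)
    centered = x - mean[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        m3 = (centered**3).mean(axis=-1)
        m4 = (centered**4).mean(axis=-1)
        skew = np.where(sd > 0, m3 / np.where(sd > 0, sd, 1.0) ** 3, 0.0)
        kurt = np.where(var > 0, m4 / np.where(var > 0, var, 1.0) ** 2 - 3.0, 0.0)
    q75, q25 = np.percentile(x, [75, 25], axis=-1)
    med = np.median(x, axis=-1)
    mad = np.median(np.abs(x - med[..., None]), axis=-1)
    signs = np.sign(x)
    # an exact zero inherits the previous sign so it is not counted twice
    for i in range(1, signs.shape[-1]):
        col = signs[..., i]
        signs[..., i] = np.where(col == 0, signs[..., i - 1], col)
    zc = np.count_nonzero(np.diff(signs, axis=-1) != 0, axis=-1).astype(float)
    return {
        "var": var,
        "skew": skew,
        "kurt": kurt,
        "rms": np.sqrt((x**2).mean(axis=-1)),
        "range": x.max(axis=-1) - x.min(axis=-1),
        "zc": zc,
        "min": x.min(axis=-1),
        "mean": mean,
        "sd": sd,
        "iqr": q75 - q25,
        "mad": mad,
    }


def _spectral_nd(x: np.ndarray, fs: float, window: str) -> tuple[np.ndarray, np.ndarray]:
    freqs, psd = sps.periodogram(x, fs=fs, window=window, axis=-1)
    total = psd.sum(axis=-1)
    safe_total = np.where(total > 0, total, 1.0)
    cum = np.cumsum(psd, axis=-1) / safe_total[..., None]
    med_idx = np.argmax(cum >= 0.5, axis=-1)
    median_freq = np.where(total > 0, freqs[med_idx], 0.0)
    peak_freq = np.where(total > 0, freqs[np.argmax(psd, axis=-1)], 0.0)
    return median_freq, peak_freq


def _hjorth_nd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dx = np.diff(x, axis=-1)
    ddx = np.diff(dx, axis=-1)
    v0 = x.var(axis=-1)
    v1 = dx.var(axis=-1)
    v2 = ddx.var(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mobility = np.where(v0 > 0, np.sqrt(v1 / np.where(v0 > 0, v0, 1.0)), 0.0)
        mob_dx = np.where(v1 > 0, np.sqrt(v2 / np.where(v1 > 0, v1, 1.0)), 0.0)
        complexity = np.where(mobility > 0, mob_dx / np.where(mobility > 0, mobility, 1.0), 0.0)
    return mobility, complexity


# ---------------------------------------------------------------------------

def extract_features(
    epochset: EpochSet, config: FeatureConfig = FeatureConfig()
) -> FeatureMatrix:
    """Assemble the named feature matrix from a band-decomposed epoch set.

    Column order is band-major, then channel, then metric, following the
    band order of ``epochset.band_epochs`` and the fixed metric order of
    the chosen feature set; with B bands, C channels and 8 metrics the
    matrix has exactly B*C*8 columns.
    """
    if epochset.band_epochs is None:
        raise ValueError("epoch set must be band-decomposed first")
    metrics = config.metrics
    names: list[str] = []
    columns: list[np.ndarray] = []
    for band, tensor in epochset.band_epochs.items():
        n, n_ch, _ = tensor.shape
        flat = tensor.reshape(n * n_ch, -1)
        amp = _amplitude_stats_nd(flat)
        values: dict[str, np.ndarray] = {k: v.reshape(n, n_ch) for k, v in amp.items()}
        if config.feature_set == "FS1":
            med, peak = _spectral_nd(flat, epochset.fs, config.psd_window)
            values["medfreq"] = med.reshape(n, n_ch)
            values["peakfreq"] = peak.reshape(n, n_ch)
        else:
            mob, comp = _hjorth_nd(flat)
            values["mobility"] = mob.reshape(n, n_ch)
            values["complexity"] = comp.reshape(n, n_ch)
            sampen = np.array(
                [sample_entropy(row, config.sampen_m, config.sampen_r_coeff) for row in flat]
            )
            values["sampen"] = sampen.reshape(n, n_ch)
        for ch_i, ch_name in enumerate(epochset.channel_names):
            for metric in metrics:
                names.append(f"{band}_{ch_name}_{metric}")
                columns.append(values[metric][:, ch_i])
    return FeatureMatrix(
        values=np.column_stack(columns),
        feature_names=names,
        labels=epochset.labels.copy(),
    )


@dataclass(frozen=True)
class PruneRecord:
    name: str
    reason: str                  # "correlated" | "zero_variance"
    partner: str | None = None   # retained column it correlated with
    r: float = float("nan")


def prune_correlated(
    fm: FeatureMatrix, threshold: float = 0.95
) -> tuple[FeatureMatrix, list[PruneRecord]]:
    """Greedy correlation pruning in column order.

    For every pair with |Pearson r| above ``threshold`` the later column is
    dropped.  Zero-variance columns correlate with nothing: they are
    retained but flagged in the audit list.  The operation is idempotent.
    """
    if fm.values.shape[0] < 3:
        raise ValueError("need at least 3 epochs to estimate correlations")
    X = fm.values
    sd = X.std(axis=0)
    audit: list[PruneRecord] = [
        PruneRecord(fm.feature_names[j], "zero_variance")
        for j in np.flatnonzero(sd == 0)
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    keep: list[int] = []
    for j in range(X.shape[1]):
        hit = next(
            (i for i in keep if sd[i] > 0 and sd[j] > 0 and abs(corr[i, j]) > threshold),
            None,
        )
        if hit is None:
            keep.append(j)
        else:
            audit.append(
                PruneRecord(
                    fm.feature_names[j], "correlated",
                    partner=fm.feature_names[hit], r=float(corr[hit, j]),
                )
            )
    pruned = FeatureMatrix(
        values=X[:, keep],
        feature_names=[fm.feature_names[j] for j in keep],
        labels=fm.labels.copy(),
    )
    return pruned, audit
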