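"""Montage conversion, filtering, sub-band decomposition, epoching, rebalancing.

The stage mirrors standard scalp-EEG seizure-detection preprocessing: convert
to a longitudinal bipolar montage, high-pass at 0.5 Hz (2nd-order
Butterworth) and notch out the power-line frequency, cut 2-s epochs (ictal
epochs with 50% overlap to soften class imbalance), subsample the non-ictal
class to an at-most 9:1 ratio, and band-pass each epoch into five sub-bands
(complete 0.5-30, delta 0.5-4, theta 4-8, alpha 8-12, beta 12-25 Hz).

All filters are applied zero-phase (forward-backward), keeping epoch and
annotation alignment exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synth import Recording

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "MontageError",
    "DEFAULT_BANDS",
    "DEFAULT_MONTAGE_PAIRS",
    "to_bipolar",
    "filter_recording",
    "segment",
    "rebalance",
    "band_decompose",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "complete": (0.5, 30.0),
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 25.0),
}

#: standard 18-derivation longitudinal bipolar ("double banana") montage
DEFAULT_MONTAGE_PAIRS: list[tuple[str, str]] = [
    ("FP1", "F7"), ("F7", "T7"), ("T7", "P7"), ("P7", "O1"),
    ("FP1", "F3"), ("F3", "C3"), ("C3", "P3"), ("P3", "O1"),
    ("FP2", "F4"), ("F4", "C4"), ("C4", "P4"), ("P4", "O2"),
    ("FP2", "F8"), ("F8", "T8"), ("T8", "P8"), ("P8", "O2"),
    ("FZ", "CZ"), ("CZ", "PZ"),
]


class MontageError(KeyError):
    """A montage references electrodes absent from the recording."""


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_hz: float = 0.5
    highpass_order: int = 2
    notch_hz: float = 60.0
    notch_q: float = 30.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    band_filter_order: int = 2
    window_s: float = 2.0
    ictal_overlap: float = 0.5
    #: minimum in-seizure sample fraction for an epoch to count as ictal;
    #: boundary epochs below it are discarded outright
    ictal_label_fraction: float = 0.5
    target_ratio: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r} edges must satisfy 0 < low < high")
        if not 0 < self.ictal_overlap < 1:
            raise ValueError("ictal_overlap must lie in (0, 1)")
        if self.target_ratio < 1:
            raise ValueError("target_ratio must be >= 1")


@dataclass
class EpochSet:
    """Fixed-length labeled epochs, optionally decomposed into sub-bands.

    ``epochs`` is (n, channels, samples); after :func:`band_decompose`,
    ``band_epochs`` maps band name -> an identically shaped tensor.
    """

    epochs: np.ndarray
    labels: np.ndarray            # (n,), 1 = ictal
    channel_names: list[str]
    fs: float
    band_epochs: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n, channels, samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal epoch count")
        if self.band_epochs is not None:
            for name, arr in self.band_epochs.items():
                if arr.shape != self.epochs.shape:
                    raise ValueError(f"band {name!r} tensor shape mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def band_names(self) -> list[str]:
        return [] if self.band_epochs is None else list(self.band_epochs)


def _electrode_index(recording: Recording) -> dict[str, int]:
    return {name.upper(): i for i, name in enumerate(recording.channel_names)}


def to_bipolar(
    recording: Recording,
    montage: list[tuple[str, str]] | None = None,
) -> Recording:
    """Derive bipolar channels: output i = anode signal - cathode signal."""
    if montage is None:
        montage = DEFAULT_MONTAGE_PAIRS
    index = _electrode_index(recording)
    missing = sorted(
        {e for pair in montage for e in pair if e.upper() not in index}
    )
    if missing:
        raise MontageError(
            f"montage references absent electrodes: {', '.join(missing)}"
        )
    rows = [
        recording.data[index[a.upper()]] - recording.data[index[c.upper()]]
        for a, c in montage
    ]
    return Recording(
        data=np.vstack(rows),
        fs=recording.fs,
        channel_names=[f"{a}-{c}" for a, c in montage],
        seizures=list(recording.seizures),
    )


def filter_recording(
    recording: Recording, config: PreprocessConfig = PreprocessConfig()
) -> Recording:
    """2nd-order Butterworth high-pass then IIR notch, both zero-phase."""
    nyq = recording.fs / 2.0
    if config.notch_hz >= nyq:
        raise ValueError(
            f"notch at {config.notch_hz} Hz requires fs > {2 * config.notch_hz} Hz"
        )
    if config.highpass_hz >= nyq:
        raise ValueError("high-pass cutoff at or above Nyquist")
    sos = signal.butter(
        config.highpass_order, config.highpass_hz, btype="highpass",
        fs=recording.fs, output="sos",
    )
    b_notch, a_notch = signal.iirnotch(config.notch_hz, config.notch_q, fs=recording.fs)
    out = signal.sosfiltfilt(sos, recording.data, axis=1)
    out = signal.filtfilt(b_notch, a_notch, out, axis=1)
    return Recording(
        data=out,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        seizures=list(recording.seizures),
    )


def segment(
    recording: Recording, config: PreprocessConfig = PreprocessConfig()
) -> EpochSet:
    """Cut labeled epochs.

    Ictal epochs stride ``window_s * ictal_overlap`` inside each annotated
    interval (epochs lie fully within the interval).  Non-ictal epochs tile
    the record without overlap; a tiled epoch is kept as non-ictal only if
    it contains no in-seizure samples at all, dropped as ambiguous when its
    in-seizure fraction is below ``ictal_label_fraction``, and dropped as
    already-covered otherwise.
    """
    win = round(config.window_s * recording.fs)
    if recording.n_samples < win:
        raise ValueError("recording shorter than one window")
    stride = round(config.window_s * config.ictal_overlap * recording.fs)
    seiz = [
        (round(s * recording.fs), round(e * recording.fs))
        for s, e in recording.seizures
    ]

    epochs: list[np.ndarray] = []
    labels: list[int] = []
    for s0, s1 in seiz:
        start = s0
        while start + win <= s1:
            epochs.append(recording.data[:, start : start + win])
            labels.append(1)
            start += stride

    def ictal_fraction(start: int) -> float:
        inside = 0
        for s0, s1 in seiz:
            inside += max(0, min(start + win, s1) - max(start, s0))
        return inside / win

    for start in range(0, recording.n_samples - win + 1, win):
        frac = ictal_fraction(start)
        if frac == 0.0:
            epochs.append(recording.data[:, start : start + win])
            labels.append(0)
        # 0 < frac: either ambiguous boundary (discard) or ictal territory
        # already covered by the overlapping pass above

    return EpochSet(
        epochs=np.stack(epochs) if epochs else np.empty((0, recording.n_channels, win)),
        labels=np.array(labels, dtype=np.int64),
        channel_names=list(recording.channel_names),
        fs=recording.fs,
    )


def rebalance(
    epochset: EpochSet, config: PreprocessConfig = PreprocessConfig()
) -> EpochSet:
    """Subsample non-ictal epochs to at most ``target_ratio`` per ictal one.

    Every ictal epoch is kept; the retained non-ictal subset is drawn
    uniformly without replacement with the config seed.  Original epoch
    order is preserved.
    """
    ictal_idx = np.flatnonzero(epochset.labels == 1)
    nonictal_idx = np.flatnonzero(epochset.labels == 0)
    if len(ictal_idx) == 0:
        raise ValueError("cannot rebalance an epoch set with no ictal epochs")
    n_keep = min(len(nonictal_idx), config.target_ratio * len(ictal_idx))
    rng = np.random.default_rng(config.seed)
    kept_nonictal = rng.choice(nonictal_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([ictal_idx, kept_nonictal]))
    return EpochSet(
        epochs=epochset.epochs[keep],
        labels=epochset.labels[keep],
        channel_names=list(epochset.channel_names),
        fs=epochset.fs,
        band_epochs=None
        if epochset.band_epochs is None
        else {k: v[keep] for k, v in epochset.band_epochs.items()},
    )


def band_decompose(
    epochset: EpochSet, config: PreprocessConfig = PreprocessConfig()
) -> EpochSet:
    """Band-pass every epoch into each configured band (zero-phase).

    Returns a new EpochSet whose ``band_epochs`` holds one identically
    shaped tensor per band; epoch count, channels and samples are conserved.
    """
    nyq = epochset.fs / 2.0
    band_epochs: dict[str, np.ndarray] = {}
    for name, (lo, hi) in config.bands.items():
        if hi >= nyq:
            raise ValueError(f"band {name!r} upper edge {hi} Hz at or above Nyquist")
        sos = signal.butter(
            config.band_filter_order, (lo, hi), btype="bandpass",
            fs=epochset.fs, output="sos",
        )
        band_epochs[name] = signal.sosfiltfilt(sos, epochset.epochs, axis=2)
    return EpochSet(
        epochs=epochset.epochs,
        labels=epochset.labels.copy(),
        channel_names=list(epochset.channel_names),
        fs=epochset.fs,
        band_epochs=band_epochs,
    )
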