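"""Synthetic annotated scalp-EEG recordings with planted ictal structure.

The generator emulates the gross statistics of long-term scalp EEG used in
seizure-detection studies: 256 Hz sampling, bipolar longitudinal ("double
banana") channels, hour-scale records containing a handful of seizures, and
a background of 1/f colored noise plus a modest alpha-range oscillation.
Seizures superimpose a higher-amplitude rhythmic component on a chosen set
of channel/band combinations, so a known subset of band/channel amplitude
features is genuinely discriminative.  That known subset
(:func:`ground_truth_features`) is what makes ranking methods testable
without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BackgroundSpec",
    "IctalComponent",
    "SynthConfig",
    "Recording",
    "SeizurePlacementError",
    "generate_recording",
    "ground_truth_features",
    "CHB_STYLE_21",
    "DOUBLE_BANANA_18",
    "MONOPOLAR_19",
]

# 18-channel longitudinal bipolar montage over the 10-20 electrode set.
DOUBLE_BANANA_18 = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
]

# The 21 channels conserved across CHB-MIT-style records: the standard 18
# double-banana derivations plus three temporal-chain extras.
CHB_STYLE_21 = DOUBLE_BANANA_18 + ["T7-FT9", "FT9-FT10", "FT10-T8"]

# 19 monopolar 10-20 electrodes from which the 18-pair montage is derived.
MONOPOLAR_19 = [
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "FZ", "CZ", "PZ",
]

#: canonical band names -> (low, high) Hz, shared with the preprocessing stage
BAND_EDGES = {
    "complete": (0.5, 30.0),
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 25.0),
}

#: feature metrics whose value scales with signal amplitude; used to name
#: the ground-truth discriminative features for a planted amplitude gain
AMPLITUDE_METRICS = {
    "FS1": ("var", "rms", "range"),
    "FS2": ("min", "iqr", "mad", "sd"),
}


@dataclass(frozen=True)
class BackgroundSpec:
    """Background activity: 1/f colored noise plus an alpha oscillation.

    Amplitudes are nominal microvolts; absolute scale is irrelevant
    downstream because evaluation min-max-normalizes features.
    """

    noise_amplitude: float = 20.0   # RMS of the 1/f component, uV
    noise_exponent: float = 1.0     # spectral slope of the colored noise
    alpha_amplitude: float = 5.0    # peak amplitude of the oscillation, uV
    alpha_freq_hz: float = 10.0


@dataclass(frozen=True)
class IctalComponent:
    """One planted seizure expression: a rhythm added on one channel."""

    channel: int
    band: str                      # key of BAND_EDGES
    amplitude_gain: float = 4.0    # rhythm amplitude as multiple of alpha_amplitude
    freq_hz: float = 6.0

    def __post_init__(self) -> None:
        if self.band not in BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")
        lo, hi = BAND_EDGES[self.band]
        if not (lo <= self.freq_hz <= hi):
            raise ValueError(
                f"rhythm frequency {self.freq_hz} Hz outside {self.band} band "
                f"({lo}-{hi} Hz)"
            )


@dataclass(frozen=True)
class SynthConfig:
    n_channels: int = 21
    fs: float = 256.0
    duration: float = 3600.0
    n_seizures: int = 4
    seizure_duration: float = 40.0   # mean seizure length, seconds
    seizure_jitter: float = 10.0     # +- uniform jitter on the length
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    ictal_spec: tuple[IctalComponent, ...] = (
        IctalComponent(channel=0, band="theta", amplitude_gain=4.0, freq_hz=6.0),
    )
    min_gap: float = 4.0             # 2x the 2-s analysis window
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = self.duration * self.fs
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        for comp in self.ictal_spec:
            if not 0 <= comp.channel < self.n_channels:
                raise ValueError(
                    f"ictal component channel {comp.channel} out of range "
                    f"for {self.n_channels} channels"
                )

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)

    def channel_names(self) -> list[str]:
        if self.n_channels == 21:
            return list(CHB_STYLE_21)
        if self.n_channels == 18:
            return list(DOUBLE_BANANA_18)
        if self.n_channels <= len(CHB_STYLE_21):
            return list(CHB_STYLE_21[: self.n_channels])
        return [f"CH{i}" for i in range(self.n_channels)]


@dataclass
class Recording:
    """Multichannel signal in microvolts with seizure annotations.

    ``seizures`` holds half-open ``(start_s, end_s)`` intervals, ordered
    and non-overlapping, mirroring the metadata files that accompany the
    public scalp-EEG seizure databases.
    """

    data: np.ndarray              # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    seizures: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        dur = self.data.shape[1] / self.fs
        prev_end = 0.0
        for start, end in self.seizures:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(f"seizure ({start}, {end}) outside record")
            if start < prev_end:
                raise ValueError("seizure intervals overlap or are unordered")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


class SeizurePlacementError(ValueError):
    """Requested seizures cannot fit into the recording."""


def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS noise with a 1/f**exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _place_seizures(
    rng: np.random.Generator, config: SynthConfig
) -> list[tuple[float, float]]:
    """Uniform-random non-overlapping placement with a minimum gap.

    Lengths are drawn first; onsets are then sampled by the classic
    spacings construction (distribute the slack uniformly), which is exact
    and cannot live-lock.
    """
    if config.n_seizures == 0:
        return []
    lengths = config.seizure_duration + rng.uniform(
        -config.seizure_jitter, config.seizure_jitter, size=config.n_seizures
    )
    lengths = np.clip(lengths, 2.0 / config.fs, None)
    # margin at both ends so no seizure touches the record edge
    occupied = float(np.sum(lengths)) + config.min_gap * (config.n_seizures + 1)
    slack = config.duration - occupied
    if slack < 0:
        raise SeizurePlacementError(
            f"{config.n_seizures} seizures totalling {np.sum(lengths):.0f}s "
            f"plus gaps do not fit into {config.duration:.0f}s"
        )
    cuts = np.sort(rng.uniform(0.0, slack, size=config.n_seizures))
    intervals = []
    cursor = config.min_gap
    prev_cut = 0.0
    for i in range(config.n_seizures):
        cursor += cuts[i] - prev_cut
        prev_cut = cuts[i]
        start = cursor
        end = start + float(lengths[i])
        intervals.append((float(start), float(end)))
        cursor = end + config.min_gap
    return intervals


def generate_recording(config: SynthConfig) -> Recording:
    """Generate a seeded annotated recording.

    Background on every channel is independent 1/f noise plus a low
    amplitude alpha oscillation (random phase per channel).  Inside each
    annotated interval the channels named in ``config.ictal_spec`` receive
    an additional rhythm at the stated frequency, amplitude-modulated by a
    raised-cosine ramp over the first and last 10% of the seizure so onsets
    are not step discontinuities.  Identical config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.fs
    bg = config.background

    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        noise = _colored_noise(rng, n, bg.noise_exponent) * bg.noise_amplitude
        phase = rng.uniform(0, 2 * np.pi)
        data[ch] = noise + bg.alpha_amplitude * np.sin(
            2 * np.pi * bg.alpha_freq_hz * t + phase
        )

    seizures = _place_seizures(rng, config)
    for start, end in seizures:
        i0, i1 = round(start * config.fs), round(end * config.fs)
        seg_t = t[i0:i1]
        m = len(seg_t)
        envelope = np.ones(m)
        ramp = max(1, int(0.1 * m))
        window = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        envelope[:ramp] = window
        envelope[m - ramp:] = window[::-1]
        for comp in config.ictal_spec:
            phase = rng.uniform(0, 2 * np.pi)
            amp = comp.amplitude_gain * bg.alpha_amplitude
            data[comp.channel, i0:i1] += (
                amp * envelope * np.sin(2 * np.pi * comp.freq_hz * seg_t + phase)
            )

    return Recording(
        data=data,
        fs=config.fs,
        channel_names=config.channel_names(),
        seizures=seizures,
    )


def ground_truth_features(
    config: SynthConfig, feature_set: str = "FS1"
) -> set[str]:
    """Names of features expected discriminative under ``config.ictal_spec``.

    A planted rhythm raises amplitude in its own band and in the complete
    (0.5-30 Hz) band on its channel, so the amplitude-sensitive metrics of
    those band/channel pairs are returned, in the ``band_channel_metric``
    naming convention used by the feature stage.
    """
    metrics = AMPLITUDE_METRICS[feature_set]
    names = config.channel_names()
    out: set[str] = set()
    for comp in config.ictal_spec:
        ch = names[comp.channel]
        for band in (comp.band, "complete"):
            for metric in metrics:
                out.add(f"{band}_{ch}_{metric}")
    return out
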