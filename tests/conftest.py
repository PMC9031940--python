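"""Shared fixtures: a small planted synthetic study reused across tests.

The recording is desk-scale (4 bipolar channels, 10 minutes, 4 seizures)
but keeps the study's structural conditions: 256 Hz sampling, 2-s epochs
with 50% ictal overlap, at most 9:1 class imbalance, five sub-bands, and
one genuinely discriminative channel/band (a 6 Hz theta rhythm planted on
channel 0).
"""

from __future__ import annotations

import numpy as np
import pytest

import ictalsel as s
from ictalsel.synth import IctalComponent


@pytest.fixture(scope="session")
def planted_config() -> s.SynthConfig:
    return s.SynthConfig(
        n_channels=4,
        duration=600.0,
        n_seizures=4,
        seizure_duration=30.0,
        seizure_jitter=5.0,
        ictal_spec=(
            IctalComponent(channel=0, band="theta", amplitude_gain=4.0, freq_hz=6.0),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_recording(planted_config) -> s.Recording:
    return s.generate_recording(planted_config)


@pytest.fixture(scope="session")
def planted_epochs(planted_recording) -> s.EpochSet:
    filtered = s.filter_recording(planted_recording)
    epochs = s.rebalance(s.segment(filtered))
    return s.band_decompose(epochs)


@pytest.fixture(scope="session")
def planted_features(planted_epochs) -> s.FeatureMatrix:
    fm = s.extract_features(planted_epochs)
    pruned, _ = s.prune_correlated(fm)
    return pruned


@pytest.fixture(scope="session")
def planted_ground_truth(planted_config, planted_features) -> set[str]:
    gt = s.ground_truth_features(planted_config, "FS1")
    surviving = gt & set(planted_features.feature_names)
    assert surviving, "pruning removed every ground-truth feature"
    return surviving


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
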