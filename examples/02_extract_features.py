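"""Preprocess a recording into labeled epochs and a named feature matrix.

Pipeline: 0.5 Hz high-pass + notch -> 2-s epochs (ictal ones with 50%
overlap, non-ictal tiled) -> subsample non-ictal epochs to at most 9:1 ->
five Butterworth sub-bands -> 8 metrics per channel and band -> prune
feature pairs with |Pearson r| > 0.95.
"""

from ictalsel import (
    SynthConfig, band_decompose, extract_features, filter_recording,
    generate_recording, prune_correlated, rebalance, segment,
)
from ictalsel.synth import IctalComponent

config = SynthConfig(
    n_channels=4, duration=300.0, n_seizures=3, seizure_duration=25.0,
    seizure_jitter=5.0,
    ictal_spec=(IctalComponent(0, "theta", 4.0, 6.0),), seed=42,
)
recording = generate_recording(config)
filtered = filter_recording(recording)
epochs = rebalance(segment(filtered))
epochs = band_decompose(epochs)
print(f"epochs   : {epochs.n_epochs} ({int(epochs.labels.sum())} ictal, "
      f"ratio 1:{(epochs.labels == 0).sum() / epochs.labels.sum():.1f})")

fm = extract_features(epochs)                       # FS1 metrics
print(f"features : {fm.n_features} columns "
      f"({len(epochs.band_names)} bands x {len(epochs.channel_names)} channels x 8 metrics)")

pruned, audit = prune_correlated(fm)
dropped = [a for a in audit if a.reason == "correlated"]
print(f"pruned   : {len(dropped)} correlated columns removed -> {pruned.n_features} kept")
print(f"example  : dropped {dropped[0].name!r} (r={dropped[0].r:.3f} with {dropped[0].partner!r})")
# Each surviving column is named band_channel_metric, e.g. theta_FP1-F7_var:
# the variance of the theta-band signal on bipolar channel FP1-F7.
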