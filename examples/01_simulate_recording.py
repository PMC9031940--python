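"""Generate a seeded annotated synthetic EEG recording and persist it.

The recording mimics the gross statistics of long-term scalp EEG used for
seizure detection: 256 Hz sampling, bipolar channel names, 1/f background
with an alpha oscillation, and a few annotated seizures expressing a
higher-amplitude 6 Hz theta rhythm on one channel.
"""

from pathlib import Path

from ictalsel import SynthConfig, generate_recording, write_recording
from ictalsel.synth import IctalComponent

config = SynthConfig(
    n_channels=4,
    duration=300.0,          # 5 minutes
    n_seizures=3,
    seizure_duration=25.0,
    seizure_jitter=5.0,
    ictal_spec=(IctalComponent(channel=0, band="theta",
                               amplitude_gain=4.0, freq_hz=6.0),),
    seed=42,
)
recording = generate_recording(config)

print(f"channels : {recording.channel_names}")
print(f"samples  : {recording.data.shape[1]} ({recording.duration:.0f} s at {recording.fs:.0f} Hz)")
print("seizures :")
for start, end in recording.seizures:
    print(f"  {start:7.2f} - {end:7.2f} s")

out = Path("scratch/example_recording")
out.parent.mkdir(exist_ok=True)
paths = write_recording(out, recording)
print(f"written  : {paths[0].name} + {paths[1].name}")
# The seizure intervals above are the ground-truth annotations every later
# stage (epoch labeling, ranking validation) is measured against.
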