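"""Recording persistence: delimited signal matrix + annotation sidecar.

A recording is stored as two plain-text files:

* ``<stem>.rec.csv`` — a small ``#``-prefixed header (fs, channel names)
  followed by a samples-by-channels delimited matrix;
* ``<stem>.seizures.tsv`` — one ``start_s<TAB>end_s`` seizure interval per
  line, mirroring the role of the metadata files that accompany the public
  scalp-EEG seizure databases.

An optional EDF hook reads real files through ``mne`` when that package is
available; it is a convenience, not a validated clinical-EDF reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .synth import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "read_annotations",
    "write_annotations",
    "load_external_recording",
    "RecordingParseError",
]


class RecordingParseError(ValueError):
    """A recording or annotation file could not be parsed."""


def _paths(stem: Path) -> tuple[Path, Path]:
    stem = Path(stem)
    return stem.with_suffix(".rec.csv"), stem.with_suffix(".seizures.tsv")


def write_annotations(path: Path, seizures: list[tuple[float, float]]) -> None:
    with open(path, "w") as fh:
        for start, end in seizures:
            fh.write(f"{start:.6f}\t{end:.6f}\n")


def read_annotations(path: Path) -> list[tuple[float, float]]:
    seizures: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RecordingParseError(
                    f"{path}:{lineno}: expected 'start_s<TAB>end_s', got {line!r}"
                )
            try:
                seizures.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise RecordingParseError(f"{path}:{lineno}: {exc}") from exc
    return seizures


def write_recording(stem: Path, recording: Recording) -> tuple[Path, Path]:
    """Persist signals and annotations; returns the two paths written."""
    rec_path, ann_path = _paths(stem)
    header = (
        f"# fs={recording.fs!r}\n"
        f"# channels={','.join(recording.channel_names)}\n"
    )
    with open(rec_path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, recording.data.T, fmt="%.6e", delimiter=",")
    write_annotations(ann_path, recording.seizures)
    return rec_path, ann_path


def read_recording(stem: Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    A missing annotation sidecar yields an empty seizure list with a
    warning; malformed headers raise :class:`RecordingParseError` with the
    offending line number.
    """
    rec_path, ann_path = _paths(stem)
    meta: dict[str, str] = {}
    with open(rec_path) as fh:
        for lineno in (1, 2):
            line = fh.readline().strip()
            if not line.startswith("#") or "=" not in line:
                raise RecordingParseError(
                    f"{rec_path}:{lineno}: expected '# key=value' header, got {line!r}"
                )
            key, value = line[1:].split("=", 1)
            meta[key.strip()] = value.strip()
        try:
            fs = float(meta["fs"])
            channels = meta["channels"].split(",")
        except (KeyError, ValueError) as exc:
            raise RecordingParseError(f"{rec_path}: bad header: {exc}") from exc
        try:
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise RecordingParseError(f"{rec_path}: bad data block: {exc}") from exc
    if data.size == 0 or data.shape[1] != len(channels):
        raise RecordingParseError(
            f"{rec_path}: data block truncated or column count does not "
            f"match {len(channels)} channels"
        )
    if ann_path.exists():
        seizures = read_annotations(ann_path)
    else:
        warnings.warn(f"no annotation sidecar at {ann_path}; assuming seizure-free")
        seizures = []
    return Recording(
        data=data.T, fs=fs, channel_names=channels, seizures=seizures
    )


def load_external_recording(path: Path, fmt: str = "native") -> Recording:
    """Load a recording in the package's native format or EDF.

    ``fmt='native'`` expects the ``.rec.csv``/``.seizures.tsv`` pair (pass
    the stem or either file).  ``fmt='edf'`` reads signals through mne and
    annotations from a ``<stem>.seizures.tsv`` sidecar if present.
    """
    path = Path(path)
    if fmt == "native":
        stem = path
        for suffix in (".csv", ".rec", ".tsv", ".seizures"):
            if stem.suffix == suffix:
                stem = stem.with_suffix("")
        return read_recording(stem)
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        ann_path = path.with_suffix(".seizures.tsv")
        if ann_path.exists():
            seizures = read_annotations(ann_path)
        else:
            warnings.warn(f"no annotation sidecar at {ann_path}; assuming seizure-free")
            seizures = []
        return Recording(
            data=raw.get_data() * 1e6,   # volts -> microvolts
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
            seizures=seizures,
        )
    raise ValueError(f"unknown format {fmt!r} (use 'native' or 'edf')")
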