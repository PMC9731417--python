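"""Recording and artifact I/O.

Heart-sound recordings enter as mono PCM WAV files and are resampled to the
pipeline rate of 2205 Hz (polyphase rational resampling with anti-aliasing),
then amplitude-normalised to max |x| = 1 so downstream amplitude-dependent
features do not reflect recording gain.  Datasets are described by a
two-column manifest (path, label); extracted features travel as CSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import DegenerateSignalError

__all__ = [
    "PIPELINE_FS",
    "PCGRecord",
    "DatasetManifest",
    "load_record",
    "save_record",
    "read_manifest",
    "write_manifest",
    "write_feature_table",
    "read_feature_table",
]

log = logging.getLogger(__name__)

PIPELINE_FS = 2205  # Hz; every recording is resampled to this rate on ingestion


@dataclass
class PCGRecord:
    """One labelled heart-sound recording at a fixed sample rate."""

    id: str
    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise DegenerateSignalError("non-finite samples")
        if self.samples.size < max(2, int(2 * self.fs / 1000)):
            raise DegenerateSignalError("recording too short")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DatasetManifest:
    """Paths and labels for one dataset, with a fixed class ordering."""

    entries: list[tuple[str, str]]
    class_names: list[str]

    def __post_init__(self) -> None:
        paths = [p for p, _ in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")
        bad = {lab for _, lab in self.entries} - set(self.class_names)
        if bad:
            raise ValueError(f"labels outside class_names: {sorted(bad)}")


def _to_float(data: np.ndarray) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(float) / float(np.iinfo(data.dtype).max)
    return data.astype(float)


def load_record(path, target_fs: float = PIPELINE_FS, label: str = "",
                normalize: bool = True) -> PCGRecord:
    """Read a WAV file, average to mono, resample, optionally normalise."""
    path = Path(path)
    orig_fs, data = wavfile.read(path)
    if data.size == 0:
        raise OSError(f"empty audio file: {path}")
    x = _to_float(np.asarray(data))
    if x.ndim == 2:
        x = x.mean(axis=1)
    if np.max(np.abs(x)) == 0:
        raise DegenerateSignalError(f"zero-amplitude signal: {path}")
    if orig_fs != target_fs:
        frac = Fraction(int(target_fs), int(orig_fs))
        x = resample_poly(x, frac.numerator, frac.denominator)
        log.info("resampled %s from %d Hz to %d Hz", path.name, orig_fs, target_fs)
    if normalize:
        x = x / np.max(np.abs(x))
    return PCGRecord(id=path.stem, samples=x, fs=float(target_fs), label=label)


def save_record(record: PCGRecord, path) -> None:
    """Write a record as 16-bit PCM WAV (amplitudes clipped to [-1, 1])."""
    x = np.clip(record.samples, -1.0, 1.0)
    wavfile.write(path, int(record.fs), (x * 32767).astype(np.int16))


def read_manifest(path) -> DatasetManifest:
    """Two-column delimited text (path <TAB> label), UTF-8."""
    entries = []
    base = Path(path).parent
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p, lab = line.split("\t")
        p = p if Path(p).is_absolute() else str(base / p)
        entries.append((p, lab))
    class_names = sorted({lab for _, lab in entries})
    return DatasetManifest(entries=entries, class_names=class_names)


def write_manifest(manifest: DatasetManifest, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p, lab in manifest.entries:
            fh.write(f"{p}\t{lab}\n")


def write_feature_table(vectors, path, ids=None, labels=None) -> None:
    """Write feature vectors as CSV: id, label, then one column per feature.

    ``vectors`` is a sequence of mappings with identical key ordering (the
    Table-1 feature order); values round-trip to 12 significant digits.
    """
    vectors = list(vectors)
    if vectors:
        names = list(vectors[0].keys())
        for v in vectors[1:]:
            if list(v.keys()) != names:
                raise ValueError("inconsistent feature-name orderings")
    else:
        from .features import FEATURE_NAMES
        names = list(FEATURE_NAMES)
    n = len(vectors)
    df = pd.DataFrame([list(v.values()) for v in vectors], columns=names)
    df.insert(0, "label", list(labels) if labels is not None else [""] * n)
    df.insert(0, "id", list(ids) if ids is not None else [str(i) for i in range(n)])
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    return pd.read_csv(path, dtype={"id": str, "label": str})
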