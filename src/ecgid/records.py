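"""Single-lead ECG record container and plain-text serialization.

Amplitudes are in millivolts, sampling rates in Hz, indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class EcgRecord:
    """A single-lead ECG time series.

    Parameters
    ----------
    samples : array-like
        Signal amplitudes in mV.
    fs : float
        Sampling rate in Hz (> 0).
    subject_id : str
        Opaque subject label.
    lead : str
        Lead tag, e.g. ``"MLII"``.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    lead: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("an ECG record needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs


def write_text(rec: EcgRecord, path: str | Path) -> None:
    """Write a record as a columnar text file: a small ``# key: value``
    header followed by one sample (mV) per line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs: {rec.fs!r}\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# lead: {rec.lead}\n")
        for v in rec.samples:
            fh.write(f"{v:.9g}\n")


def read_text(path: str | Path) -> EcgRecord:
    """Read a record written by :func:`write_text`."""
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                values.append(float(line))
    if "fs" not in meta:
        raise ValueError(f"{path}: missing 'fs' header line")
    return EcgRecord(
        samples=np.asarray(values),
        fs=float(meta["fs"]),
        subject_id=meta.get("subject_id", ""),
        lead=meta.get("lead", ""),
    )
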