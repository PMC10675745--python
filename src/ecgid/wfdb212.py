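"""Minimal WFDB reader/writer for format-212 records.

Supports the subset of the WFDB specification used by Holter archives such
as the European ST-T database: a ``.hea`` header naming the signals plus a
``.dat`` file with pairs of 12-bit two's-complement samples packed into
3 bytes. Amplitudes are converted to mV via each signal's gain/baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .records import EcgRecord

_ADC_MAX = 2047
_ADC_MIN = -2048


@dataclass
class _SignalSpec:
    filename: str
    fmt: str
    gain: float  # adc units per mV
    baseline: int
    description: str  # lead name


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[_SignalSpec]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fname, fmt = f[0], f[1]
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part[:-1].split("(")
            gain = float(gain_str)
            baseline = int(base_str)
        else:
            gain = float(gain_part)
            # adc zero is field 4 when present
            baseline = int(f[4]) if len(f) > 4 else 0
        if gain == 0:
            gain = 200.0  # WFDB convention for unspecified gain
        desc = " ".join(f[8:]) if len(f) > 8 else f"sig{len(specs)}"
        specs.append(_SignalSpec(fname, fmt, gain, baseline, desc))
    return name, nsig, fs, nsamp, specs


def _unpack_212(raw: bytes, nsig: int) -> np.ndarray:
    """Decode format-212 bytes into an (nsamples, nsig) int array."""
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: 3 * (b.size // 3)]
    b0 = b[0::3].astype(np.int32)
    b1 = b[1::3].astype(np.int32)
    b2 = b[2::3].astype(np.int32)
    first = ((b1 & 0x0F) << 8) | b0
    second = ((b1 & 0xF0) << 4) | b2
    out = np.empty(first.size + second.size, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > _ADC_MAX] -= 4096  # 12-bit two's complement
    n = out.size // nsig
    return out[: n * nsig].reshape(n, nsig)


def _pack_212(frames: np.ndarray) -> bytes:
    flat = frames.reshape(-1).astype(np.int32)
    if flat.min() < _ADC_MIN or flat.max() > _ADC_MAX:
        raise ValueError("sample out of 12-bit range for format 212")
    if flat.size % 2:
        flat = np.concatenate([flat, [0]])
    flat = np.where(flat < 0, flat + 4096, flat)
    a, b = flat[0::2], flat[1::2]
    out = np.empty(3 * a.size, dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[2::3] = b & 0xFF
    return out.tobytes()


def read_wfdb_record(path: str | Path, lead: str) -> EcgRecord:
    """Read one lead of a WFDB record pair (``<path>.hea`` + ``.dat``).

    Parameters
    ----------
    path
        Record path without extension.
    lead
        Signal description to extract (e.g. ``"MLII"``).

    Returns
    -------
    EcgRecord
        Samples in mV at the record's native sampling rate.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header at {hea}")
    name, nsig, fs, nsamp, specs = _parse_header(hea)
    leads = [s.description for s in specs]
    if lead not in leads:
        raise KeyError(f"lead {lead!r} not in record {name}; available: {leads}")
    idx = leads.index(lead)
    spec = specs[idx]
    if spec.fmt != "212":
        raise ValueError(f"unsupported WFDB signal format {spec.fmt!r} (only 212)")
    dat = path.parent / spec.filename
    if not dat.exists():
        raise FileNotFoundError(f"no WFDB signal file at {dat}")
    frames = _unpack_212(dat.read_bytes(), nsig)
    if nsamp:
        frames = frames[:nsamp]
    mv = (frames[:, idx] - spec.baseline) / spec.gain
    return EcgRecord(samples=mv, fs=fs, subject_id=name, lead=lead)


def write_wfdb_record(
    path: str | Path,
    signals: dict[str, np.ndarray],
    fs: float,
    gain: float = 200.0,
    baseline: int = 0,
) -> None:
    """Write signals (mV, equal length) as a WFDB format-212 record pair.

    Intended for fixtures and for exporting synthetic cohorts in a form
    other WFDB tools can read.
    """
    path = Path(path)
    names = list(signals)
    arrays = [np.asarray(signals[k], dtype=float) for k in names]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all leads must have the same length")
    digital = np.rint(np.stack(arrays, axis=1) * gain).astype(np.int32) + baseline
    frames = digital.reshape(n, len(names))
    (path.parent).mkdir(parents=True, exist_ok=True)
    dat_name = path.name + ".dat"
    with path.with_suffix(".hea").open("w") as fh:
        fh.write(f"{path.name} {len(names)} {fs:g} {n}\n")
        for i, lead in enumerate(names):
            fh.write(f"{dat_name} 212 {gain:g}({baseline})/mV 12 0 0 0 0 {lead}\n")
    path.with_suffix(".dat").write_bytes(_pack_212(frames))
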