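"""Wavelet decomposition, soft-threshold denoising and feature-band
reconstruction.

The ECG is decomposed with an 8-level db4 Mallat cascade. At 250 Hz the
detail bands cover, dyadically: d1 ≈ 62.5–125 Hz, d2 ≈ 31.25–62.5 Hz, ...
d8 ≈ 0.49–0.98 Hz, with a8 below 0.49 Hz. The QRS complex concentrates its
energy roughly in 0.25–45 Hz, so the default configuration drops d1
(high-frequency noise) and a8 (baseline wander) and soft-thresholds the
retained detail bands before reconstructing the feature-bearing signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .records import EcgRecord

BAND_LABELS = tuple(f"d{i}" for i in range(1, 9)) + ("a8",)


@dataclass
class WaveletDecomposition:
    """Coefficients of a multi-level DWT of one record.

    ``details[0]`` is the finest detail band (d1), ``details[-1]`` the
    coarsest (d8 for an 8-level transform); ``approx`` is the deepest
    approximation band. Record provenance (fs, subject, lead) is carried
    along so reconstruction returns a full record.
    """

    approx: np.ndarray
    details: list[np.ndarray]  # index 0 = finest (d1)
    wavelet_name: str
    original_length: int
    mode: str = "symmetric"
    fs: float = 250.0
    subject_id: str = ""
    lead: str = ""

    @property
    def levels(self) -> int:
        return len(self.details)

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            approx=self.approx.copy(),
            details=[d.copy() for d in self.details],
            wavelet_name=self.wavelet_name,
            original_length=self.original_length,
            mode=self.mode,
            fs=self.fs,
            subject_id=self.subject_id,
            lead=self.lead,
        )

    def band(self, label: str) -> np.ndarray:
        """Coefficient array for a band label (``d1``..``dL`` or ``a<L>``)."""
        if label == f"a{self.levels}":
            return self.approx
        if label.startswith("d"):
            lvl = int(label[1:])
            if 1 <= lvl <= self.levels:
                return self.details[lvl - 1]
        raise KeyError(
            f"unknown band {label!r}; valid: "
            f"{[f'd{i}' for i in range(1, self.levels + 1)] + [f'a{self.levels}']}"
        )


def soft_threshold(coeffs: np.ndarray, lam: float) -> np.ndarray:
    """Soft shrinkage ``sign(x) * max(|x| - lam, 0)``."""
    if lam < 0:
        raise ValueError("threshold must be non-negative")
    coeffs = np.asarray(coeffs, dtype=float)
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - lam, 0.0)


def decompose(
    rec: EcgRecord,
    levels: int = 8,
    wavelet: str = "db4",
    mode: str = "symmetric",
) -> WaveletDecomposition:
    """Multi-level DWT (Mallat cascade: filter + downsample per level).

    Raises a ``ValueError`` naming the maximum feasible depth when the
    signal is too short for the requested number of levels.
    """
    x = rec.samples
    if x.size < 2**levels:
        max_depth = int(np.floor(np.log2(x.size)))
        raise ValueError(
            f"signal of length {x.size} too short for {levels} levels; "
            f"at most {max_depth} feasible"
        )
    with warnings.catch_warnings():
        # pywt warns when levels exceeds its conservative max; perfect
        # reconstruction still holds, which is what we rely on.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode=mode, level=levels)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # finest first
    return WaveletDecomposition(
        approx=approx,
        details=details,
        wavelet_name=wavelet,
        original_length=x.size,
        mode=mode,
        fs=rec.fs,
        subject_id=rec.subject_id,
        lead=rec.lead,
    )


def estimate_noise_sigma(dec: WaveletDecomposition) -> float:
    """Robust noise estimate from the finest detail band:
    ``median(|d1|) / 0.6745``."""
    return float(np.median(np.abs(dec.details[0])) / 0.6745)


def denoise_and_select(
    dec: WaveletDecomposition,
    drop_levels: set[str] | frozenset[str] = frozenset({"d1", "a8"}),
    lam_rule: str = "universal",
) -> WaveletDecomposition:
    """Zero the dropped bands and soft-threshold the retained detail bands.

    ``lam_rule="universal"`` uses the universal threshold
    ``sigma_hat * sqrt(2 ln N)`` with sigma estimated from the (original)
    finest detail band; ``"none"`` applies no shrinkage. The approximation
    band is never thresholded, only dropped or kept.
    """
    valid = {f"d{i}" for i in range(1, dec.levels + 1)} | {f"a{dec.levels}"}
    unknown = set(drop_levels) - valid
    if unknown:
        raise KeyError(f"unknown band labels {sorted(unknown)}; valid: {sorted(valid)}")
    if lam_rule == "universal":
        sigma = estimate_noise_sigma(dec)
        lam = sigma * np.sqrt(2.0 * np.log(dec.original_length))
    elif lam_rule == "none":
        lam = 0.0
    else:
        raise ValueError(f"unknown lam_rule {lam_rule!r} (use 'universal' or 'none')")

    out = dec.copy()
    if f"a{dec.levels}" in drop_levels:
        out.approx = np.zeros_like(out.approx)
    for i in range(dec.levels):
        label = f"d{i + 1}"
        if label in drop_levels:
            out.details[i] = np.zeros_like(out.details[i])
        elif lam > 0:
            out.details[i] = soft_threshold(out.details[i], lam)
    return out


def reconstruct(dec: WaveletDecomposition) -> EcgRecord:
    """Inverse cascade (upsample by zero-insertion, filter, sum), trimmed
    to the original signal length."""
    coeffs = [dec.approx] + list(reversed(dec.details))
    try:
        x = pywt.waverec(coeffs, dec.wavelet_name, mode=dec.mode)
    except ValueError as exc:
        raise ValueError(f"inconsistent coefficient shapes: {exc}") from exc
    x = x[: dec.original_length]
    if x.size != dec.original_length:
        raise ValueError(
            f"reconstruction length {x.size} != original {dec.original_length}"
        )
    return EcgRecord(
        samples=x, fs=dec.fs, subject_id=dec.subject_id, lead=dec.lead
    )


def denoise_record(
    rec: EcgRecord,
    levels: int = 8,
    wavelet: str = "db4",
    drop_bands: set[str] | frozenset[str] = frozenset({"d1", "a8"}),
    lam_rule: str = "universal",
    mode: str = "symmetric",
) -> EcgRecord:
    """Convenience: decompose, drop/threshold bands, reconstruct."""
    dec = decompose(rec, levels=levels, wavelet=wavelet, mode=mode)
    return reconstruct(denoise_and_select(dec, drop_bands, lam_rule))
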