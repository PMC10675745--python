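"""Adaptive dual-threshold R-peak detection (Pan–Tompkins lineage).

Pipeline: band-pass (5–15 Hz) → 5-point derivative → squaring →
moving-window integration (150 ms) → candidate peaks → adaptive
signal/noise thresholds with search-back. The second threshold is always
half the first. Detections are refined to the QRS extremum and a 200 ms
refractory period is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import EcgRecord


@dataclass
class DetectorConfig:
    bandpass_low: float = 5.0
    bandpass_high: float = 15.0
    integration_window: float = 0.15  # s
    refractory: float = 0.2  # s
    square: bool = True  # |derivative| if False
    refine_window: float = 0.05  # s, argmax search around integrated peak
    searchback_factor: float = 1.66  # multiples of running RR


@dataclass
class RPeakList:
    """Ascending R-peak sample indices with their sampling rate."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    def rr_intervals(self) -> np.ndarray:
        """RR intervals in seconds."""
        return np.diff(self.indices) / self.fs


@dataclass
class MatchStats:
    """Greedy one-to-one matching statistics for detector evaluation."""

    n_truth: int
    n_detected: int
    n_matched: int
    sensitivity: float
    ppv: float
    f1: float


def _transform(x: np.ndarray, fs: float, cfg: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (band-passed signal, integrated detection waveform)."""
    nyq = fs / 2.0
    sos = sps.butter(
        2, [cfg.bandpass_low / nyq, cfg.bandpass_high / nyq], btype="bandpass", output="sos"
    )
    bp = sps.sosfiltfilt(sos, x)
    # 5-point derivative, zero-centered so no group delay
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    energy = deriv**2 if cfg.square else np.abs(deriv)
    w = max(1, int(round(cfg.integration_window * fs)))
    integ = np.convolve(energy, np.ones(w) / w, mode="same")
    return bp, integ


def detect_rpeaks(
    rec: EcgRecord,
    config: DetectorConfig | None = None,
    return_trace: bool = False,
):
    """Detect R peaks with adaptive dual thresholds.

    The running signal estimate SPK and noise estimate NPK are updated as
    ``SPK <- 0.125*peak + 0.875*SPK`` when a candidate exceeds T1 and
    ``NPK <- 0.125*peak + 0.875*NPK`` otherwise, with
    ``T1 = NPK + 0.25*(SPK - NPK)`` and ``T2 = T1/2``. If no peak exceeds
    T1 within 1.66x the running RR estimate, the largest skipped candidate
    above T2 is accepted (search-back). Accepted detections are refined to
    the band-passed-magnitude argmax within ±50 ms, then snapped to the
    signal-magnitude argmax within ±16 ms (the canonical R index).

    With ``return_trace=True`` also returns the list of ``(T1, T2)``
    threshold pairs applied at each candidate decision.
    """
    cfg = config or DetectorConfig()
    fs = rec.fs
    if fs < 100:
        raise ValueError("detector requires fs >= 100 Hz")
    x = rec.samples
    if x.size < int(2 * fs):
        raise ValueError("detector requires at least 2 s of signal")

    bp, integ = _transform(x, fs, cfg)
    refractory = int(round(cfg.refractory * fs))
    trace: list[tuple[float, float]] = []

    learn = integ[: int(2 * fs)]
    if learn.max() <= 0:
        peaks = RPeakList(np.array([], dtype=int), fs)
        return (peaks, trace) if return_trace else peaks

    cand, _ = sps.find_peaks(integ, distance=refractory)
    spk = 0.5 * float(learn.max())
    npk = 0.5 * float(learn.mean())

    accepted: list[int] = []
    skipped: list[tuple[int, float]] = []
    rr_hist: list[float] = []

    def rr_avg() -> float | None:
        if not rr_hist:
            return None
        return float(np.mean(rr_hist[-8:]))

    for p in cand:
        h = float(integ[p])
        t1 = npk + 0.25 * (spk - npk)
        t2 = 0.5 * t1
        trace.append((t1, t2))
        if h > t1 and (not accepted or p - accepted[-1] >= refractory):
            if accepted:
                rr_hist.append(p - accepted[-1])
            accepted.append(p)
            spk = 0.125 * h + 0.875 * spk
        else:
            skipped.append((p, h))
            npk = 0.125 * h + 0.875 * npk
            # search-back: overdue for a beat?
            ra = rr_avg()
            if accepted and ra is not None and (p - accepted[-1]) > cfg.searchback_factor * ra:
                window = [
                    (q, hq)
                    for q, hq in skipped
                    if accepted[-1] + refractory <= q <= p and hq > t2
                ]
                if window:
                    q, hq = max(window, key=lambda it: it[1])
                    rr_hist.append(q - accepted[-1])
                    accepted.append(q)
                    accepted.sort()
                    spk = 0.25 * hq + 0.75 * spk
                    skipped = [(s, hs) for s, hs in skipped if s != q]

    # refine to QRS extremum
    r1 = int(round(cfg.refine_window * fs))
    r2 = int(round(0.016 * fs))
    refined: list[int] = []
    for p in accepted:
        lo, hi = max(0, p - r1), min(x.size, p + r1 + 1)
        q = lo + int(np.argmax(np.abs(bp[lo:hi])))
        lo2, hi2 = max(0, q - r2), min(x.size, q + r2 + 1)
        refined.append(lo2 + int(np.argmax(np.abs(x[lo2:hi2]))))

    # enforce strict ordering + refractory after refinement
    refined.sort()
    final: list[int] = []
    for r in refined:
        if final and r - final[-1] < refractory:
            if np.abs(x[r]) > np.abs(x[final[-1]]):
                final[-1] = r
        else:
            final.append(r)

    peaks = RPeakList(np.asarray(final, dtype=int), fs)
    return (peaks, trace) if return_trace else peaks


def rpeak_f1(
    detected: RPeakList, truth: np.ndarray, tol: float = 0.05
) -> MatchStats:
    """Greedy one-to-one matching of detections to ground truth within
    ``tol`` seconds; returns sensitivity, positive predictivity and F1."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    truth = np.asarray(truth, dtype=int)
    det = detected.indices
    tol_samp = tol * detected.fs
    n_matched = 0
    i = j = 0
    while i < det.size and j < truth.size:
        d = det[i] - truth[j]
        if abs(d) <= tol_samp:
            n_matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    sens = n_matched / truth.size if truth.size else 0.0
    ppv = n_matched / det.size if det.size else 0.0
    f1 = 2 * sens * ppv / (sens + ppv) if (sens + ppv) > 0 else 0.0
    return MatchStats(truth.size, det.size, n_matched, sens, ppv, f1)
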