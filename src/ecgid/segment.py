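"""R-R-R segmentation, resampling and L2 standardization.

A window spans three consecutive R peaks (two full cardiac cycles),
expanded by a fixed number of samples at both ends so the edge R waves
are fully contained. Each window is resampled to a fixed length D by
linear interpolation and divided by its L2 norm; groups of three
consecutive standardized windows form one D x 3 segment matrix, the unit
the sparse coder consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import EcgRecord
from .rpeak import RPeakList

logger = logging.getLogger(__name__)


@dataclass
class SegmentMatrix:
    """Column-stacked standardized local segments (each column unit L2)."""

    columns: np.ndarray  # (D, n)
    subject_id: str = ""
    source_windows: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] < 1:
            raise ValueError("columns must be a D x n array with n >= 1")
        norms = np.linalg.norm(self.columns, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("every column must have unit L2 norm")

    @property
    def D(self) -> int:
        return self.columns.shape[0]

    @property
    def n(self) -> int:
        return self.columns.shape[1]


def make_rrr_windows(
    rec: EcgRecord,
    peaks: RPeakList,
    expand: int = 20,
    stride: int = 1,
) -> list[tuple[int, int]]:
    """Half-open ``[start, stop)`` windows over runs of three consecutive
    R peaks, expanded by ``expand`` samples at both ends and clipped to
    the signal bounds. Windows advance by ``stride`` peaks."""
    if expand < 0:
        raise ValueError("expand must be non-negative")
    if stride < 1:
        raise ValueError("stride must be at least 1")
    idx = peaks.indices
    if idx.size < 3:
        raise ValueError("need at least 3 R peaks to build an R-R-R window")
    n = len(rec)
    windows = []
    for i in range(0, idx.size - 2, stride):
        start = max(0, int(idx[i]) - expand)
        stop = min(n, int(idx[i + 2]) + expand + 1)
        windows.append((start, stop))
    return windows


def standardize_window(
    rec: EcgRecord, window: tuple[int, int], D: int = 400
) -> np.ndarray:
    """Resample a window to exactly ``D`` samples (linear interpolation on
    a uniform grid) and scale it to unit L2 norm."""
    start, stop = window
    if stop - start < 2:
        raise ValueError("window must contain at least 2 samples")
    if D < 2:
        raise ValueError("target length D must be at least 2")
    seg = rec.samples[start:stop]
    grid = np.linspace(0.0, seg.size - 1, D)
    out = np.interp(grid, np.arange(seg.size), seg)
    norm = np.linalg.norm(out)
    if norm == 0:
        raise ValueError("cannot standardize an all-zero window")
    return out / norm


def split_window_thirds(
    rec: EcgRecord, window: tuple[int, int], D: int = 400
) -> np.ndarray:
    """Alternative reading of 'evenly divided into three segments': the
    window is resampled to 3*D samples, split into thirds, and each third
    standardized to unit norm. Returns a (D, 3) array."""
    long = standardize_window(rec, window, 3 * D)
    cols = long.reshape(3, D).T
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot standardize an all-zero third")
    return cols / norms


def group_segments(
    segments: list[np.ndarray],
    group_size: int = 3,
    subject_id: str = "",
    source_windows: list[tuple[int, int]] | None = None,
) -> list[SegmentMatrix]:
    """Stack consecutive non-overlapping groups of ``group_size`` unit
    vectors into SegmentMatrix objects; a trailing partial group is
    dropped."""
    if group_size < 1:
        raise ValueError("group_size must be at least 1")
    n_groups = len(segments) // group_size
    if n_groups == 0:
        logger.warning(
            "only %d segments for group_size %d: no matrices produced",
            len(segments),
            group_size,
        )
        return []
    out = []
    for g in range(n_groups):
        cols = np.column_stack(segments[g * group_size : (g + 1) * group_size])
        wins = (
            source_windows[g * group_size : (g + 1) * group_size]
            if source_windows
            else None
        )
        out.append(SegmentMatrix(columns=cols, subject_id=subject_id, source_windows=wins))
    return out


def segment_record(
    rec: EcgRecord,
    peaks: RPeakList,
    D: int = 400,
    expand: int = 20,
    stride: int = 1,
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Windows -> standardized unit vectors, skipping degenerate windows."""
    windows = make_rrr_windows(rec, peaks, expand=expand, stride=stride)
    vectors, kept = [], []
    for w in windows:
        try:
            vectors.append(standardize_window(rec, w, D))
            kept.append(w)
        except ValueError:
            logger.warning("skipping degenerate window %s", w)
    return vectors, kept
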