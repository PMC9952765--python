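"""Stage 3: short-time energy and active/rest segmentation.

The selected component series is squared and summed over a trailing window
(length N = 51 samples by default, rectangular weighting), yielding an
energy envelope E that is high while the motion is active and near zero at
rest.  A basic threshold at a fraction of max(E) separates the states;
above-threshold runs closer than one window length are merged and the
longest run is taken as the motion bout (each trial contains a single bout).

Packet-loss detection lives here too: a receiver experiencing dropouts logs
repeats of the previous CSI row, so flat runs of identical rows flag the
affected stretches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .recording import CSIRecording

logger = logging.getLogger(__name__)

WindowKind = Literal["rectangular", "hamming"]


@dataclass
class EnergySeries:
    """Trailing-window energy of a component series."""

    E: np.ndarray
    window_length: int
    window_kind: WindowKind = "rectangular"

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=np.float64)


@dataclass
class MotionSegment:
    """Half-open sample range [start_index, end_index) of the active state."""

    start_index: int
    end_index: int
    fs: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_index < self.end_index:
            raise ValueError("require 0 <= start < end")

    @property
    def duration_s(self) -> float:
        return (self.end_index - self.start_index) / self.fs

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def short_time_energy(
    series: np.ndarray, N: int = 51, window_kind: WindowKind = "rectangular"
) -> EnergySeries:
    """E_n = sum over the trailing window m in [n-N+1, n] of (x_m w_{n-m})^2.

    Windows are prefix-truncated at the start of the series (no padding), so
    E is defined for every sample.  N must be odd and no longer than the
    series.
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if N % 2 == 0 or N <= 1:
        raise ValueError("window length N must be odd and > 1")
    if N > x.size:
        raise ValueError(f"window length {N} exceeds series length {x.size}")
    if window_kind == "rectangular":
        w2 = np.ones(N)
    elif window_kind == "hamming":
        w2 = np.hamming(N) ** 2
    else:
        raise ValueError(f"unknown window kind {window_kind!r}")
    # (x_m w_{n-m})^2 = x_m^2 * w^2_{n-m}: a trailing convolution of x^2 with w^2
    E = np.convolve(x**2, w2, mode="full")[: x.size]
    return EnergySeries(E=np.maximum(E, 0.0), window_length=N, window_kind=window_kind)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    idx = np.nonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))[0]
    return list(zip(idx[0::2].tolist(), idx[1::2].tolist()))


def segment_active(
    energy: EnergySeries,
    threshold_frac: float = 0.1,
    fs: float = 1000.0,
    return_all: bool = False,
    merge_gap: int | None = None,
) -> MotionSegment | list[MotionSegment] | None:
    """Threshold the energy envelope and return the motion bout.

    The threshold is ``threshold_frac * max(E)``.  Above-threshold runs
    separated by gaps shorter than ``merge_gap`` samples are merged: the
    energy of an oscillation dips near every zero crossing (the trailing
    window straddles mostly small samples there), so brief dips within one
    bout are not bout boundaries.  ``merge_gap`` defaults to the energy
    window length; the pipeline passes one period of the slowest passband
    motion (fs / f_low), the longest dip a genuine bout can contain.  The
    longest merged run is returned; with ``return_all`` every merged run is,
    longest first.  If nothing exceeds the threshold the result is None —
    an empty segment, distinct from an error.
    """
    E = energy.E
    if np.all(E == 0):
        raise ValueError("energy is identically zero")
    if merge_gap is None:
        merge_gap = energy.window_length
    thr = threshold_frac * float(E.max())
    runs = _runs_above(E > thr)
    if not runs:
        return [] if return_all else None

    merged: list[tuple[int, int]] = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    segments = [MotionSegment(s, e, fs) for s, e in merged]
    segments.sort(key=lambda seg: (-seg.n_samples, seg.start_index))
    if return_all:
        return segments
    return segments[0]


def detect_packet_loss(
    rec: CSIRecording, min_run: int = 3
) -> list[tuple[int, int]]:
    """Flag maximal runs of >= min_run consecutive identical CSI rows.

    Returns half-open [start, end) time-step ranges.  Continuous-valued
    noise never repeats exactly, so flagged runs indicate receiver dropouts
    (repeat-logging of the last good value).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    T = rec.n_times
    if min_run == 1 and T == 1:
        return [(0, 1)]
    same_as_prev = np.all(rec.samples[1:] == rec.samples[:-1], axis=1)
    flagged: list[tuple[int, int]] = []
    for s, e in _runs_above(same_as_prev):
        run_len = e - s + 1  # identical rows, including the anchor row
        if run_len >= min_run:
            flagged.append((s, e + 1))
    frac = sum(e - s for s, e in flagged) / T
    if flagged:
        logger.info(
            "detect_packet_loss: %d run(s), %.2f%% of samples flagged",
            len(flagged),
            100 * frac,
        )
    return flagged
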