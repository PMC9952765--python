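"""Stage 4: smoothing, peak finding, and motion quantification.

The segmented component series is smoothed with a third-order Savitzky-Golay
filter (window 101 at the 1000 Hz CSI rate) to remove fake peaks, then wave
crests are counted under three criteria:

minimum separation
    floor(fs / f_max) samples, from the upper frequency of the motion type
    (10 Hz for tapping/ruler -> 100 samples, 6 Hz for tremor -> 166 samples
    at 1000 Hz).  Candidate peaks closer than this are resolved greedily in
    favour of the higher peak (ties keep the earlier index).
minimum height
    0.2 * max(Q): discards low crests from residual noise.
minimum prominence
    0.3 * max(Q), topographic prominence: a crest must stand out above the
    higher of its two flanking valleys.

The crest count is the movement count; the bout duration comes from the
segment length; the mean frequency uses the fencepost convention
(count - 1) / (time span between first and last crest).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .segmentation import MotionSegment

logger = logging.getLogger(__name__)


@dataclass
class PeakCriteria:
    """The three crest-acceptance criteria, derived from max(Q) and f_max."""

    f_max: float
    fs: float
    height_factor: float = 0.2
    prominence_factor: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.height_factor < 1 or not 0 < self.prominence_factor < 1:
            raise ValueError("height and prominence factors must lie in (0, 1)")
        if self.min_separation < 1:
            raise ValueError("f_max too high for fs: separation below one sample")

    @property
    def min_separation(self) -> int:
        """Minimum crest spacing in samples: floor(fs / f_max)."""
        return int(math.floor(self.fs / self.f_max))

    def min_height(self, Q: np.ndarray) -> float:
        return self.height_factor * float(np.max(Q))

    def min_prominence(self, Q: np.ndarray) -> float:
        return self.prominence_factor * float(np.max(Q))


@dataclass
class MotionQuantification:
    """Count, mean frequency and duration of one motion bout."""

    count: int
    mean_frequency: float
    duration: float
    peak_indices: np.ndarray
    peak_prominences: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "mean_frequency": self.mean_frequency,
            "duration": self.duration,
            "peak_indices": np.asarray(self.peak_indices).tolist(),
            "peak_prominences": np.asarray(self.peak_prominences).tolist(),
        }


def savgol_smooth(V_W: np.ndarray, order: int = 3, window: int = 101) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial of the given
    order over a sliding window; edges use a polynomial fit on the truncated
    window.  Exactly reproduces polynomials up to the filter order."""
    x = np.asarray(V_W, dtype=np.float64).ravel()
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than the polynomial order")
    if x.size < window:
        raise ValueError(
            f"segment of {x.size} samples is shorter than the smoothing window "
            f"{window}; use a smaller window"
        )
    return savgol_filter(x, window_length=window, polyorder=order, mode="interp")


def topographic_prominence(Q: np.ndarray, peak: int) -> float:
    """Height of Q[peak] above the higher of the two flanking key valleys.

    Walk outward from the peak until a strictly higher sample (or the signal
    edge) is met; the lowest point of each walk is that side's base, and the
    prominence is the crest height minus the higher base.
    """
    x = np.asarray(Q, dtype=np.float64)
    h = x[peak]
    left_base = x[: peak + 1].min()
    for i in range(peak - 1, -1, -1):
        if x[i] > h:
            left_base = x[i + 1 : peak + 1].min()
            break
    right_base = x[peak:].min()
    for i in range(peak + 1, x.size):
        if x[i] > h:
            right_base = x[peak : i].min()
            break
    return h - max(left_base, right_base)


def find_motion_peaks(Q: np.ndarray, criteria: PeakCriteria) -> np.ndarray:
    """Crest indices of Q satisfying all three acceptance criteria.

    Local maxima (plateaus count once, at their left edge) are filtered by
    minimum height and minimum topographic prominence; the separation
    constraint is then enforced greedily, keeping the highest surviving
    crest first (ties keep the earlier index) and discarding any candidate
    within ``min_separation`` samples of an accepted one.
    """
    x = np.asarray(Q, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if float(x.max()) <= 0:
        logger.warning("find_motion_peaks: max(Q) <= 0, returning no peaks")
        return np.empty(0, dtype=int)

    candidates = _local_maxima(x)
    if candidates.size == 0:
        return np.empty(0, dtype=int)

    height = criteria.min_height(x)
    prominence = criteria.min_prominence(x)
    candidates = candidates[x[candidates] >= height]
    candidates = np.array(
        [p for p in candidates if topographic_prominence(x, p) >= prominence],
        dtype=int,
    )
    if candidates.size == 0:
        return candidates

    # greedy separation: highest first, earlier index wins ties
    order = sorted(range(candidates.size), key=lambda i: (-x[candidates[i]], candidates[i]))
    accepted: list[int] = []
    sep = criteria.min_separation
    for i in order:
        p = int(candidates[i])
        if all(abs(p - q) >= sep for q in accepted):
            accepted.append(p)
    return np.array(sorted(accepted), dtype=int)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; a flat plateau higher than both neighbours counts
    once, at its left edge.  Signal edges are not maxima."""
    peaks = []
    n = x.size
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(peaks, dtype=int)


def quantify_motion(
    peak_indices: np.ndarray,
    segment: MotionSegment,
    fs: float,
    report_duration: bool = True,
) -> MotionQuantification:
    """Combine crest indices and the bout segment into count, frequency and
    duration.

    mean_frequency is (count - 1) / (span between first and last crest);
    with fewer than two crests the rate is undefined and reported as 0.
    ``report_duration=False`` suits the ruler preset, whose decaying motion
    has no well-defined endpoint (duration reported as nan).
    """
    peaks = np.asarray(peak_indices, dtype=int)
    count = int(peaks.size)
    if count >= 2:
        span = (peaks[-1] - peaks[0]) / fs
        mean_frequency = (count - 1) / span if span > 0 else 0.0
    else:
        mean_frequency = 0.0
    duration = segment.duration_s if report_duration else float("nan")
    return MotionQuantification(
        count=count,
        mean_frequency=mean_frequency,
        duration=duration,
        peak_indices=peaks,
    )


def compute_spectrum(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude spectrum of a series."""
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("series must have at least 2 samples")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mags = np.abs(np.fft.rfft(x))
    return freqs, mags
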