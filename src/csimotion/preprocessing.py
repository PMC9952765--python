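"""Stage 1: per-subcarrier z-score normalization and Butterworth bandpass.

Every subcarrier column is standardized to zero mean and unit standard
deviation (population convention), then passed through a third-order digital
Butterworth bandpass designed by the bilinear transform with frequency
prewarping.  Band presets follow the motion types: [3, 6] Hz for resting
tremor, [1, 10] Hz for finger tapping and ruler vibration.  Filtering is
causal (zero initial conditions) by default; an optional zero-phase
forward-backward mode exists for exploratory use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

from .signals import BasicSignalMatrix

#: Bandpass presets per motion type (Hz).
BAND_PRESETS: dict[str, tuple[float, float]] = {
    "resting_tremor": (3.0, 6.0),
    "finger_tapping": (1.0, 10.0),
    "ruler_vibration": (1.0, 10.0),
    "tremor": (3.0, 6.0),
    "tapping": (1.0, 10.0),
    "ruler": (1.0, 10.0),
}

#: Upper motion frequency per motion type (Hz), used for the peak-separation
#: criterion downstream.
F_MAX_PRESETS: dict[str, float] = {
    "resting_tremor": 6.0,
    "finger_tapping": 10.0,
    "ruler_vibration": 10.0,
    "tremor": 6.0,
    "tapping": 10.0,
    "ruler": 10.0,
}


@dataclass
class FilterSpec:
    """Digital IIR bandpass as transfer-function coefficients.

    For polynomial order n the bandpass has 2n poles, so a and b have length
    2n+1 and a is normalized to a[0] = 1.
    """

    order: int
    f_low: float
    f_high: float
    fs: float
    b: np.ndarray
    a: np.ndarray
    sos: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if len(self.a) != 2 * self.order + 1 or len(self.b) != len(self.a):
            raise ValueError("bandpass coefficient arrays must have length 2n+1")
        if abs(self.a[0] - 1.0) > 1e-12:
            raise ValueError("denominator must be normalized to a[0] = 1")

    @property
    def is_stable(self) -> bool:
        return bool(np.all(np.abs(np.roots(self.a)) < 1.0))

    def response_at(self, freq_hz: float) -> complex:
        """Complex frequency response G(e^{j 2 pi f / fs})."""
        _, h = sps.freqz(self.b, self.a, worN=[freq_hz], fs=self.fs)
        return complex(h[0])


@dataclass
class NormalizedSequence:
    """Real T x S matrix at a tagged pipeline stage (P_prime or A)."""

    values: np.ndarray
    fs: float
    stage: Literal["P_prime", "A"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]


def zscore_normalize(P: BasicSignalMatrix | np.ndarray, fs: float | None = None) -> NormalizedSequence:
    """Column-wise (P - mean) / sd with the population (divide-by-T) sd.

    Raises on constant columns: a zero-variance signal carries no motion
    information and cannot be standardized.
    """
    if isinstance(P, BasicSignalMatrix):
        values, fs = P.values, P.fs
    else:
        values = np.asarray(P, dtype=np.float64)
        if values.ndim == 1:
            values = values[:, None]
        if fs is None:
            raise ValueError("fs is required when normalizing a bare array")
    sd = values.std(axis=0)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"column(s) {zero.tolist()} are constant (sd = 0) and cannot be "
            "z-score normalized"
        )
    out = (values - values.mean(axis=0)) / sd
    return NormalizedSequence(out, fs=fs, stage="P_prime")


def design_butterworth_bandpass(
    order: int, f_low: float, f_high: float, fs: float
) -> FilterSpec:
    """Digital Butterworth bandpass (bilinear transform, prewarped cutoffs).

    ``order`` is the polynomial order n; the resulting bandpass has 2n poles
    and coefficients of length 2n+1 with a[0] = 1.
    """
    if not 0 < f_low < f_high < fs / 2:
        raise ValueError(
            f"require 0 < f_low < f_high < fs/2, got ({f_low}, {f_high}) at fs={fs}"
        )
    b, a = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs)
    sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    return FilterSpec(
        order=order, f_low=f_low, f_high=f_high, fs=fs, b=b, a=a / a[0], sos=sos
    )


def design_preset(motion_type: str, fs: float, order: int = 3) -> FilterSpec:
    """Bandpass for a motion-type preset."""
    if motion_type not in BAND_PRESETS:
        raise ValueError(f"no band preset for motion type {motion_type!r}")
    f_low, f_high = BAND_PRESETS[motion_type]
    return design_butterworth_bandpass(order, f_low, f_high, fs)


def apply_filter(
    spec: FilterSpec,
    P_prime: NormalizedSequence,
    zero_phase: bool = False,
) -> NormalizedSequence:
    """Filter each column through G(z): causal, zero initial conditions
    (``zero_phase`` selects forward-backward filtering instead).

    The narrow bands used here put the poles very close to the unit circle,
    where the expanded (b, a) recursion loses ~6 digits; filtering therefore
    runs as a cascade of second-order sections of the same transfer
    function whenever the spec carries them.
    """
    if not spec.is_stable:
        raise ValueError("filter is unstable (poles on or outside the unit circle)")
    filt = sps.filtfilt if zero_phase else sps.lfilter
    sosfilt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    if spec.sos is not None:
        out = sosfilt(spec.sos, P_prime.values, axis=0)
    else:
        out = filt(spec.b, spec.a, P_prime.values, axis=0)
    return NormalizedSequence(np.asarray(out), fs=P_prime.fs, stage="A")
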