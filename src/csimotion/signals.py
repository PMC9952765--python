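"""Basic signals derived from complex CSI.

The pipeline never operates on the complex channel matrix directly; it first
reduces it to a real "basic signal": per-subcarrier amplitude |H(i)|, phase
angle(H(i)), the phase difference between two antenna streams, or the
amplitude ratio between two streams (which cancels gain noise common to both
receive chains).

Raw CSI phase is contaminated by carrier-frequency and sampling-frequency
offsets, which appear as a time-varying line (slope + offset) across the
subcarrier index.  ``extract_phase(..., sanitize=True)`` removes, at every
time step, the least-squares linear trend of unwrapped phase against
subcarrier index together with the mean offset — the standard CFO/SFO
cleanup.  Phase values follow the (-pi, pi] wrapping convention throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .recording import CSIRecording, InvalidRecordingError

logger = logging.getLogger(__name__)

SignalKind = Literal["amplitude", "phase", "phase_difference", "ratio"]


@dataclass
class BasicSignalMatrix:
    """Real-valued derived signal, T time steps x S' columns.

    ``source_streams`` records which antenna stream(s) each column came from,
    e.g. ``[(0,), (0,)...]`` for single-stream amplitude or ``[(0, 1), ...]``
    for a phase difference between streams 0 and 1.
    """

    values: np.ndarray
    kind: SignalKind
    fs: float
    source_streams: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.kind in ("amplitude", "ratio") and np.any(self.values < 0):
            raise ValueError(f"{self.kind} values must be nonnegative")
        if self.kind in ("phase", "phase_difference"):
            v = self.values
            if np.any(v > np.pi) or np.any(v <= -np.pi - 1e-12):
                raise ValueError("phase values must lie in (-pi, pi]")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    phi = np.asarray(phi, dtype=np.float64)
    wrapped = np.mod(-phi + np.pi, 2 * np.pi)
    return -(wrapped - np.pi)


def extract_amplitude(rec: CSIRecording) -> BasicSignalMatrix:
    """Per-entry modulus |H(t, i)| of the recording."""
    if rec.n_times < 1:
        raise InvalidRecordingError("empty recording")
    return BasicSignalMatrix(
        np.abs(rec.samples),
        kind="amplitude",
        fs=rec.fs,
        source_streams=[(k // 30,) for k in range(rec.n_subcarriers)],
    )


def extract_phase(rec: CSIRecording, sanitize: bool = True) -> BasicSignalMatrix:
    """Per-entry phase angle of the recording, wrapped to (-pi, pi].

    With ``sanitize`` the linear trend of phase across the subcarrier index
    and the mean offset are removed independently at every time step,
    suppressing CFO/SFO artifacts.  Zero-magnitude samples have undefined
    phase; they are assigned 0 and counted in the log.
    """
    zero_mask = rec.samples == 0
    n_zero = int(zero_mask.sum())
    if n_zero:
        logger.warning(
            "extract_phase: %d zero-magnitude samples, phase set to 0", n_zero
        )
    phase = np.angle(rec.samples)
    phase[zero_mask] = 0.0
    if sanitize:
        # detrend across subcarrier index per time step, on unwrapped phase
        unwrapped = np.unwrap(phase, axis=1)
        idx = np.arange(rec.n_subcarriers, dtype=np.float64)
        idx_c = idx - idx.mean()
        slope = (unwrapped @ idx_c) / (idx_c @ idx_c)
        fitted = unwrapped.mean(axis=1)[:, None] + slope[:, None] * idx_c[None, :]
        phase = unwrapped - fitted
    return BasicSignalMatrix(
        wrap_phase(phase),
        kind="phase",
        fs=rec.fs,
        source_streams=[(k // 30,) for k in range(rec.n_subcarriers)],
    )


def extract_phase_difference(
    rec: CSIRecording, stream_a: int = 0, stream_b: int = 1
) -> BasicSignalMatrix:
    """Wrapped phase difference angle(H_a(i)) - angle(H_b(i)).

    The difference between CSI phases of two receive chains cancels the
    common carrier-offset terms, so no further sanitization is applied.  By
    convention stream_a and stream_b default to the two rx antennas sharing
    the first tx antenna.
    """
    if stream_a == stream_b:
        logger.warning(
            "extract_phase_difference: identical streams (%d), returning zeros",
            stream_a,
        )
        zeros = np.zeros((rec.n_times, 30))
        return BasicSignalMatrix(
            zeros,
            kind="phase_difference",
            fs=rec.fs,
            source_streams=[(stream_a, stream_b)] * 30,
        )
    a = rec.stream_samples(stream_a)
    b = rec.stream_samples(stream_b)
    diff = wrap_phase(np.angle(a) - np.angle(b))
    return BasicSignalMatrix(
        diff,
        kind="phase_difference",
        fs=rec.fs,
        source_streams=[(stream_a, stream_b)] * a.shape[1],
    )


def compute_csi_ratio(
    rec: CSIRecording,
    stream_a: int = 0,
    stream_b: int = 1,
    eps_factor: float = 1e-6,
) -> BasicSignalMatrix:
    """Amplitude ratio |H_a(i)| / |H_b(i)| between two antenna streams.

    Denominator entries whose amplitude falls below ``eps_factor`` times the
    median amplitude of stream_b are treated as dropouts: the ratio there is
    imputed from the nearest valid time step of the same subcarrier, and the
    number of imputed entries is logged.
    """
    num = np.abs(rec.stream_samples(stream_a))
    den = np.abs(rec.stream_samples(stream_b))
    eps = eps_factor * float(np.median(den))
    bad = den <= eps
    ratio = np.divide(num, den, out=np.zeros_like(num), where=~bad)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning(
            "compute_csi_ratio: %d entries below eps=%.3g imputed from "
            "nearest valid neighbor",
            n_bad,
            eps,
        )
        for col in np.nonzero(bad.any(axis=0))[0]:
            col_bad = bad[:, col]
            valid_idx = np.nonzero(~col_bad)[0]
            if valid_idx.size == 0:
                raise ValueError(
                    f"ratio column {col}: denominator never exceeds eps"
                )
            bad_idx = np.nonzero(col_bad)[0]
            nearest = valid_idx[
                np.argmin(np.abs(bad_idx[:, None] - valid_idx[None, :]), axis=1)
            ]
            ratio[bad_idx, col] = ratio[nearest, col]
    return BasicSignalMatrix(
        ratio,
        kind="ratio",
        fs=rec.fs,
        source_streams=[(stream_a, stream_b)] * num.shape[1],
    )


def extract_signal(
    rec: CSIRecording,
    kind: SignalKind,
    stream_a: int = 0,
    stream_b: int = 1,
) -> BasicSignalMatrix:
    """Dispatch to the named basic-signal extractor."""
    if kind == "amplitude":
        return extract_amplitude(rec)
    if kind == "phase":
        return extract_phase(rec)
    if kind == "phase_difference":
        return extract_phase_difference(rec, stream_a, stream_b)
    if kind == "ratio":
        return compute_csi_ratio(rec, stream_a, stream_b)
    raise ValueError(f"unknown signal kind {kind!r}")
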