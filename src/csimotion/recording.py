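"""CSI recording container and file I/O.

A recording holds the complex channel matrix H sampled over time: one row per
time step, one column per subcarrier.  Commodity 802.11n hardware exposes 30
subcarriers per (tx antenna, rx antenna) stream, so the column count is always
a multiple of 30 and columns are grouped stream-by-stream.

On disk a recording is a CSV (columns ``t, s1_re, s1_im, ..., sS_re, sS_im``)
with a JSON metadata sidecar ``<name>.meta.json`` carrying the sampling rate,
stream list, carrier frequency and free-form provenance (scene geometry, seed,
ground truth).  A raw binary container (row-major float64, interleaved
re/im, fixed-size header) is provided for large files.

Parsing of vendor capture formats (e.g. Intel 5300 ``.dat``) is deliberately
not provided; ``CSIRecording.from_samples`` is the adapter hook point — a
converter only needs to build the complex matrix and metadata.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

SUBCARRIERS_PER_STREAM = 30

_BINARY_MAGIC = b"CSIREC01"


class InvalidRecordingError(ValueError):
    """Raised when a CSI recording violates its structural invariants."""


@dataclass
class CSIRecording:
    """Complex CSI time series: T time steps x S subcarriers.

    Parameters
    ----------
    samples
        Complex matrix of shape (T, S); S must be a positive multiple of 30.
        Columns are ordered stream-by-stream, 30 subcarriers each.
    fs
        Sampling rate in Hz.
    streams
        One (tx_antenna, rx_antenna) pair per block of 30 columns.
    carrier_freq
        Carrier frequency in Hz (5 GHz band by default).
    meta
        Free-form provenance: scene geometry, seed, ground truth, ...
    """

    samples: np.ndarray
    fs: float
    streams: list[tuple[int, int]] = field(default_factory=lambda: [(0, 0)])
    carrier_freq: float = 5e9
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise InvalidRecordingError(
                "samples must be a 2-D matrix with at least one time step"
            )
        T, S = self.samples.shape
        if S <= 0 or S % SUBCARRIERS_PER_STREAM != 0:
            raise InvalidRecordingError(
                f"subcarrier count {S} is not a positive multiple of "
                f"{SUBCARRIERS_PER_STREAM}"
            )
        if len(self.streams) != S // SUBCARRIERS_PER_STREAM:
            raise InvalidRecordingError(
                f"{len(self.streams)} streams declared but {S} columns imply "
                f"{S // SUBCARRIERS_PER_STREAM}"
            )
        if not self.fs > 0:
            raise InvalidRecordingError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples.view(np.float64))):
            raise InvalidRecordingError("samples contain NaN or infinite entries")

    # ------------------------------------------------------------------ shape
    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_subcarriers(self) -> int:
        return self.samples.shape[1]

    @property
    def n_streams(self) -> int:
        return len(self.streams)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.fs

    def stream_slice(self, stream_index: int) -> slice:
        """Column slice of the 30 subcarriers belonging to one stream."""
        if not 0 <= stream_index < self.n_streams:
            raise IndexError(
                f"stream {stream_index} out of range (have {self.n_streams})"
            )
        lo = stream_index * SUBCARRIERS_PER_STREAM
        return slice(lo, lo + SUBCARRIERS_PER_STREAM)

    def stream_samples(self, stream_index: int) -> np.ndarray:
        """Complex T x 30 matrix of a single antenna stream."""
        return self.samples[:, self.stream_slice(stream_index)]

    @classmethod
    def from_samples(
        cls,
        samples: np.ndarray,
        fs: float,
        streams: Sequence[tuple[int, int]] | None = None,
        carrier_freq: float = 5e9,
        meta: dict[str, Any] | None = None,
    ) -> "CSIRecording":
        """Adapter hook: build a recording from an already-decoded matrix."""
        samples = np.asarray(samples, dtype=np.complex128)
        if streams is None:
            n = samples.shape[1] // SUBCARRIERS_PER_STREAM if samples.ndim == 2 else 0
            streams = [(0, i) for i in range(max(n, 1))]
        return cls(samples, fs, list(map(tuple, streams)), carrier_freq, meta or {})

    # --------------------------------------------------------------------- IO
    def to_csv(self, path: str | Path) -> None:
        """Write CSV + ``<name>.meta.json`` sidecar."""
        path = Path(path)
        T, S = self.samples.shape
        data = {"t": np.arange(T) / self.fs}
        for k in range(S):
            data[f"s{k + 1}_re"] = self.samples[:, k].real
            data[f"s{k + 1}_im"] = self.samples[:, k].imag
        pd.DataFrame(data).to_csv(path, index=False)
        self._write_sidecar(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CSIRecording":
        path = Path(path)
        df = pd.read_csv(path)
        S = (len(df.columns) - 1) // 2
        samples = np.empty((len(df), S), dtype=np.complex128)
        for k in range(S):
            samples[:, k] = df[f"s{k + 1}_re"].to_numpy() + 1j * df[
                f"s{k + 1}_im"
            ].to_numpy()
        return cls._with_sidecar(samples, path)

    def to_binary(self, path: str | Path) -> None:
        """Raw container: 8-byte magic, uint64 T, uint64 S, float64 fs, then
        row-major float64 interleaved (re, im) pairs."""
        path = Path(path)
        T, S = self.samples.shape
        with open(path, "wb") as fh:
            fh.write(_BINARY_MAGIC)
            fh.write(struct.pack("<QQd", T, S, self.fs))
            interleaved = np.empty((T, 2 * S), dtype=np.float64)
            interleaved[:, 0::2] = self.samples.real
            interleaved[:, 1::2] = self.samples.imag
            interleaved.tofile(fh)
        self._write_sidecar(path)

    @classmethod
    def from_binary(cls, path: str | Path) -> "CSIRecording":
        path = Path(path)
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if magic != _BINARY_MAGIC:
                raise InvalidRecordingError(f"{path} is not a CSI binary container")
            T, S, _fs = struct.unpack("<QQd", fh.read(24))
            flat = np.fromfile(fh, dtype=np.float64, count=T * 2 * S)
        interleaved = flat.reshape(T, 2 * S)
        samples = interleaved[:, 0::2] + 1j * interleaved[:, 1::2]
        return cls._with_sidecar(samples, path)

    def _write_sidecar(self, data_path: Path) -> None:
        sidecar = data_path.with_suffix(data_path.suffix + ".meta.json")
        payload = {
            "fs": self.fs,
            "streams": [list(s) for s in self.streams],
            "carrier_freq": self.carrier_freq,
            "meta": _jsonable(self.meta),
        }
        sidecar.write_text(json.dumps(payload, indent=1))

    @classmethod
    def _with_sidecar(cls, samples: np.ndarray, data_path: Path) -> "CSIRecording":
        sidecar = data_path.with_suffix(data_path.suffix + ".meta.json")
        if not sidecar.exists():
            raise InvalidRecordingError(f"missing metadata sidecar {sidecar}")
        payload = json.loads(sidecar.read_text())
        return cls(
            samples,
            fs=payload["fs"],
            streams=[tuple(s) for s in payload["streams"]],
            carrier_freq=payload.get("carrier_freq", 5e9),
            meta=payload.get("meta", {}),
        )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
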