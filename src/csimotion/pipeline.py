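"""End-to-end micromotion quantification pipeline.

Chains the four stages on a CSI recording:

1. basic-signal extraction (amplitude by default) and per-subcarrier z-score
   normalization (P -> P'),
2. third-order Butterworth bandpass with the motion-type band preset
   (P' -> A),
3. SVD component selection and renormalization (A -> V*'),
4. short-time energy segmentation (V*' -> E -> V_W), Savitzky-Golay
   smoothing (V_W -> Q) and three-criterion peak counting.

Every stage's output is kept in the returned :class:`PipelineTrace` so runs
can be inspected, plotted or serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .decomposition import ComponentSelection, select_principal_component
from .preprocessing import (
    BAND_PRESETS,
    F_MAX_PRESETS,
    FilterSpec,
    NormalizedSequence,
    apply_filter,
    design_preset,
    zscore_normalize,
)
from .quantification import (
    MotionQuantification,
    PeakCriteria,
    find_motion_peaks,
    quantify_motion,
    savgol_smooth,
    topographic_prominence,
)
from .recording import CSIRecording
from .segmentation import (
    EnergySeries,
    MotionSegment,
    detect_packet_loss,
    segment_active,
    short_time_energy,
)
from .signals import BasicSignalMatrix, SignalKind, extract_signal


@dataclass
class PipelineConfig:
    """Tunable parameters of the quantification pipeline.

    Defaults follow the study conditions: band and f_max from the motion
    type, energy window 51 samples, threshold at 10% of peak energy,
    third-order Savitzky-Golay smoothing over 101 samples, height and
    prominence thresholds at 0.2 and 0.3 of max(Q).
    """

    motion_type: str = "resting_tremor"
    signal_kind: SignalKind = "amplitude"
    filter_order: int = 3
    energy_window: int = 51
    threshold_frac: float = 0.1
    savgol_order: int = 3
    savgol_window: int = 101
    height_factor: float = 0.2
    prominence_factor: float = 0.3
    packet_loss_min_run: int = 3
    stream_a: int = 0
    stream_b: int = 1

    @property
    def band(self) -> tuple[float, float]:
        return BAND_PRESETS[self.motion_type]

    @property
    def f_max(self) -> float:
        return F_MAX_PRESETS[self.motion_type]


@dataclass
class PipelineTrace:
    """Staged outputs of one pipeline run."""

    config: PipelineConfig
    basic_signal: BasicSignalMatrix
    P_prime: NormalizedSequence
    filter_spec: FilterSpec
    A: NormalizedSequence
    selection: ComponentSelection
    energy: EnergySeries
    segment: MotionSegment | None
    V_W: np.ndarray | None
    Q: np.ndarray | None
    peak_indices: np.ndarray
    quantification: MotionQuantification
    packet_loss_flags: list[tuple[int, int]] = field(default_factory=list)

    def report(self) -> dict[str, Any]:
        """JSON-serializable run report with every stage's parameters."""
        cfg = self.config
        return {
            "config": {
                "motion_type": cfg.motion_type,
                "signal_kind": cfg.signal_kind,
                "band_hz": list(cfg.band),
                "f_max_hz": cfg.f_max,
                "filter_order": cfg.filter_order,
                "energy_window": cfg.energy_window,
                "threshold_frac": cfg.threshold_frac,
                "savgol_order": cfg.savgol_order,
                "savgol_window": cfg.savgol_window,
                "height_factor": cfg.height_factor,
                "prominence_factor": cfg.prominence_factor,
            },
            "filter": {"b": self.filter_spec.b.tolist(), "a": self.filter_spec.a.tolist()},
            "component_index": self.selection.component_index,
            "singular_values": self.selection.singular_values[:10].tolist(),
            "segment": None
            if self.segment is None
            else {
                "start_index": self.segment.start_index,
                "end_index": self.segment.end_index,
                "duration_s": self.segment.duration_s,
            },
            "packet_loss_flags": [list(r) for r in self.packet_loss_flags],
            "quantification": self.quantification.to_dict(),
        }


def run_pipeline(
    rec: CSIRecording,
    config: PipelineConfig | None = None,
    **overrides: Any,
) -> PipelineTrace:
    """Quantify the motion bout in a CSI recording.

    ``overrides`` are applied on top of the default :class:`PipelineConfig`
    (e.g. ``run_pipeline(rec, motion_type="finger_tapping")``).  The ruler
    preset reports no duration — a decaying vibration has no detectable
    endpoint — so its quantification carries duration = nan.
    """
    if config is None:
        config = PipelineConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config object or keyword overrides, not both")

    flags = detect_packet_loss(rec, min_run=config.packet_loss_min_run)

    P = extract_signal(rec, config.signal_kind, config.stream_a, config.stream_b)
    P_prime = zscore_normalize(P)
    spec = design_preset(config.motion_type, fs=rec.fs, order=config.filter_order)
    A = apply_filter(spec, P_prime)
    selection = select_principal_component(A)
    energy = short_time_energy(
        selection.component_series, N=config.energy_window
    )
    segment = segment_active(
        energy,
        threshold_frac=config.threshold_frac,
        fs=rec.fs,
        merge_gap=int(rec.fs / config.band[0]),
    )

    if segment is None:
        quant = MotionQuantification(
            count=0,
            mean_frequency=0.0,
            duration=0.0,
            peak_indices=np.empty(0, dtype=int),
        )
        return PipelineTrace(
            config, P, P_prime, spec, A, selection, energy, None, None, None,
            np.empty(0, dtype=int), quant, flags,
        )

    V_W = selection.component_series[segment.start_index : segment.end_index]
    window = config.savgol_window
    if V_W.size < window:  # short bouts: shrink to the largest odd window
        window = max(config.savgol_order + 2, V_W.size - (V_W.size + 1) % 2)
    Q = savgol_smooth(V_W, order=config.savgol_order, window=window)
    criteria = PeakCriteria(
        f_max=config.f_max,
        fs=rec.fs,
        height_factor=config.height_factor,
        prominence_factor=config.prominence_factor,
    )
    peaks = find_motion_peaks(Q, criteria)
    quant = quantify_motion(
        peaks + segment.start_index,
        segment,
        rec.fs,
        report_duration=config.motion_type not in ("ruler_vibration", "ruler"),
    )
    quant.peak_prominences = np.array(
        [topographic_prominence(Q, int(p)) for p in peaks]
    )
    return PipelineTrace(
        config, P, P_prime, spec, A, selection, energy, segment, V_W, Q,
        quant.peak_indices, quant, flags,
    )
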