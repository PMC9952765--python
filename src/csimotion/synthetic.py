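"""Synthetic CSI generator with known ground truth.

Real CSI for this problem is a superposition of static multipath (walls,
furniture, the LoS path) and one dynamic reflection path off the moving hand.
When the hand sits at p(t), the reflected path length is
d(t) = |tx - p(t)| + |p(t) - rx|, and the dynamic term contributes
``reflection_gain * exp(-j 2*pi*d(t)/lambda_i)`` per subcarrier: as the hand
crosses Fresnel-zone boundaries (spaced lambda/2 in path length) the dynamic
term rotates through constructive and destructive interference with the
static field, which is what makes sub-centimetre motion visible in the
amplitude.  Only the displacement component along the gradient of d (normal
to the local Fresnel ellipse) changes the path length; tangential motion is
invisible — the simulator reproduces that directional effect.

Two fidelity modes are provided:

``geometric`` (default)
    The path-length model above.  With 8-10 cm displacement at lambda ~ 6 cm
    a single motion cycle sweeps several Fresnel fringes, as real CSI does.

``direct``
    Amplitude modulation ``baseline + gain * u(t)`` with ``u`` the
    unit-amplitude motion waveform.  One amplitude crest per motion cycle by
    construction, so pipeline outputs have exact analytic expectations; used
    wherever a test needs a closed-form answer.

Three motion waveforms are modelled, all built from per-cycle segments so the
generator can report an exact answer key (cycle count, crest times, per-cycle
frequency): exponentially damped sinusoid cycles (steel-ruler vibration from
a 10 cm initial deflection), raised-cosine pulses at ~1 Hz (finger tapping,
one strong impulse per tap), and sinusoid cycles whose frequency is redrawn
uniformly per cycle (resting tremor, 3-6 Hz).  Recordings carry the answer
key in ``meta["ground_truth"]``.

Packet-loss and slow-response injectors reproduce the two measurement
artifacts that corrupt real captures: receivers log a repeat of the previous
CSI value during a dropout (flat runs), and the channel response builds up /
dies away gradually at motion onset and offset (attenuated first and last
cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from scipy.signal import resample_poly

from .recording import CSIRecording

C_LIGHT = 299_792_458.0

MotionType = Literal["ruler_vibration", "finger_tapping", "resting_tremor"]


class InvalidConfigError(ValueError):
    """Raised for physically or numerically inconsistent configurations."""


@dataclass
class MotionProfile:
    """Kinematic description of one motion bout.

    frequency_spec is either a fixed frequency in Hz or a (low, high) range
    from which each cycle's frequency is drawn uniformly.  ``damping`` (1/s)
    applies to ruler vibration only.  ``direction`` is the unit vector along
    which the displacement is applied in the scene plane.
    """

    motion_type: MotionType = "resting_tremor"
    start: float = 5.0
    active_duration: float = 10.0
    displacement_amplitude: float = 0.09
    frequency_spec: float | tuple[float, float] = (3.0, 6.0)
    damping: float = 0.0
    direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InvalidConfigError("start must be nonnegative")
        if self.active_duration <= 0:
            raise InvalidConfigError("active_duration must be positive")
        lo, hi = self.frequency_range
        if not 0 < lo <= hi:
            raise InvalidConfigError("frequencies must be positive and ordered")
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            raise InvalidConfigError("direction must be a nonzero vector")
        self.direction = (self.direction[0] / norm, self.direction[1] / norm)

    @property
    def frequency_range(self) -> tuple[float, float]:
        if isinstance(self.frequency_spec, (int, float)):
            return float(self.frequency_spec), float(self.frequency_spec)
        lo, hi = self.frequency_spec
        return float(lo), float(hi)

    @classmethod
    def preset(cls, motion: str, **overrides: Any) -> "MotionProfile":
        """Study-condition presets: ruler (damped, 10 cm), tapping (~1 Hz,
        8 cm), tremor (3-6 Hz, ~9 cm)."""
        presets: dict[str, dict[str, Any]] = {
            "ruler": dict(
                motion_type="ruler_vibration",
                displacement_amplitude=0.10,
                frequency_spec=3.46,
                damping=0.2,
            ),
            "tapping": dict(
                motion_type="finger_tapping",
                displacement_amplitude=0.08,
                frequency_spec=1.0,
            ),
            "tremor": dict(
                motion_type="resting_tremor",
                displacement_amplitude=0.09,
                frequency_spec=(3.0, 6.0),
            ),
        }
        key = {"ruler_vibration": "ruler", "finger_tapping": "tapping",
               "resting_tremor": "tremor"}.get(motion, motion)
        if key not in presets:
            raise InvalidConfigError(f"unknown motion preset {motion!r}")
        cfg = presets[key] | overrides
        return cls(**cfg)


@dataclass
class GroundTruth:
    """The simulator's answer key for one motion bout."""

    true_count: int
    true_mean_frequency: float
    true_duration: float
    cycle_times: list[float]
    cycle_frequencies: list[float] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "true_count": self.true_count,
            "true_mean_frequency": self.true_mean_frequency,
            "true_duration": self.true_duration,
            "cycle_times": list(self.cycle_times),
            "cycle_frequencies": list(self.cycle_frequencies),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GroundTruth":
        return cls(
            true_count=int(d["true_count"]),
            true_mean_frequency=float(d["true_mean_frequency"]),
            true_duration=float(d["true_duration"]),
            cycle_times=list(d["cycle_times"]),
            cycle_frequencies=list(d.get("cycle_frequencies", [])),
        )


@dataclass
class ReferenceTrace:
    """Accelerometer-style reference signal sampled at 200 Hz.

    The stored axis is the negated acceleration along the motion direction,
    so trace crests coincide with displacement crests (the sensor's axis sign
    is an arbitrary mounting choice).
    """

    values: np.ndarray
    fs: float = 200.0
    axis: str = "-d2x/dt2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()


@dataclass
class SceneConfig:
    """Geometry and channel parameters for one simulated trial.

    The default scene mirrors the study conditions: a 4.2 m x 7.9 m room
    (origin at the LoS midpoint), a 2 m Tx-Rx link along the x axis, motion
    1 m from the LoS midpoint, 5 GHz carrier with 30 subcarriers spread over
    a 20 MHz band per stream, 1000 Hz CSI rate, 20 s per trial.
    """

    room: tuple[float, float] = (4.2, 7.9)
    tx_pos: tuple[float, float] = (-1.0, 0.0)
    rx_pos: tuple[float, float] = (1.0, 0.0)
    motion_pos: tuple[float, float] = (0.0, 1.0)
    carrier_freq: float = 5e9
    subcarrier_spacing: float = 20e6 / 29  # 30 subcarriers across 20 MHz
    n_streams: int = 6
    static_path_gain: complex | np.ndarray | None = None
    reflection_gain: float = 0.3
    noise_sd: float = 0.0
    fs: float = 1000.0
    duration: float = 20.0
    seed: int = 0
    mode: Literal["geometric", "direct"] = "geometric"
    direct_baseline: float = 1.0
    direct_gain: float = 0.2

    def __post_init__(self) -> None:
        hw, hh = self.room[0] / 2, self.room[1] / 2
        for name in ("tx_pos", "rx_pos", "motion_pos"):
            x, y = getattr(self, name)
            if abs(x) > hw or abs(y) > hh:
                raise InvalidConfigError(
                    f"{name}={x, y} lies outside the {self.room} room "
                    "(origin at the room centre)"
                )
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if self.duration <= 0 or self.fs <= 0:
            raise InvalidConfigError("duration and fs must be positive")

    @property
    def n_subcarriers(self) -> int:
        return 30 * self.n_streams

    def subcarrier_freqs(self) -> np.ndarray:
        """Carrier-band frequency of each of the 30*n_streams columns; the
        30 subcarriers span carrier +/- 10 MHz and repeat per stream."""
        offsets = (np.arange(30) - 14.5) * self.subcarrier_spacing
        return np.tile(self.carrier_freq + offsets, self.n_streams)


# ---------------------------------------------------------------- displacement
def generate_displacement(
    profile: MotionProfile,
    fs: float,
    duration: float,
    seed: int | None = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Sample the displacement waveform and its answer key.

    The waveform is identically zero outside [start, start+active_duration]
    and is assembled cycle-by-cycle inside it.  For range-valued frequency
    specs each cycle's frequency is an independent uniform draw; the last
    cycle's period is set to exactly fill the remaining active time whenever
    the implied frequency stays inside the range (otherwise a residual
    shorter than one period of the fastest admissible cycle is left quiet).
    Completed cycles define ``true_count``; ``true_mean_frequency`` uses the
    fencepost convention (count-1)/(span of cycle crests) that the
    quantification stage also reports, so estimate and truth are directly
    comparable.
    """
    f_lo, f_hi = profile.frequency_range
    if f_hi >= fs / 2:
        raise InvalidConfigError(
            f"cycle frequency {f_hi} Hz is not below the Nyquist rate {fs / 2} Hz"
        )
    if profile.start + profile.active_duration > duration + 1e-9:
        raise InvalidConfigError("motion bout extends past the recording end")
    n = int(round(fs * duration))
    x = np.zeros(n)
    if profile.displacement_amplitude == 0:
        return x, GroundTruth(0, 0.0, profile.active_duration, [], [])

    rng = np.random.default_rng(seed)
    periods: list[float] = []
    remaining = profile.active_duration
    while True:
        T = 1.0 / (rng.uniform(f_lo, f_hi) if f_lo < f_hi else f_lo)
        if T > remaining + 1e-12:
            # stretch a final cycle over the leftover only if its frequency
            # stays inside the admissible range
            if remaining > 1e-12 and f_lo <= 1.0 / remaining <= f_hi:
                periods.append(remaining)
                remaining = 0.0
            break
        periods.append(T)
        remaining -= T

    A = profile.displacement_amplitude
    t0 = profile.start
    cycle_times: list[float] = []
    cycle_freqs: list[float] = []
    t = np.arange(n) / fs
    offset = 0.0
    for k, T in enumerate(periods):
        i0 = int(np.ceil((t0 + offset) * fs - 1e-9))
        i1 = int(np.ceil((t0 + offset + T) * fs - 1e-9))
        tau = t[i0:i1] - (t0 + offset)
        amp = A
        if profile.motion_type == "ruler_vibration" and profile.damping > 0:
            amp = A * np.exp(-profile.damping * offset)
        if profile.motion_type == "finger_tapping":
            x[i0:i1] = amp * 0.5 * (1.0 - np.cos(2 * np.pi * tau / T))
            crest = t0 + offset + T / 2
        else:
            x[i0:i1] = amp * np.sin(2 * np.pi * tau / T)
            crest = t0 + offset + T / 4
        cycle_times.append(crest)
        cycle_freqs.append(1.0 / T)
        offset += T

    count = len(periods)
    if count >= 2:
        mean_f = (count - 1) / (cycle_times[-1] - cycle_times[0])
    elif count == 1:
        mean_f = cycle_freqs[0]
    else:
        mean_f = 0.0
    gt = GroundTruth(count, mean_f, profile.active_duration, cycle_times, cycle_freqs)
    return x, gt


# -------------------------------------------------------------------- channel
def synthesize_csi(
    scene: SceneConfig, profile: MotionProfile
) -> CSIRecording:
    """Simulate one CSI recording of a motion bout.

    Geometric mode builds H(t, i) = static_gain_i + reflection_gain *
    exp(-j 2 pi d(t) / lambda_i) from the reflected path length d(t);
    direct mode modulates each subcarrier's amplitude by the unit motion
    waveform.  Complex white Gaussian noise with per-component standard
    deviation ``noise_sd`` is added in both modes.  The answer key and the
    scene parameters are stored in ``meta``.
    """
    fs, duration = scene.fs, scene.duration
    displacement, gt = generate_displacement(profile, fs, duration, scene.seed)
    n = displacement.size
    S = scene.n_subcarriers
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0xC51]))

    if scene.mode == "geometric":
        freqs = scene.subcarrier_freqs()
        lam = C_LIGHT / freqs
        tx = np.asarray(scene.tx_pos)
        rx = np.asarray(scene.rx_pos)
        p = np.asarray(scene.motion_pos)[None, :] + displacement[:, None] * np.asarray(
            profile.direction
        )
        d = np.linalg.norm(p - tx, axis=1) + np.linalg.norm(rx - p, axis=1)
        if scene.static_path_gain is None:
            static = rng.uniform(0.5, 1.5, S) * np.exp(
                1j * rng.uniform(-np.pi, np.pi, S)
            )
        else:
            static = np.broadcast_to(
                np.asarray(scene.static_path_gain, dtype=np.complex128), (S,)
            ).copy()
        samples = static[None, :] + scene.reflection_gain * np.exp(
            -2j * np.pi * d[:, None] / lam[None, :]
        )
    elif scene.mode == "direct":
        unit = (
            displacement / profile.displacement_amplitude
            if profile.displacement_amplitude > 0
            else displacement
        )
        amp = scene.direct_baseline + scene.direct_gain * unit
        phases = np.exp(1j * rng.uniform(-np.pi, np.pi, S))
        samples = amp[:, None] * phases[None, :]
    else:  # pragma: no cover - guarded by the Literal type
        raise InvalidConfigError(f"unknown mode {scene.mode!r}")

    if scene.noise_sd > 0:
        noise = scene.noise_sd * (
            rng.standard_normal((n, S)) + 1j * rng.standard_normal((n, S))
        )
        samples = samples + noise

    streams = [(tx_a, rx_a) for tx_a in range(2) for rx_a in range(3)][
        : scene.n_streams
    ]
    meta = {
        "ground_truth": gt.to_dict(),
        "motion_type": profile.motion_type,
        "motion_start": profile.start,
        "motion_active_duration": profile.active_duration,
        "mode": scene.mode,
        "seed": scene.seed,
        "noise_sd": scene.noise_sd,
    }
    return CSIRecording(
        samples, fs=fs, streams=streams, carrier_freq=scene.carrier_freq, meta=meta
    )


def reflection_path_gradient(scene: SceneConfig) -> np.ndarray:
    """Unit gradient of the reflected path length at the motion position.

    Displacement along this direction crosses Fresnel-zone boundaries
    fastest; displacement perpendicular to it leaves the path length
    unchanged to first order.
    """
    p = np.asarray(scene.motion_pos, dtype=float)
    tx = np.asarray(scene.tx_pos, dtype=float)
    rx = np.asarray(scene.rx_pos, dtype=float)
    g = (p - tx) / np.linalg.norm(p - tx) + (p - rx) / np.linalg.norm(p - rx)
    return g / np.linalg.norm(g)


# ------------------------------------------------------------------ artifacts
def inject_packet_loss(
    rec: CSIRecording, rate: float, seed: int | None = 0
) -> CSIRecording:
    """Replace each time step (after the first), with probability ``rate``,
    by a repeat of the previous retained row — the receiver's behaviour
    during dropouts, which shows up as flat runs in every subcarrier."""
    if not 0 <= rate <= 1:
        raise InvalidConfigError("rate must lie in [0, 1]")
    T = rec.n_times
    rng = np.random.default_rng(seed)
    lost = np.zeros(T, dtype=bool)
    lost[1:] = rng.random(T - 1) < rate
    src = np.where(lost, 0, np.arange(T))
    src = np.maximum.accumulate(src)
    meta = dict(rec.meta)
    meta["packet_loss"] = {"rate": rate, "n_lost": int(lost.sum()), "seed": seed}
    return CSIRecording(
        rec.samples[src].copy(),
        fs=rec.fs,
        streams=list(rec.streams),
        carrier_freq=rec.carrier_freq,
        meta=meta,
    )


def inject_slow_response(
    rec: CSIRecording, attack_time: float, release_time: float
) -> CSIRecording:
    """Attenuate the motion-induced CSI component near the bout's start and
    end with a linear attack/release ramp.

    Models the channel's sluggish response at motion onset/offset, which
    shrinks the first and last waves of the active state.  Applies only to
    synthetic recordings: the static component is estimated as the
    per-subcarrier mean over the pre-motion lead-in, and the active window is
    read from ``meta`` (raises if the recording carries no answer key).
    """
    if attack_time < 0 or release_time < 0:
        raise InvalidConfigError("attack and release times must be nonnegative")
    if "motion_start" not in rec.meta:
        raise InvalidConfigError(
            "recording carries no ground-truth meta; slow-response injection "
            "is defined for synthetic recordings only"
        )
    t0 = float(rec.meta["motion_start"])
    t1 = t0 + float(rec.meta["motion_active_duration"])
    t = np.arange(rec.n_times) / rec.fs
    env = np.ones(rec.n_times)
    active = (t >= t0) & (t < t1)
    if attack_time > 0:
        env[active] = np.minimum(env[active], (t[active] - t0) / attack_time)
    if release_time > 0:
        env[active] = np.minimum(env[active], (t1 - t[active]) / release_time)
    env = np.clip(env, 0.0, 1.0)

    n_lead = max(int(t0 * rec.fs), 1)
    static = rec.samples[:n_lead].mean(axis=0)
    samples = static[None, :] + env[:, None] * (rec.samples - static[None, :])
    meta = dict(rec.meta)
    meta["slow_response"] = {"attack_time": attack_time, "release_time": release_time}
    return CSIRecording(
        samples,
        fs=rec.fs,
        streams=list(rec.streams),
        carrier_freq=rec.carrier_freq,
        meta=meta,
    )


# ------------------------------------------------------------------ reference
def generate_reference_trace(
    profile: MotionProfile,
    seed: int | None = 0,
    duration: float | None = None,
    fs_out: float = 200.0,
    noise_sd: float = 0.05,
    sim_fs: float = 1000.0,
) -> ReferenceTrace:
    """Wearable-sensor reference: negated second derivative of displacement,
    resampled to the sensor rate (200 Hz) with additive Gaussian sensor
    noise.  Crests coincide with the answer key's cycle times."""
    if duration is None:
        duration = 2 * profile.start + profile.active_duration
    disp, _ = generate_displacement(profile, sim_fs, duration, seed)
    dt = 1.0 / sim_fs
    accel = -np.gradient(np.gradient(disp, dt), dt)
    up, down = _resample_ratio(fs_out, sim_fs)
    values = resample_poly(accel, up, down)
    n_out = int(round(fs_out * duration))
    values = values[:n_out]
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 0xACC]))
        values = values + noise_sd * rng.standard_normal(values.size)
    return ReferenceTrace(values=values, fs=fs_out)


def _resample_ratio(fs_out: float, fs_in: float) -> tuple[int, int]:
    from math import gcd

    a, b = int(round(fs_out)), int(round(fs_in))
    g = gcd(a, b)
    return a // g, b // g
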