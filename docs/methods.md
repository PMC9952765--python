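# Methods

## Signal model

Received CSI is modelled as `Y = H·X + N` per subcarrier, with `H` the
channel, `X` the known transmitted symbol and `N` additive white Gaussian
noise; the package works on the channel matrix `H(t, i)` (time × subcarrier,
complex), written in polar form as magnitude and wrapped phase. Four basic
signals are derived:

- **amplitude** `|H(t, i)|` — the default analysis signal; robust because it
  needs no phase synchronization;
- **phase** — raw phase is contaminated by carrier-frequency and
  sampling-frequency offsets, which at each time step appear as an
  approximately linear trend of phase across the subcarrier index.
  Sanitization removes, per time step, the least-squares line (slope and
  mean) of the unwrapped phase against subcarrier index. This is the
  standard CFO/SFO cleanup; it also removes any genuine linear
  delay signature, which is acceptable because the pipeline only consumes
  temporal variation.
- **phase difference** between two rx chains sharing a tx antenna — the
  common offsets cancel in the difference, so no further sanitization is
  applied;
- **CSI ratio** `|H_a|/|H_b|` between two rx chains — cancels gain noise
  common to both. Denominator entries below `10⁻⁶ ×` the stream's median
  amplitude are treated as dropouts and imputed from the nearest valid time
  step of the same subcarrier (count logged).

Phases follow the `(−π, π]` wrapping convention throughout; it must be fixed
somewhere for testability and this choice keeps `+π` representable.

## Pipeline stages and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| normalization | sd convention | population (divide by T) | immaterial at T = 20000, fixed for testability |
| bandpass | order / bands | 3; [3, 6] Hz tremor, [1, 10] Hz tapping & ruler | motion-type frequency ranges |
| component selection | centering | on | that is what PCA denotes; selection then picks the leading singular vector |
| energy | window N | 51 samples, rectangular | short relative to a motion period, long enough to smooth sample noise |
| segmentation | threshold | 0.1 · max(E) | rest-state energy sits far below active-state energy at the SNRs of interest |
| segmentation | merge gap | fs / f_low | see below |
| smoothing | Savitzky–Golay | order 3, window 101 @ 1000 Hz | removes fake peaks while preserving crests of 3–6 Hz waves |
| peak finding | separation | ⌊fs / f_max⌋ | two true crests cannot be closer than one period of the fastest motion |
| peak finding | height, prominence | 0.2·max(Q), 0.3·max(Q) | discard residual-noise crests |

**Filtering numerics.** The band designs put poles within ~10⁻³ of the unit
circle. The expanded transfer-function recursion `lfilter(b, a, ·)` then
loses about six significant digits (linearity holds only to ~10⁻⁶
relative); the implementation therefore applies the identical transfer
function as a cascade of second-order sections (`sosfilt`), which is linear
to ~10⁻¹³. The `(b, a)` arrays remain on `FilterSpec` as the reportable
design. Filtering is causal with zero initial conditions — the design's
printed coefficients describe a causal IIR — with a zero-phase
forward–backward option off by default.

**Segmentation merge gap.** The trailing energy window dips near every zero
crossing of the component series (the window then straddles mostly
small-amplitude samples). For 3 Hz cycles at N = 51 the dip falls below the
10 % threshold for up to ~100 samples, so merging only gaps shorter than N
splits one bout into several runs. The pipeline merges gaps shorter than one
period of the slowest passband motion, `fs / f_low` (333 samples for the
tremor band) — the longest below-threshold dip a genuine bout can contain.
During rest there are no above-threshold runs to merge, so the wider gap
cannot extend a bout into the rest state. `segment_active` itself defaults
to the conservative N-sample gap.

**Component selection.** The "component time series" is the projection score
`A·v_k` (length T), the only object of the right length to feed the energy
stage; the series with maximal variance (equal to σ₁²/T on centered data) is
selected. The SVD's sign ambiguity is resolved by requiring nonnegative
sample skewness, so crests point upward as the peak finder assumes.
Zero-variance columns are dropped with a warning before the decomposition.
Multi-link recordings are handled by concatenating all links' subcarrier
columns before a single decomposition.

**Quantification conventions.** `mean_frequency = (count − 1)/(span of
crests)`: it is insensitive to how much quiet margin segmentation attaches
to either end of the bout, unlike `count/duration`. With fewer than two
crests the rate is reported as 0 rather than extrapolated. The ruler preset
reports frequency but not duration (nan): a decaying vibration has no
detectable endpoint. Topographic prominence is used for the prominence
criterion: crest height above the higher of the two flanking key valleys,
walking outward to the nearest strictly higher sample or the series edge.
The separation criterion is enforced greedily, keeping the highest surviving
crest first with earlier-index tie-breaks; this matches an exhaustive
filter-then-greedy oracle exactly (tested on random series).

## Synthetic data

The simulator emulates the study conditions: 20 s trials at 1000 Hz with
180 subcarriers (6 streams × 30), a 4.2 m × 7.9 m room with a 2 m link,
motion 1 m from the LoS midpoint, a 5 s static lead-in and a 10 s bout from
the 6th second. Motion waveforms are built cycle-by-cycle so the generator
reports an exact answer key (cycle count, crest times, per-cycle
frequencies):

- **resting tremor** — sinusoid cycles whose frequency is redrawn uniformly
  from [3, 6] Hz per cycle, displacement ~9 cm; the final cycle's period is
  stretched to fill the bout exactly when the implied frequency stays in
  range, otherwise a residual shorter than one fastest-cycle period is left
  quiet;
- **finger tapping** — raised-cosine pulses at ~1 Hz, 8 cm (one strong
  impulse per tap);
- **ruler vibration** — an exponentially damped sinusoid from a 10 cm
  initial deflection at a fixed 3.46 Hz.

Ground-truth mean frequency uses the same fencepost convention as the
estimator, computed from crest times, so estimate and truth are directly
comparable.

Two channel modes exist. The **geometric** mode (default) computes the
reflected path length `d(t) = |tx − p(t)| + |p(t) − rx|` and sets
`H(t, i) = static_i + g·exp(−j2πd(t)/λᵢ)`, with per-subcarrier wavelengths
spanning a 20 MHz band at 5 GHz and random static multipath gains; with
~9 cm displacement at λ ≈ 6 cm each motion cycle sweeps several Fresnel
fringes, as real CSI does, and motion tangential to the path-length gradient
is invisible (the directional effect). The **direct** mode modulates each
subcarrier's amplitude by the unit motion waveform
(`baseline + gain·u(t)`), producing exactly one amplitude crest per cycle;
it is the mode with closed-form expectations and is what end-to-end recovery
tests use. Defaults: baseline 1.0, gain 0.2, complex-noise component sd
0.04, giving an amplitude SNR of `(0.2²/2)/0.04² ≈ 11 dB`. Fixed seeds give
bit-identical recordings.

Artifacts: `inject_packet_loss` replaces each time step, with the given
probability, by a repeat of the previous retained row (the receiver's
repeat-logging during dropouts); `inject_slow_response` applies a linear
attack/release envelope to the motion-induced component (recovered as the
deviation from the lead-in mean), shrinking the first and last waves of the
bout. The reference-trace generator differentiates the displacement twice,
resamples to the 200 Hz wearable-sensor rate, negates (a mounting-sign
choice that aligns acceleration crests with displacement crests) and adds
Gaussian sensor noise (sd 0.05 m/s²). `quantify_reference` rescales the
smoothing window to the sensor rate (101 samples at 1000 Hz → 21 at 200 Hz);
an unscaled half-second window would flatten 3–6 Hz cycles.

**What the simulator does not model:** furniture/wall ray-tracing, moving
bystanders, hardware AGC, antenna coupling, or absolute channel gains.
Passing recovery tests therefore demonstrates the pipeline's correctness
under its stated signal model — coherent narrowband modulation over static
multipath with white noise and dropout artifacts — not the accuracy any
particular physical room will deliver, which is dominated by gains and
geometry the simulator leaves free.

## Evaluation layer

Accuracy is `100 − e` in percent with `e` the mean absolute relative error
(the absolute value is required for the complement to be meaningful).
Frequency accuracy compares mean-frequency estimates, count accuracy
compares counts; both are emitted. The accuracy contour interpolates
measured points linearly on a Delaunay triangulation over the measured half
of the room and answers queries on the far side by reflecting them across
the Fresnel symmetry axis (for a single link, the LoS centerline); queries
outside the measured convex hull are reported missing, never extrapolated.
The distance model is an OLS line of accuracy against LoS-perpendicular
distance with R². Validation-point discrepancy is |measured − mirrored
prediction|.

## Problem sizes in tests

End-to-end recovery tests run 20 seeded trials at the full study scale
(20 s × 1000 Hz × 180 subcarriers, direct mode); the smaller oracle and
property tests use series up to 2000 samples and matrices up to 200 × 12,
where exhaustive and closed-form references are exact and cheap.

## Known limitations

- One bout per recording is assumed (the longest merged run);
  `segment_active(..., return_all=True)` exposes all runs for multi-bout
  extensions but the pipeline does not iterate over them.
- Streaming/online operation is out of scope; recordings are processed in
  one block.
- Motion amplitude in physical units is not estimated — amplitude maps to
  fringe count nonlinearly and depends on unobservable channel gains.
- Ruler trials undercount late cycles by design: the decaying crests fall
  below the 0.2·max(Q) height criterion (frequency is still recovered from
  the surviving crests).
- Phase sanitization assumes offsets linear in subcarrier index; nonlinear
  hardware distortion is not corrected.
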