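"""Evaluation: error percentage, reference quantification, accuracy-vs-
distance regression and the mirrored accuracy contour.

Accuracy of the CSI estimate q against the wearable-sensor reference g is
the complement of the mean absolute relative error over N repetitions:

    e = (1/N) * sum_i |q_i - g_i| / g_i * 100 %,     accuracy = 100 - e.

Room-scale accuracy maps exploit the Fresnel-zone symmetry: a single Tx-Rx
link's zones are ellipses about the LoS, so accuracy measured on one side of
the LoS centerline mirrors to the other side.  Measured points are
interpolated linearly on a triangulation over the measured half and
reflected across the symmetry axis to fill the rest; validation points are
compared against the mirrored prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .quantification import (
    MotionQuantification,
    PeakCriteria,
    find_motion_peaks,
    quantify_motion,
    savgol_smooth,
)
from .segmentation import MotionSegment, segment_active, short_time_energy
from .synthetic import ReferenceTrace


@dataclass
class AccuracyReport:
    """Per-repetition estimates vs reference, and the derived accuracy."""

    q: np.ndarray
    g: np.ndarray
    error_pct: float
    accuracy_pct: float

    @property
    def n_reps(self) -> int:
        return self.q.size


def error_percentage(q: np.ndarray, g: np.ndarray) -> AccuracyReport:
    """Mean absolute relative error (in %) of estimates q against reference g."""
    q = np.asarray(q, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if q.size != g.size:
        raise ValueError("q and g must have the same length")
    if q.size == 0:
        raise ValueError("need at least one repetition")
    if np.any(g == 0):
        raise ValueError("reference contains zeros; relative error is undefined")
    e = float(np.mean(np.abs(q - g) / np.abs(g)) * 100.0)
    return AccuracyReport(q=q, g=g, error_pct=e, accuracy_pct=100.0 - e)


def quantify_reference(
    trace: ReferenceTrace,
    f_max: float,
    smooth_window: int | None = None,
    threshold_frac: float = 0.1,
    energy_window: int = 51,
) -> MotionQuantification:
    """Run the quantification stages on a wearable-sensor trace.

    Mirrors the CSI path at the sensor rate: energy segmentation, smoothing
    and the three-criterion peak finder, with min_separation =
    floor(fs / f_max).  The smoothing window defaults to the CSI window
    rescaled to the trace rate (101 samples at 1000 Hz -> 21 at 200 Hz),
    keeping the smoothed bandwidth comparable.
    """
    x = trace.values
    if np.all(x == 0):
        return quantify_motion(
            np.empty(0, dtype=int), MotionSegment(0, max(x.size, 1), trace.fs), trace.fs
        )
    if smooth_window is None:
        smooth_window = int(round(101 * trace.fs / 1000.0))
        if smooth_window % 2 == 0:
            smooth_window += 1
        smooth_window = max(smooth_window, 5)
    energy = short_time_energy(x, N=min(energy_window, x.size - (x.size + 1) % 2), window_kind="rectangular")
    segment = segment_active(energy, threshold_frac=threshold_frac, fs=trace.fs)
    if segment is None:
        return quantify_motion(np.empty(0, dtype=int), MotionSegment(0, x.size, trace.fs), trace.fs)
    windowed = x[segment.start_index : segment.end_index]
    Q = savgol_smooth(windowed, order=3, window=min(smooth_window, windowed.size - (windowed.size + 1) % 2))
    criteria = PeakCriteria(f_max=f_max, fs=trace.fs)
    peaks = find_motion_peaks(Q, criteria)
    return quantify_motion(peaks + segment.start_index, segment, trace.fs)


# ----------------------------------------------------------------- regression
@dataclass
class DistanceFit:
    """OLS line accuracy = slope * distance + intercept, with R^2."""

    slope: float
    intercept: float
    r_squared: float


def fit_accuracy_vs_distance(d_y: np.ndarray, accuracy: np.ndarray) -> DistanceFit:
    """Ordinary least-squares fit of accuracy (%) against distance (m)."""
    d = np.asarray(d_y, dtype=np.float64).ravel()
    a = np.asarray(accuracy, dtype=np.float64).ravel()
    if d.size != a.size or d.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(d) == 0:
        raise ValueError("distances are all equal; slope is undefined")
    X = np.column_stack([d, np.ones_like(d)])
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = a - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((a - a.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DistanceFit(slope=slope, intercept=intercept, r_squared=r2)


# -------------------------------------------------------------------- contour
@dataclass
class MirrorAxis:
    """Reflection line through ``point`` along unit ``direction``."""

    point: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be nonzero")
        self.direction = tuple(d / n)

    def reflect(self, xy: np.ndarray) -> np.ndarray:
        """Mirror points across the axis (an involution)."""
        p = np.atleast_2d(np.asarray(xy, dtype=np.float64)) - np.asarray(self.point)
        d = np.asarray(self.direction)
        proj = (p @ d)[:, None] * d[None, :]
        out = 2 * proj - p + np.asarray(self.point)
        return out if np.asarray(xy).ndim == 2 else out[0]

    def signed_side(self, xy: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(xy, dtype=np.float64)) - np.asarray(self.point)
        d = np.asarray(self.direction)
        return p[:, 0] * d[1] - p[:, 1] * d[0]


@dataclass
class ContourModel:
    """Accuracy surface from measured points on one side of a symmetry axis."""

    points: np.ndarray
    accuracy: np.ndarray
    axis: MirrorAxis
    validation_discrepancies: np.ndarray = field(default_factory=lambda: np.empty(0))
    _interp: LinearNDInterpolator = field(repr=False, default=None)

    def predict(self, xy: np.ndarray) -> np.ndarray:
        """Accuracy at query points; points on the unmeasured side are
        reflected into the measured half first.  Queries outside the convex
        hull of the measured points are NaN (missing), never extrapolated."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        measured_side = np.sign(np.median(self.axis.signed_side(self.points)))
        side = self.axis.signed_side(xy)
        mirrored = self.axis.reflect(xy)
        use_mirror = side * measured_side < 0
        queries = np.where(use_mirror[:, None], mirrored, xy)
        return self._interp(queries)

    def grid(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Accuracy evaluated on a mesh grid (NaN where missing)."""
        xx, yy = np.meshgrid(x, y)
        vals = self.predict(np.column_stack([xx.ravel(), yy.ravel()]))
        return xx, yy, vals.reshape(xx.shape)


def build_accuracy_contour(
    points: np.ndarray,
    accuracy: np.ndarray,
    axis: MirrorAxis | None = None,
    validation_points: np.ndarray | None = None,
    validation_accuracy: np.ndarray | None = None,
) -> ContourModel:
    """Interpolate measured (x, y, accuracy) points and mirror across the
    Fresnel symmetry axis.

    ``points`` must all lie on one (measured) side of the axis; queries on
    the other side are answered by reflection.  Optional validation points
    yield absolute discrepancies |measured - mirrored prediction|.
    """
    pts = np.asarray(points, dtype=np.float64)
    acc = np.asarray(accuracy, dtype=np.float64).ravel()
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] != acc.size:
        raise ValueError("points must be (n, 2) with matching accuracy values")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("points are collinear; triangulation is impossible")
    axis = axis or MirrorAxis()
    model = ContourModel(
        points=pts,
        accuracy=acc,
        axis=axis,
        _interp=LinearNDInterpolator(pts, acc),
    )
    if validation_points is not None:
        v_pts = np.asarray(validation_points, dtype=np.float64)
        v_acc = np.asarray(validation_accuracy, dtype=np.float64).ravel()
        pred = model.predict(v_pts)
        model.validation_discrepancies = np.abs(pred - v_acc)
    return model
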