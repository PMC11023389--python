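"""Signal conditioning and event extraction for throwing trials.

Covers the standard biomechanics preprocessing chain: zero-lag Butterworth
low-pass filtering, Winter-style residual analysis for cutoff selection,
stride-foot contact detection from vertical ground-reaction force, cubic
spline time-normalisation of the movement window, and extraction of the ball
release parameters (angle, speed, height) from a digitised 2D flight path.

The filter and normaliser are also exposed as scikit-learn style transformers
(:class:`ButterworthLowPass`, :class:`TimeNormaliser`) so they can slot into
sklearn pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .affordance import ReleaseParameters
from .kinematics import gradient_series

__all__ = [
    "BallTrajectory",
    "butterworth_lowpass_zero_lag",
    "residual_analysis",
    "detect_contact",
    "segment_and_normalise",
    "extract_release_parameters",
    "ButterworthLowPass",
    "TimeNormaliser",
    "NOT_FOUND",
]

NOT_FOUND = -1

# dual-pass cutoff correction so the -3 dB point of the effective 4th-order
# (2nd-order forward + backward) filter sits at the nominal fc
_DUAL_PASS_CORRECTION = 1.0 / (2 ** 0.5 - 1) ** 0.25  # ~1.2465


@dataclass
class BallTrajectory:
    """Digitised 2D ball path around release.

    x is horizontal toward the target, y vertical, both in image units times
    ``scale`` (m per image unit).  ``release_index`` marks the release frame;
    at least 10 samples on either side are expected when extraction is
    requested.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    release_index: int
    scale: float = 1.0

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")


def butterworth_lowpass_zero_lag(
    series: np.ndarray, fs: float, fc: float, order: int = 4, axis: int = 0
) -> np.ndarray:
    """Zero-lag low-pass Butterworth filter (forward-backward pass).

    An ``order``-th order zero-lag response is produced by one forward and one
    backward pass of an ``order/2``-order filter, with the design cutoff
    raised by the dual-pass correction factor so the -3 dB point of the
    combined response sits at ``fc`` — the convention used throughout
    biomechanics.  DC gain is exactly 1.

    Set ``order=8`` for the alternative (4th-order dual-pass) variant.
    """
    series = np.asarray(series, float)
    if not 0 < fc < fs / 2:
        raise ValueError("fc must lie in (0, fs/2)")
    half_order = max(order // 2, 1)
    fc_design = min(fc * _DUAL_PASS_CORRECTION, 0.999 * fs / 2)
    sos = signal.butter(half_order, fc_design, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, series, axis=axis)


def residual_analysis(
    series: np.ndarray,
    fs: float,
    fc_grid: np.ndarray,
    noise_fraction: float = 0.4,
    tol: float = None,
) -> float:
    """Recommend a low-pass cutoff by Winter's residual-analysis construction.

    The RMS residual between the raw and filtered series is computed on a
    grid of candidate cutoffs.  A straight line fitted to the high-frequency
    (noise-dominated) end of the residual curve — the top ``noise_fraction``
    of the grid — is extrapolated to fc = 0; its intercept estimates the
    noise RMS that an ideal cutoff would leave behind.  The recommended
    cutoff is the lowest grid frequency whose residual falls to that level
    (ties broken toward lower fc).  ``tol`` absorbs the degenerate noiseless
    case where the intercept is ~0; it defaults to 1% of the RMS of the series.
    """
    series = np.asarray(series, float)
    fc_grid = np.sort(np.asarray(fc_grid, float))
    if fc_grid[0] <= 0 or fc_grid[-1] >= fs / 2:
        raise ValueError("fc grid must lie within (0, fs/2)")
    if np.allclose(series, 0):
        warnings.warn("all-zero series: residual analysis is degenerate")
        return float(fc_grid[-1])
    residuals = np.array(
        [
            np.sqrt(np.mean((series - butterworth_lowpass_zero_lag(series, fs, fc)) ** 2))
            for fc in fc_grid
        ]
    )
    n_noise = max(int(round(noise_fraction * len(fc_grid))), 2)
    slope, intercept = np.polyfit(fc_grid[-n_noise:], residuals[-n_noise:], 1)
    level = max(intercept, 0.0)
    if tol is None:
        tol = 1e-2 * np.sqrt(np.mean(series**2))
    below = np.nonzero(residuals <= level + tol)[0]
    if below.size == 0:
        return float(fc_grid[-1])
    return float(fc_grid[below[0]])


def detect_contact(grf_vertical: np.ndarray, threshold: float = 10.0) -> int:
    """First sample where vertical ground-reaction force strictly exceeds
    ``threshold`` (study convention: 10 N); ``NOT_FOUND`` if never exceeded."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    idx = np.nonzero(np.asarray(grf_vertical, float) > threshold)[0]
    return int(idx[0]) if idx.size else NOT_FOUND


def segment_and_normalise(
    series: np.ndarray, start: int, end: int, n_out: int = 100
) -> np.ndarray:
    """Time-normalise ``series[start:end+1]`` to ``n_out`` samples by cubic
    spline, so every trial spans 0-100% of the movement on a common base.

    Output sample 0 equals ``series[start]`` and sample n_out-1 equals
    ``series[end]`` exactly (interpolation at the knots).
    """
    series = np.asarray(series, float)
    if end - start < 4:
        raise ValueError("segment must contain at least 5 samples")
    if not (0 <= start < end < series.shape[0]):
        raise ValueError("segment out of bounds")
    seg = series[start : end + 1]
    knots = np.arange(seg.shape[0], dtype=float)
    spline = CubicSpline(knots, seg, axis=0)
    phase = np.linspace(0.0, knots[-1], n_out)
    return spline(phase)


def extract_release_parameters(
    traj: BallTrajectory, fs: float, fc: float = 10.0
) -> ReleaseParameters:
    """Release angle, speed and height from a digitised ball path.

    The scaled x and y series are low-pass filtered (zero-lag, default
    10 Hz) and differentiated by central differences; at the release frame,
    speed = sqrt(Vx^2 + Vy^2), angle = atan2(Vy, Vx) in degrees above
    horizontal, and height is the filtered y coordinate.
    """
    i = traj.release_index
    if not 0 < i < len(traj.t) - 1:
        raise ValueError("release_index must be an interior sample")
    x = butterworth_lowpass_zero_lag(traj.x * traj.scale, fs, fc)
    y = butterworth_lowpass_zero_lag(traj.y * traj.scale, fs, fc)
    vx = gradient_series(x[:, None], fs)[:, 0]
    vy = gradient_series(y[:, None], fs)[:, 0]
    speed = float(np.hypot(vx[i], vy[i]))
    angle = float(np.degrees(np.arctan2(vy[i], vx[i])))
    return ReleaseParameters(angle=angle, speed=speed, height=float(y[i]))


class ButterworthLowPass(TransformerMixin, BaseEstimator):
    """Zero-lag Butterworth low-pass as a stateless sklearn transformer.

    Filters each column of X (samples along axis 0).
    """

    def __init__(self, fs: float = 250.0, fc: float = 10.0, order: int = 4):
        self.fs = fs
        self.fc = fc
        self.order = order

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if not 0 < self.fc < self.fs / 2:
            raise ValueError("fc must lie in (0, fs/2)")
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        return butterworth_lowpass_zero_lag(np.asarray(X, float), self.fs, self.fc, self.order)


class TimeNormaliser(TransformerMixin, BaseEstimator):
    """Cubic-spline time normalisation of a segment to ``n_out`` samples."""

    def __init__(self, n_out: int = 100):
        self.n_out = n_out

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        return segment_and_normalise(X, 0, X.shape[0] - 1, self.n_out)
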