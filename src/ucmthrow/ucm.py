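"""Uncontrolled-manifold (UCM) variance decomposition and the index of synergy.

The UCM method asks whether trial-to-trial variability of a redundant set of
elemental variables (here the n = 7 joint angles of the shoulder-elbow-wrist
chain) is structured to stabilise a lower-dimensional performance variable
(dimension d < n).  At each instant i of the time-normalised movement:

1.  A Jacobian J_i (d x n) linking mean-free joint-angle deviations to
    mean-free performance-variable deviations is estimated across trials by
    multiple linear regression (no intercept; both sides are mean-centred).
2.  The UCM is approximated by the null space of J_i, spanned by n - d
    orthonormal basis vectors eps.
3.  Each trial's joint-configuration deviation (theta - theta0) is projected
    onto the null space (theta_par) and its orthogonal complement
    (theta_perp).
4.  Variance per degree of freedom inside and orthogonal to the UCM:

        V_UCM = sum ||theta_par||^2  / ((n - d) * N_trials)
        V_ORT = sum ||theta_perp||^2 / (d * N_trials)

5.  The index of synergy:

        dV = (V_UCM - V_ORT) / V_TOT,
        V_TOT = (1/n) * (d * V_ORT + (n - d) * V_UCM),

    bounded in [-n/d, n/(n - d)].  dV > 0 indicates a synergy stabilising
    that performance variable.

Nine candidate performance variables are supported: hand orientation,
position and velocity, each in an internal (shoulder) or external (lab)
frame (d = 3), and the release-parameter analogues angle, speed, height
(external frame, d = 1).

The user-facing entry point is :class:`SynergyDecomposition`, a
scikit-learn style estimator fit on an (N_trials, T, 7) stack of joint-angle
series; the module-level functions implement the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.linalg import null_space as _scipy_null_space
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .kinematics import ArmModel, forward_kinematics, gradient_series

__all__ = [
    "TrialEnsemble",
    "PerformanceVariableSpec",
    "VarianceProfile",
    "ALL_PERFORMANCE_VARIABLES",
    "SynergyDecomposition",
    "mean_free",
    "pv_timeseries",
    "estimate_jacobian",
    "null_space_basis",
    "project_deviations",
    "variance_components",
    "index_of_synergy",
    "group_synergy",
    "proportion_above",
]

N_JOINTS = 7


@dataclass
class TrialEnsemble:
    """Stack of time-normalised joint-angle series for one condition.

    ``angles`` has shape (N_trials, T, 7), degrees, joints ordered wrist
    (q1-q3), elbow (q4), shoulder (q5-q7).
    """

    angles: np.ndarray
    participant: str = "P0"
    distance: float = 10.0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        if self.angles.ndim != 3 or self.angles.shape[2] != N_JOINTS:
            raise ValueError("angles must have shape (N_trials, T, 7)")
        if self.angles.shape[0] < 2:
            raise ValueError("need at least 2 trials")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.angles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.angles.shape[1]


@dataclass(frozen=True)
class PerformanceVariableSpec:
    """One candidate controlled quantity: its name, frame and dimension d."""

    name: str  # hand_orientation | hand_position | hand_velocity | release_*
    frame: str  # "internal" (shoulder) or "external" (lab)
    d: int

    def __post_init__(self):
        if not 0 < self.d < N_JOINTS:
            raise ValueError("pv dimension must satisfy 0 < d < 7")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.frame}"


ALL_PERFORMANCE_VARIABLES = tuple(
    [
        PerformanceVariableSpec(name, frame, 3)
        for name in ("hand_orientation", "hand_position", "hand_velocity")
        for frame in ("internal", "external")
    ]
    + [
        PerformanceVariableSpec(name, "external", 1)
        for name in ("release_angle", "release_speed", "release_height")
    ]
)


def get_pv_spec(name: str, frame: str = "external") -> PerformanceVariableSpec:
    for spec in ALL_PERFORMANCE_VARIABLES:
        if spec.name == name and spec.frame == frame:
            return spec
    raise KeyError(f"unknown performance variable {name!r} in frame {frame!r}")


@dataclass
class VarianceProfile:
    """Per-time-point variance components and synergy index for one analysis."""

    v_ucm: np.ndarray
    v_ort: np.ndarray
    v_tot: np.ndarray
    delta_v: np.ndarray
    pv: str = ""
    participant: str = ""
    distance: float = float("nan")
    n: int = N_JOINTS
    d: int = 1

    def proportion_above(self, threshold: float = 0.5) -> float:
        return proportion_above(self.delta_v, threshold)


# ---------------------------------------------------------------------------
# elemental-variable side


def mean_free(ensemble) -> tuple:
    """Split trials into the across-trial mean trajectory and deviations.

    Returns ``(theta0, deviations)`` with ``theta0`` of shape (T, 7) and
    ``deviations = angles - theta0`` of shape (N, T, 7); deviations sum to
    zero across trials at every (time, joint).
    """
    angles = ensemble.angles if isinstance(ensemble, TrialEnsemble) else np.asarray(ensemble, float)
    theta0 = angles.mean(axis=0)
    return theta0, angles - theta0


# ---------------------------------------------------------------------------
# performance-variable side


def _hand_states(angles_deg: np.ndarray, model: ArmModel):
    q = np.radians(angles_deg)
    return forward_kinematics(model, q)


def _orientation_angles(orientation: np.ndarray, frame: str, model: ArmModel) -> np.ndarray:
    """Hand orientation as unwrapped XYZ Euler angles (degrees), (N, T, 3)."""
    if frame == "external":
        orientation = np.einsum("ij,ntjk->ntik", model.thorax_orientation, orientation)
    N, T = orientation.shape[:2]
    eul = Rotation.from_matrix(orientation.reshape(-1, 3, 3)).as_euler("XYZ")
    eul = eul.reshape(N, T, 3)
    eul = np.unwrap(eul, axis=1)  # remove +-pi jumps along time
    return np.degrees(eul)


def pv_timeseries(
    ensemble,
    model: ArmModel,
    spec: PerformanceVariableSpec,
    fs_equivalent: float = 250.0,
    release_mode: str = "instantaneous",
) -> np.ndarray:
    """Per-trial time series of a performance variable, shape (N, T, d).

    Hand variables come from the forward-kinematic chain in the requested
    frame.  The release-parameter variables are instantaneous hand-based
    analogues in the lab's sagittal (y-z) plane — speed = |(v_y, v_z)|,
    angle = atan2(v_z, v_y) in degrees, height = hand z — which coincide
    with the ball's release parameters at the release sample.  With
    ``release_mode="constant"`` the value at the final (release) sample is
    used at every time point instead.
    """
    angles = ensemble.angles if isinstance(ensemble, TrialEnsemble) else np.asarray(ensemble, float)
    state = _hand_states(angles, model)
    pos = state.position_lab if spec.frame == "external" else state.position_shoulder

    if spec.name == "hand_position":
        out = pos
    elif spec.name == "hand_velocity":
        out = gradient_series(pos, fs_equivalent)
    elif spec.name == "hand_orientation":
        out = _orientation_angles(state.orientation, spec.frame, model)
    elif spec.name in ("release_angle", "release_speed", "release_height"):
        v = gradient_series(state.position_lab, fs_equivalent)
        if spec.name == "release_speed":
            out = np.hypot(v[..., 1], v[..., 2])[..., None]
        elif spec.name == "release_angle":
            out = np.degrees(np.arctan2(v[..., 2], v[..., 1]))[..., None]
        else:
            out = state.position_lab[..., 2][..., None]
        if release_mode == "constant":
            out = np.broadcast_to(out[:, -1:, :], out.shape).copy()
        elif release_mode != "instantaneous":
            raise ValueError(f"unknown release_mode {release_mode!r}")
    else:
        raise KeyError(f"unknown performance variable {spec.name!r}")
    if out.shape[-1] != spec.d:
        raise ValueError("pv dimension mismatch")
    return out


# ---------------------------------------------------------------------------
# the decomposition proper


def estimate_jacobian(dev_angles: np.ndarray, dev_pv: np.ndarray) -> np.ndarray:
    """Regression Jacobian at one time point.

    Each performance-variable component is regressed on the 7 mean-free
    joint angles without intercept (both sides are mean-free, so the
    intercept is analytically zero); the rows of the returned (d x 7)
    matrix are the coefficient vectors.  Solved by a rank-revealing least
    squares; a rank-deficient predictor matrix yields the minimum-norm
    solution with a warning.
    """
    dev_angles = np.atleast_2d(np.asarray(dev_angles, float))
    dev_pv = np.asarray(dev_pv, float)
    if dev_pv.ndim == 1:
        dev_pv = dev_pv[:, None]
    N, n = dev_angles.shape
    if N <= n:
        raise ValueError(f"need more trials than predictors (N={N}, n={n})")
    coef, _, rank, _ = np.linalg.lstsq(dev_angles, dev_pv, rcond=None)
    if rank < n:
        warnings.warn(
            f"rank-deficient joint-angle deviations (rank {rank} < {n}); "
            "minimum-norm Jacobian returned"
        )
    return coef.T


def null_space_basis(J: np.ndarray, tol: float = None) -> np.ndarray:
    """Orthonormal basis of the null space of J (the linearised UCM).

    Computed by SVD; the rank tolerance defaults to
    ``eps * max_singular_value * max(J.shape)``.  For a full-rank d x 7
    Jacobian the basis has 7 - d columns; a rank-deficient J yields
    7 - rank(J) columns (callers should check the width).
    """
    J = np.atleast_2d(np.asarray(J, float))
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian contains non-finite entries")
    basis = _scipy_null_space(J, rcond=tol)
    return basis


def _check_orthonormal(basis: np.ndarray, tol: float = 1e-8):
    G = basis.T @ basis
    if not np.allclose(G, np.eye(basis.shape[1]), atol=tol):
        raise ValueError("basis columns are not orthonormal")


def project_deviations(dev: np.ndarray, basis: np.ndarray) -> tuple:
    """Split deviations into components within and orthogonal to the UCM.

    ``theta_par = dev @ basis @ basis.T`` lies in span(basis);
    ``theta_perp = dev - theta_par``.  The two are orthogonal per trial and
    the projection is idempotent.
    """
    dev = np.atleast_2d(np.asarray(dev, float))
    basis = np.asarray(basis, float)
    _check_orthonormal(basis)
    theta_par = dev @ basis @ basis.T
    theta_perp = dev - theta_par
    return theta_par, theta_perp


def variance_components(
    theta_par: np.ndarray,
    theta_perp: np.ndarray,
    n: int = N_JOINTS,
    d: int = 1,
    ddof_compat: bool = False,
) -> tuple:
    """Variance per degree of freedom within (V_UCM) and orthogonal to
    (V_ORT) the UCM.

    Divisors are (n - d) * N and d * N with N the trial count, exactly as
    in the defining equations; ``ddof_compat=True`` swaps N for N - 1.
    """
    theta_par = np.atleast_2d(theta_par)
    theta_perp = np.atleast_2d(theta_perp)
    N = theta_par.shape[0]
    denom = N - 1 if ddof_compat else N
    v_ucm = float(np.sum(theta_par**2) / ((n - d) * denom))
    v_ort = float(np.sum(theta_perp**2) / (d * denom))
    return v_ucm, v_ort


def index_of_synergy(v_ucm, v_ort, n: int = N_JOINTS, d: int = 1) -> tuple:
    """Total variance per DOF and the index of synergy dV.

    ``V_TOT = (1/n) (d V_ORT + (n - d) V_UCM)``;
    ``dV = (V_UCM - V_ORT) / V_TOT``, bounded in [-n/d, n/(n-d)].
    A degenerate time point with V_TOT = 0 yields dV = NaN (missing), which
    the proportion summary then excludes.
    """
    v_ucm = np.asarray(v_ucm, float)
    v_ort = np.asarray(v_ort, float)
    v_tot = (d * v_ort + (n - d) * v_ucm) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        delta_v = np.where(v_tot > 0, (v_ucm - v_ort) / np.where(v_tot > 0, v_tot, 1.0), np.nan)
    if np.ndim(v_tot) == 0:
        return float(v_tot), float(delta_v)
    return v_tot, delta_v


def group_synergy(profiles: list) -> VarianceProfile:
    """Across-participant averaging scheme for the group synergy index.

    V_UCM and V_ORT are averaged across participants at each time point
    first, and the group dV is computed from those averaged components —
    not as the mean of per-participant dV values (the order of operations
    is observable and deliberate).
    """
    if not profiles:
        raise ValueError("need at least one participant profile")
    lengths = {len(p.v_ucm) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("participant profiles have mismatched time bases")
    n, d = profiles[0].n, profiles[0].d
    v_ucm = np.mean([p.v_ucm for p in profiles], axis=0)
    v_ort = np.mean([p.v_ort for p in profiles], axis=0)
    v_tot, delta_v = index_of_synergy(v_ucm, v_ort, n, d)
    return VarianceProfile(
        v_ucm=v_ucm,
        v_ort=v_ort,
        v_tot=v_tot,
        delta_v=delta_v,
        pv=profiles[0].pv,
        participant="group",
        distance=profiles[0].distance,
        n=n,
        d=d,
    )


def proportion_above(delta_v_series: np.ndarray, threshold: float = 0.5) -> float:
    """Proportion of time points with dV strictly above ``threshold``.

    Missing (NaN) points are excluded from both numerator and denominator;
    an all-missing series yields NaN.
    """
    x = np.asarray(delta_v_series, float)
    valid = np.isfinite(x)
    if not valid.any():
        return float("nan")
    return float(np.count_nonzero(x[valid] > threshold) / valid.sum())


# ---------------------------------------------------------------------------
# estimator


class SynergyDecomposition(BaseEstimator):
    """UCM variance decomposition of a trial ensemble for one performance
    variable, as a scikit-learn style estimator.

    Parameters
    ----------
    pv : str
        Performance variable: ``hand_orientation``, ``hand_position``,
        ``hand_velocity``, ``release_angle``, ``release_speed`` or
        ``release_height``.
    frame : {"external", "internal"}
        Frame of reference (release variables are external only).
    model : ArmModel or None
        Arm geometry for the forward-kinematic chain (default model if None).
    fs_equivalent : float
        Nominal sampling rate (Hz) assigned to the normalised time base when
        differentiating positions.
    release_mode : {"instantaneous", "constant"}
        Whether release-parameter variables use the instantaneous hand-based
        analogue at every time point, or the per-trial value at the release
        sample held constant.
    ddof_compat : bool
        Use N - 1 instead of N in the variance divisors.
    threshold : float
        Synergy threshold for the proportion summary.

    Attributes (after ``fit``)
    --------------------------
    mean_trajectory_ : (T, 7) mean joint-angle series (degrees)
    jacobians_ : (T, d, 7) per-time regression Jacobians
    v_ucm_, v_ort_, v_tot_, delta_v_ : (T,) variance profiles
    rank_deficient_ : (T,) bool, True where the Jacobian lost rank
    profile_ : VarianceProfile bundling the above
    """

    def __init__(
        self,
        pv: str = "hand_position",
        frame: str = "external",
        model: ArmModel = None,
        fs_equivalent: float = 250.0,
        release_mode: str = "instantaneous",
        ddof_compat: bool = False,
        threshold: float = 0.5,
    ):
        self.pv = pv
        self.frame = frame
        self.model = model
        self.fs_equivalent = fs_equivalent
        self.release_mode = release_mode
        self.ddof_compat = ddof_compat
        self.threshold = threshold

    def _resolve(self):
        spec = get_pv_spec(self.pv, self.frame)
        model = self.model if self.model is not None else ArmModel()
        return spec, model

    def fit(self, X, y=None, pv_values: np.ndarray = None):
        """Decompose an (N_trials, T, 7) joint-angle ensemble (degrees).

        ``pv_values`` (N, T, d) overrides the kinematically computed
        performance-variable series — used for synthetic ensembles whose
        performance variable is an explicit linear map of the angles.
        """
        ensemble = X if isinstance(X, TrialEnsemble) else TrialEnsemble(np.asarray(X, float))
        spec, model = self._resolve()
        theta0, dev = mean_free(ensemble)
        if pv_values is None:
            pv_values = pv_timeseries(
                ensemble, model, spec, self.fs_equivalent, self.release_mode
            )
        pv_values = np.asarray(pv_values, float)
        dev_pv = pv_values - pv_values.mean(axis=0)

        N, T, n = ensemble.angles.shape
        d = spec.d
        jac = np.empty((T, d, n))
        v_ucm = np.empty(T)
        v_ort = np.empty(T)
        rank_flag = np.zeros(T, dtype=bool)
        for i in range(T):
            J = estimate_jacobian(dev[:, i, :], dev_pv[:, i, :])
            basis = null_space_basis(J)
            rank_flag[i] = basis.shape[1] != n - d
            par, perp = project_deviations(dev[:, i, :], basis)
            v_ucm[i], v_ort[i] = variance_components(
                par, perp, n=n, d=d, ddof_compat=self.ddof_compat
            )
            jac[i] = J
        v_tot, delta_v = index_of_synergy(v_ucm, v_ort, n=n, d=d)

        self.mean_trajectory_ = theta0
        self.jacobians_ = jac
        self.v_ucm_ = v_ucm
        self.v_ort_ = v_ort
        self.v_tot_ = v_tot
        self.delta_v_ = delta_v
        self.rank_deficient_ = rank_flag
        self.n_features_in_ = n
        self.profile_ = VarianceProfile(
            v_ucm=v_ucm,
            v_ort=v_ort,
            v_tot=v_tot,
            delta_v=delta_v,
            pv=spec.label,
            participant=getattr(ensemble, "participant", ""),
            distance=getattr(ensemble, "distance", float("nan")),
            n=n,
            d=d,
        )
        return self

    def proportion_above(self, threshold: float = None) -> float:
        """Proportion of the movement with a synergy (dV above threshold)."""
        if not hasattr(self, "delta_v_"):
            raise AttributeError("estimator is not fitted")
        thr = self.threshold if threshold is None else threshold
        return proportion_above(self.delta_v_, thr)

    def score(self, X=None, y=None) -> float:
        """Mean synergy index across the movement (NaN-aware)."""
        if not hasattr(self, "delta_v_"):
            raise AttributeError("estimator is not fitted")
        return float(np.nanmean(self.delta_v_))
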