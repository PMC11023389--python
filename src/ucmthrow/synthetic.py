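"""Synthetic data with known synergy structure.

Every downstream stage of the analysis is validated against data whose
ground truth is known by construction: joint-angle trial ensembles whose
trial-to-trial deviations carry a prescribed variance inside a known null
space (and its orthogonal complement), ball flights sampled from the
projectile simulator, step-like ground-reaction-force traces, and a full
on-disk study layout (participants x distances x trials) mirroring the
pipeline's reader contract.

Deviations are drawn i.i.d. across time points by default (the UCM
estimator treats time points independently); an optional AR(1) smoothness
parameter introduces temporal correlation when wanted.  Angles are stored
in degrees on disk and in ensembles; kinematics converts internally.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import affordance as aff
from .affordance import Environment, ReleaseParameters, TargetSpec
from .kinematics import ArmModel, position_jacobian_fd
from .preprocess import BallTrajectory
from .ucm import TrialEnsemble, null_space_basis

__all__ = [
    "SyntheticSpec",
    "ThrowScenario",
    "StudyConfig",
    "generate_mean_trajectory",
    "generate_ensemble",
    "generate_ball_flight",
    "generate_grf_trace",
    "jacobian_basis_field",
    "generate_study_dataset",
    "load_study_dataset",
    "nominal_release_for",
]

STUDY_DISTANCES = (5.0, 10.0, 15.0)


@dataclass
class SyntheticSpec:
    """Conditions under which synthetic ensembles are generated.

    ``v_ucm_target`` / ``v_ort_target`` are the injected trial-to-trial
    variances per DOF (deg^2) inside and orthogonal to the null space.
    The defaults (4 and 1 deg^2) give an analytic synergy index of 0.84
    for d = 1 — a clearly positive synergy at realistic joint-angle
    variability of a practised throw.
    """

    n_participants: int = 7
    n_trials: int = 20
    n_samples: int = 100
    n_joints: int = 7
    v_ucm_target: float = 4.0
    v_ort_target: float = 1.0
    pv_dim: int = 3
    seed: int = 0
    amplitude: float = 30.0  # deg, scale of the sinusoidal mean trajectory
    ar1_rho: float = 0.0  # temporal correlation of deviations (off by default)

    def __post_init__(self):
        if self.pv_dim not in (1, 3):
            raise ValueError("pv_dim must be 1 or 3")
        if self.n_joints <= self.pv_dim:
            raise ValueError("need more elemental than performance DOFs")
        if self.v_ucm_target < 0 or self.v_ort_target < 0:
            raise ValueError("variance targets must be non-negative")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")


def _trajectory_components(spec: SyntheticSpec, rng: np.random.Generator):
    """Sinusoid parameters of the mean trajectory (per joint, <= 3 terms)."""
    n_terms = 3
    offsets = rng.uniform(-40.0, 40.0, size=spec.n_joints)
    raw = rng.uniform(0.2, 1.0, size=(spec.n_joints, n_terms))
    amps = spec.amplitude * raw / raw.sum(axis=1, keepdims=True)
    freqs = rng.uniform(0.5, 2.5, size=(spec.n_joints, n_terms))  # cycles/movement
    phases = rng.uniform(0, 2 * math.pi, size=(spec.n_joints, n_terms))
    return offsets, amps, freqs, phases


def generate_mean_trajectory(spec: SyntheticSpec, rng=None) -> np.ndarray:
    """Smooth mean joint-angle trajectory, shape (n_samples, n_joints), deg.

    Each joint is an offset plus a sum of three sinusoids over the movement
    phase (C-infinity smooth by construction), with total amplitude bounded
    by ``spec.amplitude`` so angles stay within anatomical range.
    Deterministic for a given seed.
    """
    if abs(spec.amplitude) > 140:
        raise ValueError("amplitude too large for anatomical bounds")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    offsets, amps, freqs, phases = _trajectory_components(spec, rng)
    phase = np.linspace(0.0, 1.0, spec.n_samples)[:, None, None]
    waves = amps * np.sin(2 * math.pi * freqs * phase + phases)
    return offsets + waves.sum(axis=2)


def _complement(basis: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of span(basis)."""
    return null_space_basis(basis.T)


def _check_basis_field(basis_field: np.ndarray):
    T = basis_field.shape[0]
    for i in range(T):
        B = basis_field[i]
        if not np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-8):
            raise ValueError(f"basis at time {i} is not orthonormal")


def generate_ensemble(
    mean: np.ndarray,
    basis_field: np.ndarray,
    spec: SyntheticSpec,
    rng=None,
    participant: str = "P0",
    distance: float = 10.0,
) -> TrialEnsemble:
    """Trial ensemble with prescribed variance split about a known null space.

    At each time point the deviation of each trial is Gaussian with variance
    ``v_ucm_target`` per DOF inside span(basis) and ``v_ort_target`` per DOF
    in the orthogonal complement; components are drawn independently, so the
    parallel and orthogonal parts are uncorrelated.  With ``ar1_rho > 0``
    the component scores follow an AR(1) process along time instead of being
    i.i.d.
    """
    angles = _ensemble_angles(mean, basis_field, spec, rng)
    return TrialEnsemble(angles, participant=participant, distance=distance)


def _ensemble_angles(mean, basis_field, spec, rng=None) -> np.ndarray:
    """Raw (N, T, n) angle stack behind :func:`generate_ensemble` (also used
    when writing datasets with fewer than two trials per condition)."""
    mean = np.asarray(mean, float)
    basis_field = np.asarray(basis_field, float)
    T, n = mean.shape
    if basis_field.shape[0] != T or basis_field.shape[1] != n:
        raise ValueError("basis_field must have shape (T, n, n-d)")
    _check_basis_field(basis_field)
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    m = basis_field.shape[2]
    d = n - m
    comp_field = np.stack([_complement(basis_field[i]) for i in range(T)])

    def draw(size):
        z = rng.standard_normal(size)  # (N, T, k)
        if spec.ar1_rho > 0:
            rho = spec.ar1_rho
            out = np.empty_like(z)
            out[:, 0] = z[:, 0]
            for t in range(1, size[1]):
                out[:, t] = rho * out[:, t - 1] + math.sqrt(1 - rho**2) * z[:, t]
            z = out
        return z

    N = spec.n_trials
    c_par = math.sqrt(spec.v_ucm_target) * draw((N, T, m))
    c_perp = math.sqrt(spec.v_ort_target) * draw((N, T, d))
    dev = np.einsum("tnm,atm->atn", basis_field, c_par) + np.einsum(
        "tnm,atm->atn", comp_field, c_perp
    )
    return mean + dev


def jacobian_basis_field(
    mean_deg: np.ndarray, model: ArmModel = None, d: int = 3, frame: str = "external"
) -> np.ndarray:
    """Ground-truth null-space basis field along a mean trajectory.

    Runs the finite-difference position Jacobian of the kinematic chain at
    every mean configuration and takes its null space, so the generator's
    injected structure is consistent with what the estimator should recover.
    For d = 1 the vertical (hand height) row of the Jacobian is used; for
    d = 3 the full position Jacobian.
    """
    model = model if model is not None else ArmModel()
    mean_rad = np.radians(np.asarray(mean_deg, float))
    T, n = mean_rad.shape
    field_ = np.empty((T, n, n - d))
    for i in range(T):
        J = position_jacobian_fd(model, mean_rad[i], frame=frame)
        if d == 1:
            J = J[2:3, :]
        elif d != 3:
            raise ValueError("d must be 1 or 3")
        basis = null_space_basis(J)
        if basis.shape[1] != n - d:
            raise ValueError(f"degenerate Jacobian at time {i}")
        field_[i] = basis
    return field_


def generate_ball_flight(
    release: ReleaseParameters,
    env: Environment = Environment(),
    fs: float = 250.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_before: int = 25,
    n_after: int = 25,
) -> BallTrajectory:
    """Digitised-ball-path fixture around a release event.

    Post-release samples step the projectile simulator at 1/fs; pre-release
    samples continue the same flight solution backward in time (the fixture
    needs at least 10 frames on either side of release for extraction).
    I.i.d. Gaussian position noise of ``noise_sd`` metres emulates
    digitisation error.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_after < 10 or n_before < 10:
        raise ValueError("need at least 10 samples on either side of release")
    dt = 1.0 / fs
    km, g = env.drag_factor, env.g
    vx0, vy0 = release.velocity
    state0 = np.array([0.0, release.height, vx0, vy0])

    back = []
    state = state0.copy()
    for _ in range(n_before):
        state = aff.rk4_step(state, -dt, km, g)
        back.append(state.copy())
    fwd = []
    state = state0.copy()
    for _ in range(n_after):
        state = aff.rk4_step(state, dt, km, g)
        fwd.append(state.copy())
    states = np.array(back[::-1] + [state0] + fwd)

    t = np.arange(-n_before, n_after + 1) * dt
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(len(t), 2)) if noise_sd > 0 else 0.0
    xy = states[:, :2] + noise
    return BallTrajectory(t=t, x=xy[:, 0], y=xy[:, 1], release_index=n_before)


def generate_grf_trace(
    fs: float = 1000.0,
    duration: float = 1.0,
    contact_time: float = 0.3,
    peak: float = 900.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Vertical ground-reaction-force trace with a single loading event.

    Zero (plus sensor noise) before ``contact_time``, then a rapid sigmoid
    rise to ``peak`` newtons — enough structure to exercise threshold-based
    contact detection.
    """
    t = np.arange(0.0, duration, 1.0 / fs)
    rise = 1.0 / (1.0 + np.exp(-(t - contact_time - 0.02) / 0.005))
    fz = peak * rise * (t >= contact_time)
    rng = np.random.default_rng(seed)
    fz = fz + rng.normal(0.0, noise_sd, size=t.shape)
    return t, fz


@dataclass(frozen=True)
class ThrowScenario:
    """A target distance with a nominal release that hits it.

    The nominal release must intercept the target under the drag-free
    closed form before the scenario is accepted.
    """

    distance: float
    target: TargetSpec
    nominal_release: ReleaseParameters

    def __post_init__(self):
        y = aff.closed_form_height_at(
            self.target.distance,
            self.nominal_release.speed,
            self.nominal_release.angle,
            self.nominal_release.height,
        )
        if not abs(y - self.target.centre_height) <= self.target.height / 2:
            raise ValueError(
                f"nominal release misses the target (y at plane = {y:.3f} m)"
            )


_NOMINAL_ANGLE = {5.0: 6.0, 10.0: 12.0, 15.0: 18.0}
_NOMINAL_HEIGHT = {5.0: 1.85, 10.0: 1.90, 15.0: 1.95}


def nominal_release_for(distance: float, g: float = aff.GRAVITY) -> ThrowScenario:
    """Scenario whose drag-free flight passes through the target centre.

    The release angle and height grow mildly with distance (6-18 deg,
    1.85-1.95 m); the speed is solved from the drag-free trajectory equation
    so the ball crosses the plane exactly at the target centre.
    """
    target = TargetSpec(distance=distance)
    angle = _NOMINAL_ANGLE.get(distance, 6.0 + 1.2 * (distance - 5.0))
    height = _NOMINAL_HEIGHT.get(distance, 1.9)
    th = math.radians(angle)
    drop = height + distance * math.tan(th) - target.centre_height
    if drop <= 0:
        raise ValueError("target centre unreachable at this angle/height")
    v = math.sqrt(g * distance**2 / (2 * math.cos(th) ** 2 * drop))
    release = ReleaseParameters(angle=angle, speed=v, height=height)
    return ThrowScenario(distance=distance, target=target, nominal_release=release)


@dataclass
class StudyConfig:
    """Layout and conditions of a full synthetic study."""

    out_dir: str
    n_participants: int = 7
    distances: tuple = STUDY_DISTANCES
    n_trials: int = 20
    n_samples: int = 100
    v_ucm_target: float = 4.0
    v_ort_target: float = 1.0
    pv_dim: int = 3
    pv_frame: str = "external"
    seed: int = 0
    release_jitter: tuple = (2.0, 0.5, 0.03)  # sd of angle (deg), speed (m/s), height (m)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def generate_study_dataset(config: StudyConfig) -> dict:
    """Write a participant/distance/trial CSV tree plus manifest.

    Layout: ``P{id}/D{distance}/T{trial}.csv`` with header
    ``time_pct,q1,...,q7`` (angles in degrees), a per-trial release table
    ``releases.csv``, and ``manifest.json`` recording seeds, injected
    variance targets and per-file checksums.  Re-running the same config
    reproduces identical bytes.
    """
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    model = ArmModel()
    time_pct = np.linspace(0.0, 100.0, config.n_samples)

    files = {}
    release_rows = []
    truth = []
    child_seeds = ss.generate_state(config.n_participants * len(config.distances) * 2)
    k = 0
    for p in range(1, config.n_participants + 1):
        for dist in config.distances:
            spec = SyntheticSpec(
                n_trials=config.n_trials,
                n_samples=config.n_samples,
                v_ucm_target=config.v_ucm_target,
                v_ort_target=config.v_ort_target,
                pv_dim=config.pv_dim,
                seed=int(child_seeds[k] % 2**31),
            )
            rng = np.random.default_rng(spec.seed)
            mean = generate_mean_trajectory(spec, rng)
            basis_field = jacobian_basis_field(
                mean, model, d=config.pv_dim, frame=config.pv_frame
            )
            angles = _ensemble_angles(mean, basis_field, spec, rng)
            cond_dir = root / f"P{p}" / f"D{int(dist)}"
            cond_dir.mkdir(parents=True, exist_ok=True)
            for tr in range(1, config.n_trials + 1):
                df = pd.DataFrame(
                    angles[tr - 1], columns=[f"q{j}" for j in range(1, 8)]
                )
                df.insert(0, "time_pct", time_pct)
                path = cond_dir / f"T{tr}.csv"
                df.to_csv(path, index=False, float_format="%.10g")
                files[str(path.relative_to(root))] = _md5(path)

            scenario = nominal_release_for(dist)
            rel_seed = int(child_seeds[k + 1] % 2**31)
            rel_rng = np.random.default_rng(rel_seed)
            sd_a, sd_s, sd_h = config.release_jitter
            nom = scenario.nominal_release
            for tr in range(1, config.n_trials + 1):
                release_rows.append(
                    {
                        "participant": f"P{p}",
                        "distance": dist,
                        "trial": tr,
                        "release_angle": nom.angle + rel_rng.normal(0, sd_a),
                        "release_speed": max(nom.speed + rel_rng.normal(0, sd_s), 0.1),
                        "release_height": nom.height + rel_rng.normal(0, sd_h),
                    }
                )
            truth.append(
                {
                    "participant": f"P{p}",
                    "distance": dist,
                    "seed": spec.seed,
                    "release_seed": rel_seed,
                    "v_ucm_target": config.v_ucm_target,
                    "v_ort_target": config.v_ort_target,
                    "pv_dim": config.pv_dim,
                    "pv_frame": config.pv_frame,
                }
            )
            k += 2

    rel_df = pd.DataFrame(release_rows)
    rel_path = root / "releases.csv"
    rel_df.to_csv(rel_path, index=False, float_format="%.10g")
    files["releases.csv"] = _md5(rel_path)

    manifest = {
        "config": asdict(config),
        "ground_truth": truth,
        "files": dict(sorted(files.items())),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_study_dataset(path) -> tuple:
    """Read a dataset written by :func:`generate_study_dataset`.

    Returns ``(ensembles, releases, manifest)``: a dict keyed by
    ``(participant, distance)`` of :class:`TrialEnsemble`, the per-trial
    release-parameter table, and the manifest dict.
    """
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    releases = pd.read_csv(root / "releases.csv")
    ensembles = {}
    for pdir in sorted(root.glob("P*")):
        for ddir in sorted(pdir.glob("D*")):
            dist = float(ddir.name[1:])
            trials = []
            for tpath in sorted(ddir.glob("T*.csv"), key=lambda p: int(p.stem[1:])):
                df = pd.read_csv(tpath)
                trials.append(df[[f"q{j}" for j in range(1, 8)]].to_numpy())
            ensembles[(pdir.name, dist)] = TrialEnsemble(
                np.stack(trials), participant=pdir.name, distance=dist
            )
    return ensembles, releases, manifest
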