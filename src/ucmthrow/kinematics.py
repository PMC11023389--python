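"""Forward kinematics of a 7-DOF throwing arm.

A four-segment chain (thorax, upper arm, forearm, hand) maps the seven joint
angles of the shoulder-elbow-wrist system to the position, orientation and
velocity of the hand, expressed either in an internal frame (relative to the
shoulder) or in the external laboratory frame.

Conventions
-----------
Axes follow the ISB recommendation: +z vertically upward, +y anterior
(toward the target), +x lateral (to the right).  The lab-frame origin sits at
the centre of the force platform.  In the reference pose (all angles zero) the
arm hangs along -z with the hand aligned to the forearm; this zero pose is a
documented constant of the model.

The seven angles are ordered wrist (q1, q2, q3), elbow (q4), shoulder
(q5, q6, q7).  The shoulder rotates relative to the thorax through an
intrinsic ZYZ Euler sequence; the elbow and wrist rotate relative to their
proximal segment through an intrinsic XYZ Cardan sequence (the elbow uses only
its first axis, flexion-extension; forearm pronation-supination is carried as
the wrist's axial rotation in the default layout).  An alternative layout with
two elbow DOFs is available through ``dof_layout``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ArmModel",
    "rotation_from_euler",
    "forward_kinematics",
    "hand_state_series",
    "hand_velocity",
    "position_jacobian_fd",
]

# direction of each segment in its local frame at the reference pose
_SEGMENT_AXIS = np.array([0.0, 0.0, -1.0])

_SUPPORTED_SEQUENCES = ("ZYZ", "XYZ")

#: default layout: shoulder 3 DOF, elbow 1 DOF, wrist 3 DOF
DOF_LAYOUT_3_1_3 = ("wrist:XYZ:3", "elbow:X:1", "shoulder:ZYZ:3")
#: alternative layout: shoulder 3 DOF, elbow 2 DOF (flexion + pro/supination), wrist 2 DOF
DOF_LAYOUT_3_2_2 = ("wrist:XY:2", "elbow:XZ:2", "shoulder:ZYZ:3")


class ConfigurationError(ValueError):
    """Raised when a model or sequence specification is invalid."""


@dataclass
class ArmModel:
    """Geometry and frame layout of the throwing arm.

    Segment lengths are in metres.  The defaults (0.30 / 0.27 / 0.08 m) are
    plausible adult values used for synthetic work, not measured quantities.
    """

    upper_arm_length: float = 0.30
    forearm_length: float = 0.27
    hand_length: float = 0.08
    shoulder_position_lab: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.45])
    )
    thorax_orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    dof_layout: tuple = DOF_LAYOUT_3_1_3

    def __post_init__(self):
        self.shoulder_position_lab = np.asarray(self.shoulder_position_lab, float)
        self.thorax_orientation = np.asarray(self.thorax_orientation, float)
        if min(self.upper_arm_length, self.forearm_length, self.hand_length) <= 0:
            raise ConfigurationError("segment lengths must be positive")
        R = self.thorax_orientation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-12) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-12
        ):
            raise ConfigurationError("thorax_orientation must be a proper rotation")
        n_dof = sum(int(part.split(":")[2]) for part in self.dof_layout)
        if n_dof != 7:
            raise ConfigurationError(
                f"dof_layout must cover exactly 7 angles, got {n_dof}"
            )

    @property
    def reach(self) -> float:
        return self.upper_arm_length + self.forearm_length + self.hand_length

    def to_json(self) -> str:
        return json.dumps(
            {
                "upper_arm_length": self.upper_arm_length,
                "forearm_length": self.forearm_length,
                "hand_length": self.hand_length,
                "shoulder_position_lab": self.shoulder_position_lab.tolist(),
                "thorax_orientation": self.thorax_orientation.ravel().tolist(),
                "dof_layout": list(self.dof_layout),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ArmModel":
        d = json.loads(text)
        return cls(
            upper_arm_length=d["upper_arm_length"],
            forearm_length=d["forearm_length"],
            hand_length=d["hand_length"],
            shoulder_position_lab=np.array(d["shoulder_position_lab"]),
            thorax_orientation=np.array(d["thorax_orientation"]).reshape(3, 3),
            dof_layout=tuple(d["dof_layout"]),
        )


def rotation_from_euler(sequence: str, angles: np.ndarray) -> np.ndarray:
    """Proper rotation matrix from an intrinsic Euler/Cardan sequence.

    Parameters
    ----------
    sequence : {"ZYZ", "XYZ"}
        Intrinsic axis sequence (shoulder uses ZYZ, elbow/wrist XYZ).
    angles : array-like, shape (3,) or (..., 3)
        Rotation angles in radians.

    Returns
    -------
    ndarray, shape (3, 3) or (..., 3, 3)
    """
    if sequence not in _SUPPORTED_SEQUENCES:
        raise ConfigurationError(f"unsupported Euler sequence {sequence!r}")
    return Rotation.from_euler(sequence, np.asarray(angles, float)).as_matrix()


def euler_from_rotation(sequence: str, R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rotation_from_euler` (away from gimbal lock)."""
    if sequence not in _SUPPORTED_SEQUENCES:
        raise ConfigurationError(f"unsupported Euler sequence {sequence!r}")
    return Rotation.from_matrix(np.asarray(R, float)).as_euler(sequence)


def _segment_rotations(model: ArmModel, q: np.ndarray):
    """Per-joint rotation matrices (batched over leading axes of q)."""
    q = np.asarray(q, float)
    batch = q.shape[:-1]
    rots = {}
    idx = 0
    for part in model.dof_layout:
        joint, axes, n = part.split(":")
        n = int(n)
        if len(axes) != n:
            raise ConfigurationError(f"bad dof_layout entry {part!r}")
        block = q[..., idx : idx + n]
        idx += n
        R = Rotation.from_euler(axes, block.reshape(-1, n)).as_matrix()
        rots[joint] = R.reshape(batch + (3, 3))
    return rots


def _chain(model: ArmModel, q: np.ndarray):
    """Hand position (shoulder frame) and hand orientation for batched q (rad)."""
    rots = _segment_rotations(model, q)
    R_sh, R_el, R_wr = rots["shoulder"], rots["elbow"], rots["wrist"]
    a = _SEGMENT_AXIS
    # chain from distal to proximal: hand tip in shoulder frame
    p_hand_in_wrist = model.hand_length * a
    p_wrist = model.forearm_length * a + np.einsum("...ij,j->...i", R_wr, p_hand_in_wrist)
    p_elbow = model.upper_arm_length * a + np.einsum("...ij,...j->...i", R_el, p_wrist)
    position_shoulder = np.einsum("...ij,...j->...i", R_sh, p_elbow)
    orientation = R_sh @ R_el @ R_wr
    return position_shoulder, orientation


@dataclass
class HandState:
    """Pose of the hand for one joint configuration."""

    position_lab: np.ndarray
    position_shoulder: np.ndarray
    orientation: np.ndarray  # hand w.r.t. thorax (internal) frame


def forward_kinematics(model: ArmModel, q: np.ndarray) -> HandState:
    """Map a 7-vector of joint angles (radians) to the hand state.

    ``position_lab = shoulder_position_lab + thorax_orientation @ position_shoulder``.
    """
    q = np.asarray(q, float)
    if q.shape[-1] != 7:
        raise ValueError("q must have 7 angles")
    p_sh, R = _chain(model, q)
    p_lab = model.shoulder_position_lab + np.einsum(
        "ij,...j->...i", model.thorax_orientation, p_sh
    )
    return HandState(position_lab=p_lab, position_shoulder=p_sh, orientation=R)


def hand_state_series(model: ArmModel, q_series: np.ndarray) -> HandState:
    """Vectorised :func:`forward_kinematics` over a (..., 7) series of angles."""
    return forward_kinematics(model, q_series)


def hand_velocity(
    model: ArmModel, q_series: np.ndarray, fs: float, frame: str = "external"
) -> np.ndarray:
    """Hand translational velocity from a T x 7 angle series (radians).

    Central differences at interior samples, one-sided at the endpoints.
    """
    q_series = np.asarray(q_series, float)
    if q_series.ndim < 2 or q_series.shape[-2] < 3:
        raise ValueError("need at least 3 time samples")
    state = forward_kinematics(model, q_series)
    pos = state.position_lab if frame == "external" else state.position_shoulder
    return gradient_series(pos, fs)


def gradient_series(x: np.ndarray, fs: float) -> np.ndarray:
    """Time derivative along axis -2: central differences, one-sided endpoints."""
    return np.gradient(np.asarray(x, float), 1.0 / fs, axis=-2)


def position_jacobian_fd(
    model: ArmModel, q: np.ndarray, h: float = 1e-6, frame: str = "external"
) -> np.ndarray:
    """Central-difference Jacobian of hand position w.r.t. the 7 angles (3 x 7).

    Serves as the ground-truth oracle against which the per-time regression
    estimate of the Jacobian is validated; error decreases as O(h^2).
    """
    if not 0 < h <= 1e-2:
        raise ValueError("h must be in (0, 1e-2]")
    q = np.asarray(q, float)
    steps = h * np.eye(7)
    qp = q + steps
    qm = q - steps
    state_p = forward_kinematics(model, qp)
    state_m = forward_kinematics(model, qm)
    attr = "position_lab" if frame == "external" else "position_shoulder"
    return (getattr(state_p, attr) - getattr(state_m, attr)).T / (2 * h)
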