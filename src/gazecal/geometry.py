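"""Coordinate frames, rotation algebra and the shared domain types.

World frame convention
----------------------
Right-handed, origin at the centre of the physical display surface:

* ``x`` — to the viewer's right,
* ``y`` — up,
* ``z`` — from the screen toward the viewer.

The display therefore occupies the plane ``z = 0`` and a viewer standing in
front of it has a positive ``z`` coordinate.

Euler convention
----------------
All public Euler angles are intrinsic yaw–pitch–roll in **degrees**:

* yaw  ``psi``   — about the world up axis ``y``,
* pitch ``theta`` — about the intermediate lateral axis ``z``,
* roll ``phi``   — about the body-forward axis ``x``,

so ``R = R_y(psi) @ R_z(theta) @ R_x(phi)``.  The body-forward direction is
the local ``+x`` axis; a head facing the display (forward = world ``-z``)
has yaw 90 deg.  This keeps the operating range of a viewer in front of the
screen far away from the gimbal-lock singularity at pitch +/-90 deg.  The
motion tracker's own convention is unknowable from data alone; it only
matters that simulator and estimators agree, which they do by construction.

Gimbal lock (``|pitch| = 90``) is resolved by the canonical branch
``psi = 0``; it is never an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HeadPose",
    "PupilSample",
    "InputSample",
    "ScreenPoint",
    "EyePose",
    "EyeAngles",
    "rotation_from_euler",
    "euler_from_rotation",
    "angle_between",
    "normalize_angle",
]

_GIMBAL_TOL = 1.0 - 1e-12


def normalize_angle(a):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return float(out) if out.ndim == 0 else out


def rotation_from_euler(phi, theta, psi):
    """Rotation matrix from intrinsic yaw-pitch-roll Euler angles (degrees).

    ``R = R_y(psi) @ R_z(theta) @ R_x(phi)`` — yaw ``psi`` about the world up
    axis, pitch ``theta`` about the intermediate lateral axis, roll ``phi``
    about the body-forward axis.  Broadcasts: scalar inputs give a (3, 3)
    matrix, array inputs of shape ``s`` give ``s + (3, 3)``.
    """
    phi, theta, psi = np.broadcast_arrays(
        np.asarray(phi, float), np.asarray(theta, float), np.asarray(psi, float)
    )
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(theta)) and np.all(np.isfinite(psi))):
        raise ValueError("Euler angles must be finite")
    cf, sf = np.cos(np.radians(phi)), np.sin(np.radians(phi))
    ct, st = np.cos(np.radians(theta)), np.sin(np.radians(theta))
    cp, sp = np.cos(np.radians(psi)), np.sin(np.radians(psi))
    R = np.empty(phi.shape + (3, 3), dtype=float)
    # R_y(psi) @ R_z(theta) @ R_x(phi), expanded once by hand
    R[..., 0, 0] = cp * ct
    R[..., 0, 1] = -cp * st * cf + sp * sf
    R[..., 0, 2] = cp * st * sf + sp * cf
    R[..., 1, 0] = st
    R[..., 1, 1] = ct * cf
    R[..., 1, 2] = -ct * sf
    R[..., 2, 0] = -sp * ct
    R[..., 2, 1] = sp * st * cf + cp * sf
    R[..., 2, 2] = -sp * st * sf + cp * cf
    return R


def euler_from_rotation(R):
    """Inverse of :func:`rotation_from_euler`: ``(phi, theta, psi)`` degrees.

    At gimbal lock (pitch = +/-90 deg) the canonical branch ``psi = 0`` is
    returned.  Input must be orthonormal; this is not re-checked beyond what
    the trigonometric extraction implicitly assumes.
    """
    R = np.asarray(R, dtype=float)
    st = np.clip(R[..., 1, 0], -1.0, 1.0)
    theta = np.degrees(np.arcsin(st))
    locked = np.abs(st) >= _GIMBAL_TOL
    psi = np.where(locked, 0.0, np.degrees(np.arctan2(-R[..., 2, 0], R[..., 0, 0])))
    phi_reg = np.degrees(np.arctan2(-R[..., 1, 2], R[..., 1, 1]))
    # locked branch: R = R_z(+/-90) @ R_x(phi); read phi off the first row
    phi_lock = np.where(
        st > 0,
        np.degrees(np.arctan2(R[..., 0, 2], -R[..., 0, 1])),
        np.degrees(np.arctan2(-R[..., 0, 2], R[..., 0, 1])),
    )
    phi = np.where(locked, phi_lock, phi_reg)
    if R.ndim == 2:
        return float(phi), float(theta), float(psi)
    return phi, theta, psi


def angle_between(v1, v2):
    """Angle between two 3-vectors in degrees, in [0, 180].

    Uses the atan2 form, which is numerically stable for nearly parallel and
    nearly antiparallel vectors.  Raises on (near-)zero input.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-300) or np.any(n2 < 1e-300):
        raise ValueError("angle_between requires non-zero vectors")
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.sum(v1 * v2, axis=-1)
    ang = np.degrees(np.arctan2(cross, dot))
    return float(ang) if np.ndim(ang) == 0 else ang


@dataclass
class HeadPose:
    """6-DOF head pose from the motion tracker: position (cm) + orientation.

    Angles are intrinsic yaw-pitch-roll degrees (see module docstring) and
    are wrapped to (-180, 180] on construction.
    """

    t: float
    h_x: float
    h_y: float
    h_z: float
    h_phi: float
    h_theta: float
    h_psi: float

    def __post_init__(self):
        for a in (self.h_phi, self.h_theta, self.h_psi):
            if not np.isfinite(a):
                raise ValueError("head orientation angles must be finite")
        self.h_phi = normalize_angle(self.h_phi)
        self.h_theta = normalize_angle(self.h_theta)
        self.h_psi = normalize_angle(self.h_psi)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.h_x, self.h_y, self.h_z], dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_from_euler(self.h_phi, self.h_theta, self.h_psi)


@dataclass
class PupilSample:
    """Pupil centroid in eye-camera image units (dimensionless tracker units)."""

    t: float
    p_x: float
    p_y: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.p_x, self.p_y], dtype=float)


@dataclass
class InputSample:
    """One time-aligned (head pose, pupil) observation — the 8-D input."""

    head: HeadPose
    pupil: PupilSample

    def __post_init__(self):
        if abs(self.head.t - self.pupil.t) > 1e-9:
            raise ValueError("head and pupil samples must share a timestamp")

    @property
    def x(self) -> np.ndarray:
        """The 8-vector (h_x, h_y, h_z, h_phi, h_theta, h_psi, p_x, p_y)."""
        h = self.head
        return np.array(
            [h.h_x, h.h_y, h.h_z, h.h_phi, h.h_theta, h.h_psi, self.pupil.p_x, self.pupil.p_y]
        )


@dataclass
class ScreenPoint:
    """A point in display pixel coordinates (may lie outside the panel)."""

    u: float
    v: float

    @property
    def uv(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass
class EyePose:
    """Eye centre position (cm, world frame) and orientation matrix."""

    position: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        R = self.rotation
        if np.linalg.norm(R @ R.T - np.eye(3)) > 1e-9:
            raise ValueError("eye rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("eye rotation must be proper (det = 1)")


@dataclass
class EyeAngles:
    """Eye-in-head rotation: horizontal ``phi``, vertical ``theta`` (degrees).

    Positive ``phi`` rotates the gaze toward the viewer's right, positive
    ``theta`` upward, for an eye facing the display.
    """

    phi: float
    theta: float
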