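"""Planar display model: pixel <-> metric <-> 3-D mapping and gaze-ray intersection.

The screen is a planar surface described by a centre point ``c`` (cm, world
frame), a unit normal ``n``, metric width/height ``s_x, s_y`` (cm) and pixel
resolution ``s_u x s_v``.  A unit in-plane "screen-up" vector completes the
2-D pixel frame, which a centre-and-normal description alone leaves free up
to an in-plane roll; for the vertical display studied here the world up axis
projected into the plane is the natural completion and is the default.

Pixel convention: origin at the top-left corner, ``u`` increasing rightward,
``v`` increasing downward, so ``v`` grows as elevation decreases.  Pixel
coordinates are continuous; the corners of the panel are (0, 0) and
(s_u, s_v) and its centre is (s_u/2, s_v/2).

All mapping functions broadcast over leading axes; scalar convenience
wrappers operating on the domain dataclasses are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import EyeAngles, EyePose, ScreenPoint

__all__ = [
    "ScreenParams",
    "GazeRay",
    "default_screen",
    "por_to_world",
    "world_to_por",
    "gaze_direction",
    "gaze_vector",
    "intersect_gaze",
    "intersect_rays",
    "inverse_screen",
    "inverse_screen_batch",
]

#: |direction . normal| below this means the ray is treated as parallel.
PARALLEL_TOL = 1e-9


@dataclass
class ScreenParams:
    """Geometry of a planar display (the screen parameter set)."""

    c: np.ndarray
    n: np.ndarray
    up: np.ndarray
    s_x: float
    s_y: float
    s_u: int
    s_v: int

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float).reshape(3)
        self.n = np.asarray(self.n, dtype=float).reshape(3)
        self.up = np.asarray(self.up, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.n) - 1.0) > 1e-9:
            raise ValueError("screen normal must be a unit vector")
        if abs(np.linalg.norm(self.up) - 1.0) > 1e-9:
            raise ValueError("screen up vector must be a unit vector")
        if abs(float(self.n @ self.up)) > 1e-9:
            raise ValueError("screen up vector must lie in the screen plane")
        if min(self.s_x, self.s_y) <= 0 or min(self.s_u, self.s_v) <= 0:
            raise ValueError("screen dimensions must be positive")

    @property
    def right(self) -> np.ndarray:
        """In-plane unit vector of increasing ``u`` (the viewer's right)."""
        return np.cross(self.up, self.n)

    @property
    def diagonal_px(self) -> float:
        return float(np.hypot(self.s_u, self.s_v))

    def to_dict(self) -> dict:
        return {
            "center": self.c.tolist(),
            "normal": self.n.tolist(),
            "up": self.up.tolist(),
            "width_cm": self.s_x,
            "height_cm": self.s_y,
            "width_px": self.s_u,
            "height_px": self.s_v,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenParams":
        return cls(
            c=d["center"],
            n=d["normal"],
            up=d["up"],
            s_x=d["width_cm"],
            s_y=d["height_cm"],
            s_u=d["width_px"],
            s_v=d["height_px"],
        )


@dataclass
class GazeRay:
    """Half-line from the eye centre along the line of sight."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            raise ValueError("gaze direction must be non-zero")
        self.direction = d / nd


def default_screen() -> ScreenParams:
    """The back-projection display used throughout the fixtures.

    1024 x 768 px, 220 x 160 cm, centred at the world origin in the plane
    z = 0, facing the viewer (+z).
    """
    return ScreenParams(
        c=np.zeros(3),
        n=np.array([0.0, 0.0, 1.0]),
        up=np.array([0.0, 1.0, 0.0]),
        s_x=220.0,
        s_y=160.0,
        s_u=1024,
        s_v=768,
    )


def por_to_world(screen: ScreenParams, u, v) -> np.ndarray:
    """Map pixel coordinates to 3-D world points on the screen plane.

    Out-of-panel pixels extrapolate linearly; use the ``on_screen`` flag of
    :func:`intersect_gaze` (or compare against the resolution) to detect them.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    dx = (u - screen.s_u / 2.0) * (screen.s_x / screen.s_u)
    dy = (screen.s_v / 2.0 - v) * (screen.s_y / screen.s_v)
    return (
        screen.c
        + dx[..., None] * screen.right
        + dy[..., None] * screen.up
    )


def world_to_por(screen: ScreenParams, point, atol: float = 1e-6):
    """Map 3-D points on the screen plane to pixel coordinates ``(u, v)``.

    Raises if any point is farther than ``atol`` cm from the plane.
    """
    point = np.asarray(point, dtype=float)
    rel = point - screen.c
    off = rel @ screen.n
    if np.any(np.abs(off) > atol):
        raise ValueError("point does not lie on the screen plane")
    u = (rel @ screen.right) * (screen.s_u / screen.s_x) + screen.s_u / 2.0
    v = screen.s_v / 2.0 - (rel @ screen.up) * (screen.s_v / screen.s_y)
    return u, v


def gaze_direction(R_e, phi, theta) -> np.ndarray:
    """World-frame gaze direction ``g = R_e R_phi R_theta (1, 0, 0)^T``.

    ``R_theta`` rotates the eye-frame forward axis by ``theta`` about the
    lateral axis (positive = up), ``R_phi`` by ``phi`` about the eye's up
    axis (positive = toward the viewer's right for an eye facing the
    display).  In the eye frame the rotated forward axis is
    ``(cos phi cos theta, sin theta, sin phi cos theta)``.
    Broadcasts; returns unit vectors.
    """
    R_e = np.asarray(R_e, dtype=float)
    phi = np.radians(np.asarray(phi, dtype=float))
    theta = np.radians(np.asarray(theta, dtype=float))
    local = np.stack(
        [
            np.cos(phi) * np.cos(theta),
            np.sin(theta) + np.zeros_like(phi),
            np.sin(phi) * np.cos(theta),
        ],
        axis=-1,
    )
    return np.einsum("...ij,...j->...i", R_e, local)


def gaze_vector(eye: EyePose, angles: EyeAngles) -> GazeRay:
    """Gaze ray of an eye pose and eye-in-head rotation angles."""
    d = gaze_direction(eye.rotation, angles.phi, angles.theta)
    return GazeRay(origin=eye.position, direction=d)


def intersect_rays(screen: ScreenParams, origins, directions):
    """Vectorised ray/screen intersection.

    Returns ``(u, v, on_screen, valid)``.  ``valid`` is False where the ray
    is parallel to the plane or the intersection lies behind the origin;
    ``u, v`` are NaN there.  No exception is raised — callers that need the
    strict scalar contract use :func:`intersect_gaze`.
    """
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    denom = directions @ screen.n
    num = (screen.c - origins) @ screen.n
    with np.errstate(divide="ignore", invalid="ignore"):
        s = num / denom
    valid = (np.abs(denom) >= PARALLEL_TOL) & (s > 0)
    s = np.where(valid, s, np.nan)
    pts = origins + s[..., None] * directions
    rel = pts - screen.c
    u = (rel @ screen.right) * (screen.s_u / screen.s_x) + screen.s_u / 2.0
    v = screen.s_v / 2.0 - (rel @ screen.up) * (screen.s_v / screen.s_y)
    on = valid & (u >= 0) & (u <= screen.s_u) & (v >= 0) & (v <= screen.s_v)
    return u, v, on, valid


def intersect_gaze(screen: ScreenParams, eye: EyePose, angles: EyeAngles):
    """Intersect the gaze ray with the display; the POR in pixels.

    Returns ``(ScreenPoint, on_screen)``.  Raises if the ray is parallel to
    the screen plane or the intersection lies behind the eye.
    """
    d = gaze_direction(eye.rotation, angles.phi, angles.theta)
    u, v, on, valid = intersect_rays(screen, eye.position, d)
    if not bool(valid):
        raise ValueError("gaze ray does not intersect the screen in front of the eye")
    return ScreenPoint(float(u), float(v)), bool(on)


def inverse_screen_batch(screen: ScreenParams, eye_positions, eye_rotations, u, v):
    """Eye-in-head angles that aim each eye at the given pixel target(s).

    Inverse of the forward chain ``gaze_direction`` -> plane intersection:
    the target pixel is lifted to the world, the unit eye-to-target
    direction ``w`` is expressed in the eye frame as ``b = R_e^T w`` and the
    angles recovered as ``theta = asin(b_y)``, ``phi = atan2(b_z, b_x)``.
    Returns ``(phi, theta)`` in degrees.
    """
    target = por_to_world(screen, np.asarray(u, float), np.asarray(v, float))
    w = target - np.asarray(eye_positions, dtype=float)
    norm = np.linalg.norm(w, axis=-1, keepdims=True)
    if np.any(norm < 1e-9):
        raise ValueError("target point coincides with the eye position")
    w = w / norm
    b = np.einsum("...ji,...j->...i", np.asarray(eye_rotations, float), w)
    theta = np.degrees(np.arcsin(np.clip(b[..., 1], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(b[..., 2], b[..., 0]))
    return phi, theta


def inverse_screen(screen: ScreenParams, eye: EyePose, p: ScreenPoint) -> EyeAngles:
    """Scalar wrapper around :func:`inverse_screen_batch`."""
    phi, theta = inverse_screen_batch(screen, eye.position, eye.rotation, p.u, p.v)
    return EyeAngles(phi=float(phi), theta=float(theta))
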