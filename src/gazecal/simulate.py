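"""Synthetic gaze sessions: stimulus schedules, head motion and a forward model.

The simulator emulates the data-collection protocol used to evaluate both
estimators: a *dynamic* pursuit phase in which a marker moves at 100 px/s
along cardinal directions for at least 100 px before turning (pausing
750 ms at every turn) for 3 min, and a *static* phase in which each of the
20 points of a 5 x 4 grid (spanning +/-32 deg x +/-23 deg of visual angle
from the chin-rest position) is shown 10 times for 1500 ms — 200
presentations, 5 min.

Head motion comes in three mobility conditions: *head_fixed* (chin rest —
constant pose plus sensor noise), *head_free* (fixed position, smooth
orientation wander around facing the current stimulus) and *walking*
(smooth positional random walk confined to a 150 x 145 cm floor area in
front of the display, orientation facing the stimulus).  Real sessions get
their head motion from a human; the wander here is an Ornstein-Uhlenbeck
process, chosen for smoothness and boundedness, with time constants of a
few seconds.

The forward model assumes the user fixates the stimulus exactly: the
required eye-in-head angles follow from the inverse screen mapping at the
ground-truth eye pose, and the pupil coordinates from inverting the linear
eye model.  Optional fixation jitter (degrees) relaxes the exact-fixation
assumption for robustness experiments.  With all noise at zero the
geometric predictor run at the ground-truth parameters reproduces the
stimulus exactly — the simulator and predictor are inverse by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SessionDataset
from .geometric import EyeModelParams, GeometricModel, HeadEyeParams
from .screen import ScreenParams, default_screen, inverse_screen_batch, por_to_world

__all__ = [
    "SimulationConfig",
    "StimulusEvent",
    "default_ground_truth",
    "dynamic_stimulus_path",
    "static_stimulus_sequence",
    "static_grid_points",
    "simulate_head_trajectory",
    "forward_model",
    "simulate_session",
]

#: chin-rest viewing distance (cm) and walking-area extents (cm)
CHIN_REST_DISTANCE = 140.0
WALK_AREA = (150.0, 145.0)

MOBILITIES = ("head_fixed", "head_free", "walking")

DYNAMIC_DURATION_S = 180.0
PAUSE_S = 0.75
PURSUIT_SPEED = 100.0  # px/s
MIN_SEGMENT_PX = 100.0
STATIC_PRESENT_S = 1.5
GRID_SHAPE = (5, 4)
GRID_REPEATS = 10
GRID_HALF_ANGLES = (32.0, 23.0)  # degrees, horizontal x vertical


def default_ground_truth(screen: ScreenParams | None = None) -> GeometricModel:
    """A plausible helmet geometry, fixed across fixtures.

    Eye 8 cm forward of and 9 cm below the tracked marker centroid (markers
    sit on top of the eye tracker's headband), no orientation offset; eye
    model 0.01 deg per camera image unit with zero intercept, so a +/-38 deg
    gaze range spans roughly +/-3800 image units — the scale of a video eye
    tracker's raw pupil coordinates.
    """
    return GeometricModel(
        head_eye=HeadEyeParams(x_T=8.0, y_T=-9.0, z_T=0.0),
        eye=EyeModelParams(m_phi=0.01, b_phi=0.0, m_theta=0.01, b_theta=0.0),
        screen=screen if screen is not None else default_screen(),
    )


@dataclass
class SimulationConfig:
    """Everything a synthetic session depends on.

    Noise levels are per-sample Gaussian sensor noise: ``noise_pupil`` in
    image units, ``noise_head_pos`` cm, ``noise_head_rot`` degrees;
    ``fixation_jitter_deg`` perturbs the fixated gaze direction itself.
    Defaults emulate a quiet tracker: 15 image units of pupil noise
    (~0.15 deg through the default eye model), 0.05 cm and 0.1 deg of head
    tracker noise, no fixation jitter.
    """

    seed: int = 0
    mobility: str = "walking"
    sample_rate: float = 60.0
    noise_pupil: float = 15.0
    noise_head_pos: float = 0.05
    noise_head_rot: float = 0.1
    fixation_jitter_deg: float = 0.0
    eye_height_cm: float = 0.0
    viewing_distance_cm: float = CHIN_REST_DISTANCE
    #: world-frame displacement of the user's base position (cm); used to
    #: place a validation session outside the calibration coverage
    base_offset_cm: tuple = (0.0, 0.0, 0.0)
    ground_truth: GeometricModel = field(default_factory=default_ground_truth)

    def __post_init__(self):
        if self.mobility not in MOBILITIES:
            raise ValueError(f"mobility must be one of {MOBILITIES}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for v in (self.noise_pupil, self.noise_head_pos, self.noise_head_rot,
                  self.fixation_jitter_deg):
            if v < 0:
                raise ValueError("noise levels must be non-negative")

    def noiseless(self) -> "SimulationConfig":
        return replace(self, noise_pupil=0.0, noise_head_pos=0.0, noise_head_rot=0.0,
                       fixation_jitter_deg=0.0)


@dataclass
class StimulusEvent:
    onset: float
    duration: float
    position: tuple
    kind: str  # static_dot | pursuit_segment | pause


def dynamic_stimulus_path(duration_s: float, seed, screen: ScreenParams,
                          sample_rate: float = 60.0):
    """Pursuit-marker trajectory: positions per sample and the event list.

    The marker moves at exactly 100 px/s along one cardinal direction for a
    segment of at least 100 px, pauses 750 ms, then turns into one of the
    three other cardinal directions (chosen uniformly among those with at
    least a full segment of room before the screen edge).  State changes
    at sample boundaries, so every in-motion step is exactly
    ``100/sample_rate`` px.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = 1.0 / sample_rate
    step = PURSUIT_SPEED * dt
    n = int(round(duration_s * sample_rate))
    margin = 40.0
    lo = np.array([margin, margin])
    hi = np.array([screen.s_u - margin, screen.s_v - margin])
    pos = lo + rng.random(2) * (hi - lo)
    dirs = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)

    def room(p, d):
        proj = d @ np.where(d > 0, hi - p, np.where(d < 0, p - lo, 0.0))
        return float(abs(proj)) if np.any(d != 0) else 0.0

    def pick(p, exclude=None):
        cand = [i for i in range(4) if room(p, dirs[i]) >= MIN_SEGMENT_PX
                and (exclude is None or i != exclude)]
        if not cand:
            cand = [int(np.argmax([room(p, dirs[i]) for i in range(4)]))]
        return int(rng.choice(cand))

    d_idx = pick(pos)
    seg_len = MIN_SEGMENT_PX + rng.random() * min(300.0, max(0.0, room(pos, dirs[d_idx]) - MIN_SEGMENT_PX))
    seg_steps = max(int(np.ceil(seg_len / step)), int(np.ceil(MIN_SEGMENT_PX / step)))
    pause_steps = int(round(PAUSE_S * sample_rate))

    out = np.empty((n, 2))
    events = []
    seg_start_t, seg_start_pos = 0.0, pos.copy()
    in_pause, counter = False, seg_steps
    for i in range(n):
        out[i] = pos
        t = i * dt
        if in_pause:
            counter -= 1
            if counter <= 0:
                events.append(StimulusEvent(t - PAUSE_S + dt, PAUSE_S, tuple(pos), "pause"))
                d_idx = pick(pos, exclude=d_idx)
                avail = room(pos, dirs[d_idx])
                seg_len = MIN_SEGMENT_PX + rng.random() * min(300.0, max(0.0, avail - MIN_SEGMENT_PX))
                seg_steps = int(np.ceil(max(seg_len, MIN_SEGMENT_PX) / step))
                in_pause, counter = False, seg_steps
                seg_start_t, seg_start_pos = t + dt, pos.copy()
        else:
            pos = pos + dirs[d_idx] * step
            counter -= 1
            if counter <= 0 or room(pos, dirs[d_idx]) < step:
                events.append(StimulusEvent(seg_start_t, t + dt - seg_start_t,
                                            tuple(seg_start_pos), "pursuit_segment"))
                in_pause, counter = True, pause_steps
    return out, events


def static_grid_points(screen: ScreenParams,
                       distance_cm: float = CHIN_REST_DISTANCE) -> np.ndarray:
    """Pixel coordinates of the 5 x 4 calibration grid.

    The grid is centred on the display and spans +/-32 deg x +/-23 deg of
    visual angle as seen from the on-axis chin-rest position, converted to
    pixels through the screen's metric geometry.
    """
    half_w_cm = distance_cm * np.tan(np.radians(GRID_HALF_ANGLES[0]))
    half_h_cm = distance_cm * np.tan(np.radians(GRID_HALF_ANGLES[1]))
    half_u = half_w_cm * screen.s_u / screen.s_x
    half_v = half_h_cm * screen.s_v / screen.s_y
    us = screen.s_u / 2.0 + np.linspace(-half_u, half_u, GRID_SHAPE[0])
    vs = screen.s_v / 2.0 + np.linspace(-half_v, half_v, GRID_SHAPE[1])
    return np.array([(u, v) for v in vs for u in us])


def static_stimulus_sequence(seed, screen: ScreenParams,
                             distance_cm: float = CHIN_REST_DISTANCE):
    """The static-phase schedule: 20 grid points x 10 repeats, 1500 ms each.

    Each round of 20 presentations is a fresh random permutation of the
    grid (sampling without replacement), repeated 10 times.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = static_grid_points(screen, distance_cm)
    events = []
    t = 0.0
    for _ in range(GRID_REPEATS):
        for idx in rng.permutation(len(grid)):
            events.append(StimulusEvent(t, STATIC_PRESENT_S, tuple(grid[idx]), "static_dot"))
            t += STATIC_PRESENT_S
    return events


def _facing_angles(positions, targets_world):
    """Yaw/pitch (deg) that point the head-forward axis at the target."""
    d = targets_world - positions
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    theta = np.degrees(np.arcsin(np.clip(d[..., 1], -1, 1)))
    psi = np.degrees(np.arctan2(-d[..., 2], d[..., 0]))
    return psi, theta


def _ou(rng, n, dt, tau, sigma, dim=1):
    """Stationary Ornstein-Uhlenbeck path(s), zero mean, std sigma."""
    x = np.empty((n, dim))
    x[0] = rng.normal(0, sigma, dim)
    a = np.exp(-dt / tau)
    s = sigma * np.sqrt(1 - a * a)
    eps = rng.normal(0, 1, (n - 1, dim)) if n > 1 else np.empty((0, dim))
    for i in range(1, n):
        x[i] = a * x[i - 1] + s * eps[i - 1]
    return x


def simulate_head_trajectory(config: SimulationConfig, duration_s: float,
                             stimulus_px=None, rng=None):
    """Head-pose streams (positions (n,3) cm, yaw/pitch/roll angles (n,3) deg).

    ``stimulus_px`` (n, 2) lets head-free and walking heads orient toward
    the current stimulus; without it they face the screen centre.  Angle
    columns are ordered (roll, pitch, yaw) to match the pose convention.
    Sensor noise is added per sample.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(duration_s * config.sample_rate))
    dt = 1.0 / config.sample_rate
    screen = config.ground_truth.screen
    base = screen.c + config.viewing_distance_cm * screen.n \
        + config.eye_height_cm * screen.up + np.asarray(config.base_offset_cm, float)

    if config.mobility == "head_fixed":
        positions = np.tile(base, (n, 1))
    elif config.mobility == "head_free":
        positions = np.tile(base, (n, 1))
    else:  # walking: OU wander confined to the floor area
        half = np.array([WALK_AREA[0] / 2.0, WALK_AREA[1] / 2.0])
        wander = _ou(rng, n, dt, tau=5.0, sigma=0.45, dim=2)  # unitless, ~N(0,1) scale
        xz = np.tanh(wander) * half  # smooth, strictly inside the area
        positions = np.tile(base, (n, 1))
        positions[:, 0] += xz[:, 0] * screen.right[0] + xz[:, 1] * screen.n[0]
        positions[:, 1] += xz[:, 0] * screen.right[1] + xz[:, 1] * screen.n[1]
        positions[:, 2] += xz[:, 0] * screen.right[2] + xz[:, 1] * screen.n[2]

    if stimulus_px is None:
        target_world = np.tile(screen.c, (n, 1))
    else:
        target_world = por_to_world(screen, stimulus_px[:, 0], stimulus_px[:, 1])
    psi, theta = _facing_angles(positions, target_world)
    if config.mobility == "head_fixed":
        # chin rest: constant neutral orientation facing the screen centre
        psi0, theta0 = _facing_angles(base[None, :], screen.c[None, :])
        psi = np.full(n, psi0[0])
        theta = np.full(n, theta0[0])
        roll = np.zeros(n)
    else:
        # the head points only roughly at the stimulus; the eyes do the rest
        psi = psi + _ou(rng, n, dt, tau=2.0, sigma=4.0)[:, 0]
        theta = 0.6 * theta + _ou(rng, n, dt, tau=2.0, sigma=2.5)[:, 0]
        roll = _ou(rng, n, dt, tau=3.0, sigma=1.5)[:, 0]

    angles = np.stack([roll, theta, psi], axis=-1)
    positions = positions + rng.normal(0, config.noise_head_pos, (n, 3)) \
        if config.noise_head_pos > 0 else positions
    angles = angles + rng.normal(0, config.noise_head_rot, (n, 3)) \
        if config.noise_head_rot > 0 else angles
    return positions, angles


def forward_model(head_pos, head_ang, targets_px, truth: GeometricModel,
                  noise_pupil: float = 0.0, rng=None,
                  fixation_jitter_deg: float = 0.0):
    """Pupil coordinates a fixating eye would produce, (n, 2) image units.

    The ground-truth head-eye transform gives the eye pose; the inverse
    screen mapping gives the eye-in-head angles that fixate the target; the
    inverted linear eye model gives the pupil centroid:
    ``p_x = (phi - b_phi)/m_phi``, ``p_y = (theta - b_theta)/m_theta``.
    Gaussian pupil noise (image units) and fixation jitter (degrees) are
    added when requested.
    """
    if abs(truth.eye.m_phi) < 1e-12 or abs(truth.eye.m_theta) < 1e-12:
        raise ValueError("eye model slope of zero cannot be inverted")
    head_pos = np.atleast_2d(np.asarray(head_pos, float))
    head_ang = np.atleast_2d(np.asarray(head_ang, float))
    targets_px = np.atleast_2d(np.asarray(targets_px, float))
    from .geometry import rotation_from_euler

    R_h = rotation_from_euler(head_ang[:, 0], head_ang[:, 1], head_ang[:, 2])
    e = head_pos + R_h @ truth.head_eye.offset
    R_e = R_h @ truth.head_eye.rotation
    # a fixated target must be in front of the eye
    w = por_to_world(truth.screen, targets_px[:, 0], targets_px[:, 1]) - e
    if np.any(np.einsum("ni,i->n", w, -truth.screen.n) <= 0):
        raise ValueError("target not visible from the eye position")
    phi, theta = inverse_screen_batch(truth.screen, e, R_e,
                                      targets_px[:, 0], targets_px[:, 1])
    if fixation_jitter_deg > 0:
        if rng is None:
            rng = np.random.default_rng()
        phi = phi + rng.normal(0, fixation_jitter_deg, phi.shape)
        theta = theta + rng.normal(0, fixation_jitter_deg, theta.shape)
    p = np.stack([(phi - truth.eye.b_phi) / truth.eye.m_phi,
                  (theta - truth.eye.b_theta) / truth.eye.m_theta], axis=-1)
    if noise_pupil > 0:
        if rng is None:
            rng = np.random.default_rng()
        p = p + rng.normal(0, noise_pupil, p.shape)
    return p


def simulate_session(config: SimulationConfig, protocol: str = "both") -> SessionDataset:
    """Generate a full synthetic session as a :class:`SessionDataset`.

    ``protocol`` is "dynamic" (3 min pursuit), "static" (5 min grid) or
    "both" (dynamic followed by static, timestamps continuous).  All
    randomness flows from ``config.seed``.
    """
    if protocol not in ("dynamic", "static", "both"):
        raise ValueError("protocol must be dynamic, static or both")
    rng = np.random.default_rng(config.seed)
    screen = config.ground_truth.screen
    dt = 1.0 / config.sample_rate
    parts = []
    t0 = 0.0

    if protocol in ("dynamic", "both"):
        stim, _events = dynamic_stimulus_path(DYNAMIC_DURATION_S, rng, screen,
                                              config.sample_rate)
        n = len(stim)
        parts.append((t0 + np.arange(n) * dt, stim, "dynamic",
                      np.full(n, -1, dtype=int)))
        t0 += n * dt

    if protocol in ("static", "both"):
        events = static_stimulus_sequence(rng, screen, config.viewing_distance_cm)
        per = int(round(STATIC_PRESENT_S * config.sample_rate))
        n = per * len(events)
        stim = np.repeat([e.position for e in events], per, axis=0)
        sid = np.repeat(np.arange(len(events)), per)
        parts.append((t0 + np.arange(n) * dt, np.asarray(stim, float), "static", sid))
        t0 += n * dt

    ts = np.concatenate([p[0] for p in parts])
    stim_all = np.vstack([p[1] for p in parts])
    phases = np.concatenate([[p[2]] * len(p[0]) for p in parts])
    sids = np.concatenate([p[3] for p in parts])

    # pupil data reflect the *true* head pose; tracker noise corrupts only
    # the recorded pose, as it does on real hardware
    clean = replace(config, noise_head_pos=0.0, noise_head_rot=0.0)
    head_pos, head_ang = simulate_head_trajectory(
        clean, len(ts) * dt, stimulus_px=stim_all, rng=rng
    )
    head_pos, head_ang = head_pos[: len(ts)], head_ang[: len(ts)]
    pupil = forward_model(head_pos, head_ang, stim_all, config.ground_truth,
                          noise_pupil=config.noise_pupil, rng=rng,
                          fixation_jitter_deg=config.fixation_jitter_deg)
    if config.noise_head_pos > 0:
        head_pos = head_pos + rng.normal(0, config.noise_head_pos, head_pos.shape)
    if config.noise_head_rot > 0:
        head_ang = head_ang + rng.normal(0, config.noise_head_rot, head_ang.shape)
    return SessionDataset.from_arrays(
        ts, head_pos, head_ang, pupil, stim_all, phases, sids,
        user=f"sim-{config.mobility}-{config.seed}",
    )
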