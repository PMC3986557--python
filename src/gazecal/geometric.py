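"""Geometric gaze estimation: head->eye transform, linear eye model, and the
nested cost-minimisation calibration.

The geometric method composes three models.  The head-eye transform maps the
tracked head pose to an eye pose: ``e = h + R_h t`` and ``R_e = R_h R_T``,
where ``t`` is the eye's position offset in the head frame and ``R_T`` the
orientation offset.  The eye model maps the pupil centroid in the camera
image linearly to eye-in-head rotation angles, ``phi = m_phi p_x + b_phi``
and ``theta = m_theta p_y + b_theta``.  The screen model turns the resulting
gaze ray into a POR in display pixels.

Calibration minimises the mean pixel distance between predicted and true
PORs over a session.  The transform parameters are found by a bounded
derivative-free search (Powell's quadratic-model family); for every
candidate transform the four eye-model coefficients are fitted in closed
form by regressing the angles required to hit the known targets (obtained
from the inverse screen mapping at the candidate eye poses) onto the pupil
coordinates.  Because the eye model is linear this inner fit is exact, so
the nominally 10-dimensional joint problem is searched over only the six
transform parameters.

Screen calibration wraps the same machinery in an outer search over the
display geometry, summing the per-user minimised costs over a corpus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, minimize

from .dataset import SessionDataset
from .geometry import EyeAngles, EyePose, HeadPose, PupilSample, InputSample, rotation_from_euler
from .screen import ScreenParams, gaze_direction, intersect_rays, por_to_world

__all__ = [
    "HeadEyeParams",
    "EyeModelParams",
    "GeometricModel",
    "CalibrationResult",
    "head_to_eye",
    "pupil_to_angles",
    "fit_eye_model",
    "predict_geometric",
    "predict_geometric_batch",
    "geometric_cost",
    "calibrate_user",
    "calibrate_screen",
]

#: optimiser box: +/-30 cm position offsets, +/-45 deg orientation offsets
DEFAULT_OFFSET_BOUND_CM = 30.0
DEFAULT_ANGLE_BOUND_DEG = 45.0


@dataclass
class HeadEyeParams:
    """Rigid offset from the tracked head origin to the eye (head frame).

    ``x_T, y_T, z_T`` in cm along the head's forward/up/lateral axes;
    ``phi_T, theta_T, psi_T`` the orientation offset in roll/pitch/yaw
    degrees (same convention as head poses).
    """

    x_T: float = 0.0
    y_T: float = 0.0
    z_T: float = 0.0
    phi_T: float = 0.0
    theta_T: float = 0.0
    psi_T: float = 0.0

    @property
    def offset(self) -> np.ndarray:
        return np.array([self.x_T, self.y_T, self.z_T], dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        return rotation_from_euler(self.phi_T, self.theta_T, self.psi_T)

    def as_vector(self) -> np.ndarray:
        return np.array([self.x_T, self.y_T, self.z_T, self.phi_T, self.theta_T, self.psi_T])

    @classmethod
    def from_vector(cls, v) -> "HeadEyeParams":
        return cls(*[float(x) for x in v])


@dataclass
class EyeModelParams:
    """Slopes/intercepts of the two linear pupil->angle maps.

    ``m`` in degrees per image unit, ``b`` in degrees.
    """

    m_phi: float = 1.0
    b_phi: float = 0.0
    m_theta: float = 1.0
    b_theta: float = 0.0


@dataclass
class GeometricModel:
    """The full parameter triple: head-eye transform, eye model, screen."""

    head_eye: HeadEyeParams
    eye: EyeModelParams
    screen: ScreenParams


@dataclass
class CalibrationResult:
    head_eye: HeadEyeParams
    eye: EyeModelParams
    cost: float
    n_evaluations: int
    converged: bool
    history: list = field(default_factory=list)


def head_to_eye(head: HeadPose, params: HeadEyeParams) -> EyePose:
    """Eye pose from a tracked head pose: ``e = h + R_h t``, ``R_e = R_h R_T``."""
    R_h = head.rotation
    return EyePose(
        position=head.position + R_h @ params.offset,
        rotation=R_h @ params.rotation,
    )


def _eye_poses(head_pos, R_h, params: HeadEyeParams):
    """Batched head->eye: positions (n,3) and rotations (n,3,3)."""
    e = head_pos + R_h @ params.offset
    R_e = R_h @ params.rotation
    return e, R_e


def pupil_to_angles(p: PupilSample, params: EyeModelParams) -> EyeAngles:
    """Linear eye model: phi = m_phi p_x + b_phi, theta = m_theta p_y + b_theta."""
    return EyeAngles(
        phi=params.m_phi * p.p_x + params.b_phi,
        theta=params.m_theta * p.p_y + params.b_theta,
    )


def _fit_line(x: np.ndarray, y: np.ndarray):
    """Least-squares slope/intercept of y on x (normal equations)."""
    vx = np.var(x)
    if vx < 1e-12:
        raise ValueError("degenerate pupil coordinate: no variation to regress on")
    m = np.cov(x, y, bias=True)[0, 1] / vx
    b = np.mean(y) - m * np.mean(x)
    return float(m), float(b)


def fit_eye_model(pairs) -> EyeModelParams:
    """Fit the linear eye model from (PupilSample, EyeAngles) pairs.

    Per-axis simple linear regression: phi on p_x and theta on p_y.
    Requires at least two pairs with non-constant pupil coordinates.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to fit the eye model")
    px = np.array([p.p_x for p, _ in pairs])
    py = np.array([p.p_y for p, _ in pairs])
    phi = np.array([a.phi for _, a in pairs])
    theta = np.array([a.theta for _, a in pairs])
    m_phi, b_phi = _fit_line(px, phi)
    m_theta, b_theta = _fit_line(py, theta)
    return EyeModelParams(m_phi=m_phi, b_phi=b_phi, m_theta=m_theta, b_theta=b_theta)


def predict_geometric(model: GeometricModel, x: InputSample):
    """Predict the POR for one input sample: ``(ScreenPoint, on_screen)``."""
    from .screen import intersect_gaze

    eye = head_to_eye(x.head, model.head_eye)
    angles = pupil_to_angles(x.pupil, model.eye)
    return intersect_gaze(model.screen, eye, angles)


def predict_geometric_batch(model: GeometricModel, data: SessionDataset):
    """Vectorised prediction over a session.

    Returns ``(uv, valid)``: predicted pixel coordinates of shape (n, 2)
    (NaN where the gaze ray misses the screen plane) and a boolean mask of
    samples with a valid forward intersection.
    """
    e, R_e = _eye_poses(data.head_positions, data.head_rotations, model.head_eye)
    pupil = data.pupil
    phi = model.eye.m_phi * pupil[:, 0] + model.eye.b_phi
    theta = model.eye.m_theta * pupil[:, 1] + model.eye.b_theta
    dirs = gaze_direction(R_e, phi, theta)
    u, v, _on, valid = intersect_rays(model.screen, e, dirs)
    return np.stack([u, v], axis=-1), valid


def _cost_from_predictions(uv, valid, targets, screen: ScreenParams) -> float:
    """Mean pixel error; rays that miss the plane cost twice the diagonal."""
    d = np.linalg.norm(uv - targets, axis=-1)
    penalty = 2.0 * screen.diagonal_px
    d = np.where(valid, np.minimum(np.nan_to_num(d, nan=penalty), penalty * 10), penalty)
    return float(np.mean(d))


def geometric_cost(model: GeometricModel, data: SessionDataset) -> float:
    """Mean Euclidean pixel distance between predicted and true PORs."""
    if len(data) == 0:
        raise ValueError("cannot evaluate the calibration cost on an empty dataset")
    uv, valid = predict_geometric_batch(model, data)
    return _cost_from_predictions(uv, valid, data.targets, model.screen)


class _UserObjective:
    """Calibration cost as a function of the 6 head-eye parameters.

    Precomputes everything that does not depend on the candidate transform;
    the closed-form inner eye-model fit happens inside ``__call__``.
    """

    def __init__(self, data: SessionDataset, screen: ScreenParams):
        if len(data) == 0:
            raise ValueError("cannot calibrate on an empty dataset")
        self.screen = screen
        self.head_pos = data.head_positions
        self.R_h = data.head_rotations
        self.pupil = data.pupil
        self.targets = data.targets
        if not np.isfinite(self.targets).all():
            raise ValueError("calibration data must have a stimulus POR for every sample")
        self.target_world = por_to_world(screen, self.targets[:, 0], self.targets[:, 1])
        if np.var(self.pupil[:, 0]) < 1e-12 or np.var(self.pupil[:, 1]) < 1e-12:
            raise ValueError("degenerate pupil data: a coordinate is constant")
        self.penalty = 2.0 * screen.diagonal_px

    def eye_model_for(self, vec) -> EyeModelParams:
        """Closed-form eye-model fit for a candidate transform."""
        params = HeadEyeParams.from_vector(vec)
        e, R_e = _eye_poses(self.head_pos, self.R_h, params)
        w = self.target_world - e
        norm = np.linalg.norm(w, axis=-1, keepdims=True)
        if np.any(norm < 1e-9):
            raise ValueError("eye position coincides with a calibration target")
        w = w / norm
        b = np.einsum("nji,nj->ni", R_e, w)
        theta_req = np.degrees(np.arcsin(np.clip(b[:, 1], -1.0, 1.0)))
        phi_req = np.degrees(np.arctan2(b[:, 2], b[:, 0]))
        m_phi, b_phi = _fit_line(self.pupil[:, 0], phi_req)
        m_theta, b_theta = _fit_line(self.pupil[:, 1], theta_req)
        return EyeModelParams(m_phi=m_phi, b_phi=b_phi, m_theta=m_theta, b_theta=b_theta)

    def residuals(self, vec) -> np.ndarray:
        """Per-sample pixel residual vector (2n,) at a candidate transform."""
        try:
            eye = self.eye_model_for(vec)
        except ValueError:
            return np.full(2 * len(self.targets), self.penalty)
        params = HeadEyeParams.from_vector(vec)
        e, R_e = _eye_poses(self.head_pos, self.R_h, params)
        phi = eye.m_phi * self.pupil[:, 0] + eye.b_phi
        theta = eye.m_theta * self.pupil[:, 1] + eye.b_theta
        dirs = gaze_direction(R_e, phi, theta)
        u, v, _on, valid = intersect_rays(self.screen, e, dirs)
        r = np.stack([u, v], axis=-1) - self.targets
        r[~valid] = self.penalty
        return np.nan_to_num(r, nan=self.penalty).ravel()

    def __call__(self, vec) -> float:
        try:
            eye = self.eye_model_for(vec)
        except ValueError:
            return self.penalty
        params = HeadEyeParams.from_vector(vec)
        e, R_e = _eye_poses(self.head_pos, self.R_h, params)
        phi = eye.m_phi * self.pupil[:, 0] + eye.b_phi
        theta = eye.m_theta * self.pupil[:, 1] + eye.b_theta
        dirs = gaze_direction(R_e, phi, theta)
        u, v, _on, valid = intersect_rays(self.screen, e, dirs)
        uv = np.stack([u, v], axis=-1)
        return _cost_from_predictions(uv, valid, self.targets, self.screen)


def calibrate_user(
    data: SessionDataset,
    screen: ScreenParams,
    *,
    x0=None,
    subset_size: int | None = None,
    offset_bound: float = DEFAULT_OFFSET_BOUND_CM,
    angle_bound: float = DEFAULT_ANGLE_BOUND_DEG,
    ftol: float = 1e-6,
    maxfev: int = 5000,
    method: str = "powell",
) -> CalibrationResult:
    """Fit the user-specific head-eye transform and eye model.

    Outer bounded derivative-free search over the six transform parameters
    with an exact inner linear-regression fit of the eye model for every
    candidate.  ``method="powell"`` (default) runs Powell's direction-set
    search and then polishes the optimum with a bounded trust-region
    least-squares refinement on the pixel residuals (finite-difference
    model, function evaluations only) — the calibration valley is narrow
    and curved and the polish converges its floor far faster than direction
    sets alone.  ``method="lsq"`` runs only the least-squares stage (used
    as the fast inner solver of the screen search).

    ``x0`` warm-starts the search (zeros by default); ``subset_size``
    optionally subsamples the data uniformly in time first.
    """
    from scipy.optimize import least_squares

    if method not in ("powell", "lsq"):
        raise ValueError("method must be 'powell' or 'lsq'")
    work = data.with_targets()
    if subset_size is not None:
        work = work.subsample(subset_size)
    obj = _UserObjective(work, screen)
    if x0 is None:
        x0 = np.zeros(6)
    x0 = np.asarray(x0, dtype=float)
    lb = np.array([-offset_bound] * 3 + [-angle_bound] * 3)
    ub = np.array([offset_bound] * 3 + [angle_bound] * 3)
    x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)
    nfev = 0
    best = x0
    success = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "powell":
            res = minimize(
                obj,
                x0,
                method="Powell",
                bounds=Bounds(lb, ub),
                options={"ftol": ftol, "xtol": 1e-6, "maxfev": maxfev},
            )
            nfev += int(res.nfev)
            success = bool(res.success)
            best = res.x if res.fun <= obj(x0) else x0
        pol = least_squares(
            obj.residuals,
            np.clip(best, lb + 1e-9, ub - 1e-9),
            bounds=(lb, ub),
            method="trf",
            diff_step=1e-4,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=200,
        )
        nfev += int(pol.nfev) * 7  # FD jacobian evaluations
        if obj(pol.x) <= obj(best):
            best = pol.x
    head_eye = HeadEyeParams.from_vector(best)
    eye = obj.eye_model_for(best)
    cost = obj(best)
    if not np.isfinite(cost):
        raise RuntimeError("calibration failed: non-finite objective at the optimum")
    return CalibrationResult(
        head_eye=head_eye,
        eye=eye,
        cost=cost,
        n_evaluations=nfev,
        converged=success,
    )


def _screen_from_vector(vec, shape_prior, fixed_size) -> ScreenParams:
    cx, cy, cz, a, b = vec[:5]
    if fixed_size is None:
        s_x, s_y = vec[5], vec[6]
    else:
        s_x, s_y = fixed_size
    ar, br = np.radians(a), np.radians(b)
    n = np.array([np.sin(ar) * np.cos(br), np.sin(br), np.cos(ar) * np.cos(br)])
    up = np.array([0.0, 1.0, 0.0]) - n[1] * n
    up = up / np.linalg.norm(up)
    return ScreenParams(
        c=np.array([cx, cy, cz]),
        n=n,
        up=up,
        s_x=float(s_x),
        s_y=float(s_y),
        s_u=shape_prior[0],
        s_v=shape_prior[1],
    )


def calibrate_screen(
    corpus,
    shape_prior=(1024, 768),
    *,
    initial: ScreenParams | None = None,
    fix_size: bool = False,
    subset_size: int = 500,
    center_bound_cm: float = 20.0,
    tilt_bound_deg: float = 15.0,
    size_bound_frac: float = 0.2,
    maxfev: int = 150,
    refine_maxiter: int = 80,
    ftol: float = 1e-8,
):
    """Estimate the display geometry from one or more users' sessions.

    The objective at a candidate screen is the sum over users of the
    per-user minimised calibration cost (each evaluation re-runs
    :func:`calibrate_user` on a uniform temporal subset).  The search runs
    over the screen centre, two normal-direction angles and — unless
    ``fix_size`` — the metric width and height; the pixel resolution comes
    from ``shape_prior`` and the in-plane roll is fixed by projecting the
    world up axis into the plane.  A bounded Powell stage handles the
    large-scale landscape, then a bounded trust-region least-squares
    refinement (finite-difference models on the stacked per-user residuals
    at their warm-started inner optima) converges the narrow valley.

    ``initial`` seeds the search (default: a fronto-parallel screen of the
    prior's aspect at the origin).  Per-user transform fits are warm-started
    from the previous outer iteration, which keeps the nested search cheap.
    Returns ``(ScreenParams, info dict)``; on non-convergence the best
    screen found so far is still returned, with ``info["converged"]=False``.
    """
    from scipy.optimize import least_squares
    corpus = [d.with_targets().subsample(subset_size) for d in corpus]
    if not corpus or any(len(d) == 0 for d in corpus):
        raise ValueError("screen calibration needs at least one non-empty dataset")
    if initial is None:
        initial = _screen_from_vector(
            np.array([0, 0, 0, 0, 0, 100.0, 100.0 * shape_prior[1] / shape_prior[0]]),
            shape_prior,
            None,
        )
    fixed_size = (initial.s_x, initial.s_y) if fix_size else None
    x0 = [initial.c[0], initial.c[1], initial.c[2]]
    a0 = np.degrees(np.arctan2(initial.n[0], initial.n[2]))
    b0 = np.degrees(np.arcsin(np.clip(initial.n[1], -1, 1)))
    x0 += [a0, b0]
    lb = [initial.c[i] - center_bound_cm for i in range(3)] + [a0 - tilt_bound_deg, b0 - tilt_bound_deg]
    ub = [initial.c[i] + center_bound_cm for i in range(3)] + [a0 + tilt_bound_deg, b0 + tilt_bound_deg]
    if not fix_size:
        x0 += [initial.s_x, initial.s_y]
        lb += [initial.s_x * (1 - size_bound_frac), initial.s_y * (1 - size_bound_frac)]
        ub += [initial.s_x * (1 + size_bound_frac), initial.s_y * (1 + size_bound_frac)]
    warm = [None] * len(corpus)

    history = []

    def inner_fit(vec):
        scr = _screen_from_vector(vec, shape_prior, fixed_size)
        for i, d in enumerate(corpus):
            res = calibrate_user(d, scr, x0=warm[i], method="lsq")
            warm[i] = res.head_eye.as_vector()
        return scr

    def objective(vec):
        try:
            scr = inner_fit(vec)
        except ValueError:
            return 1e9
        total = sum(
            _UserObjective(d, scr)(warm[i]) for i, d in enumerate(corpus)
        )
        history.append(total)
        return total

    def stacked_residuals(vec):
        try:
            scr = inner_fit(vec)
        except ValueError:
            return np.full(sum(2 * len(d) for d in corpus), 1e6)
        r = np.concatenate(
            [_UserObjective(d, scr).residuals(warm[i]) for i, d in enumerate(corpus)]
        )
        history.append(float(np.mean(np.linalg.norm(r.reshape(-1, 2), axis=1))))
        return r

    x = np.array(x0, dtype=float)
    total_nfev = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if maxfev > 0:
            res = minimize(
                objective,
                x,
                method="Powell",
                bounds=Bounds(lb, ub),
                options={"ftol": ftol, "xtol": 1e-6, "maxfev": maxfev},
            )
            total_nfev += int(res.nfev)
            if res.fun <= objective(x):
                x = res.x
        ref = least_squares(
            stacked_residuals,
            np.clip(x, np.array(lb) + 1e-9, np.array(ub) - 1e-9),
            bounds=(lb, ub),
            method="trf",
            diff_step=1e-3,
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-12,
            max_nfev=refine_maxiter,
        )
        total_nfev += int(ref.nfev) * (len(x) + 1)
        if objective(ref.x) <= objective(x):
            x = ref.x
    fun = objective(x)
    best_screen = _screen_from_vector(x, shape_prior, fixed_size)
    info = {
        "cost": fun,
        "n_evaluations": total_nfev,
        "converged": bool(ref.status > 0),
        "history": history,
    }
    return best_screen, info
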