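"""Calibration-validation protocol: splits, fixation filtering, angular
errors, the coverage-overlap statistic and confidence-based rejection.

Accuracy is reported in degrees of visual angle rather than pixels: for
every validation sample the estimated and the true POR are lifted to world
points on the screen, and the two direction vectors from the current head
position to those points are compared.  The *combined* error is the angle
between the vectors; *azimuth* and *elevation* errors are the differences
of their world-frame spherical coordinates (horizon plane = the world x-z
plane).  The combined error is frame-independent and is the primary metric.

The overlap statistic discretises a 5-D space — head position (10 cm bins)
and pupil position (1500 image-unit bins, the scale of raw video-tracker
coordinates) — and reports the proportion of bins occupied by the
validation data that the calibration data also visited.  Head orientation
is deliberately left out: including it would make the space too sparse to
populate.  Low overlap flags exactly the sessions where a purely
data-driven estimator must extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SessionDataset
from .geometric import calibrate_user, GeometricModel, predict_geometric_batch
from .gp import predict_por, train_gaze_gp
from .screen import ScreenParams, por_to_world

__all__ = [
    "EvalPairing",
    "ErrorSummary",
    "split_session",
    "filter_fixations",
    "angular_error",
    "angular_error_batch",
    "overlap_metric",
    "reject_by_confidence",
    "run_evaluation",
]

FIXATION_SETTLE_S = 1.25
CALIB_SPLIT_S = 120.0
HEAD_BIN_CM = 10.0
PUPIL_BIN_UNITS = 1500.0
SIGMA_REJECT_PX = 75.0


@dataclass
class EvalPairing:
    """One calibration/validation dataset pairing."""

    calib: SessionDataset
    valid: SessionDataset
    label: str = ""


@dataclass
class ErrorSummary:
    """Angular accuracy of one evaluation run."""

    azimuth_mean: float
    elevation_mean: float
    combined_mean: float
    per_sample: pd.DataFrame
    rejected_fraction: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "azimuth_mean_deg": self.azimuth_mean,
            "elevation_mean_deg": self.elevation_mean,
            "combined_mean_deg": self.combined_mean,
            "n_samples": int(len(self.per_sample)),
            "rejected_fraction": self.rejected_fraction,
            **self.extras,
        }


def filter_fixations(static_data: SessionDataset,
                     settle_s: float = FIXATION_SETTLE_S) -> SessionDataset:
    """Keep only the stable tail of each static presentation.

    The first ``settle_s`` (default 1.25 s) after each stimulus onset are
    dropped — the time the eye and head need to saccade toward and settle
    on the new target — leaving the final 250 ms of a 1.5 s presentation.
    Onsets are the first timestamp of each consecutive run of ``stim_id``.
    """
    df = static_data.df
    if len(df) == 0:
        return static_data
    sid = df["stim_id"].to_numpy()
    t = df["t_s"].to_numpy(float)
    run = np.r_[0, np.cumsum(np.diff(sid) != 0)]
    onset = pd.Series(t).groupby(run).transform("min").to_numpy()
    keep = (sid >= 0) & (t - onset >= settle_s)
    return static_data.select(keep)


def split_session(dynamic: SessionDataset, static: SessionDataset):
    """The four evaluation datasets from a session's two phases.

    Dynamic phase: first 2 min -> Calib-Dynamic, remainder (the last
    minute of a 3 min phase) -> Valid-Dynamic.  Static phase: stable
    fixations only, first 2 min -> Calib-Static, remainder (last 3 min)
    -> Valid-Static.  Split times are relative to each phase's start.
    Returns ``(calib_dynamic, valid_dynamic, calib_static, valid_static)``.
    """
    dyn = dynamic.phase("dynamic") if "dynamic" in set(dynamic.df["phase"]) else dynamic
    sta = static.phase("static") if "static" in set(static.df["phase"]) else static
    if len(dyn) == 0 or len(sta) == 0:
        raise ValueError("both phases must be non-empty")
    t0_dyn = dyn.t[0]
    t0_sta = sta.t[0]
    if dyn.t[-1] - t0_dyn < CALIB_SPLIT_S or sta.t[-1] - t0_sta < CALIB_SPLIT_S:
        raise ValueError("session too short to split at 2 minutes per phase")
    cd = dyn.time_slice(t0_dyn, t0_dyn + CALIB_SPLIT_S)
    vd = dyn.time_slice(t0_dyn + CALIB_SPLIT_S, np.inf)
    fixed = filter_fixations(sta)
    cs = fixed.time_slice(t0_sta, t0_sta + CALIB_SPLIT_S)
    vs = fixed.time_slice(t0_sta + CALIB_SPLIT_S, np.inf)
    return cd, vd, cs, vs


def _spherical(d):
    """World-frame azimuth/elevation (deg) of direction vectors.

    Azimuth is measured in the horizontal (x-z) plane from the screen-ward
    direction ``-z`` toward ``+x``; elevation from the horizon toward
    ``+y``.
    """
    d = np.asarray(d, float)
    norm = np.linalg.norm(d, axis=-1)
    az = np.degrees(np.arctan2(d[..., 0], -d[..., 2]))
    el = np.degrees(np.arcsin(np.clip(d[..., 1] / norm, -1, 1)))
    return az, el


def angular_error_batch(head_pos, est_uv, true_uv, screen: ScreenParams):
    """Per-sample (azimuth, elevation, combined) errors in degrees.

    Signed azimuth/elevation differences (estimated minus true) of the two
    head-to-POR direction vectors; combined is the full angle between them.
    """
    head_pos = np.atleast_2d(np.asarray(head_pos, float))
    est_uv = np.atleast_2d(np.asarray(est_uv, float))
    true_uv = np.atleast_2d(np.asarray(true_uv, float))
    on_plane = np.abs((head_pos - screen.c) @ screen.n) < 1e-9
    if np.any(on_plane):
        raise ValueError("head position lies on the screen plane")
    d_est = por_to_world(screen, est_uv[:, 0], est_uv[:, 1]) - head_pos
    d_true = por_to_world(screen, true_uv[:, 0], true_uv[:, 1]) - head_pos
    az_e, el_e = _spherical(d_est)
    az_t, el_t = _spherical(d_true)
    cross = np.linalg.norm(np.cross(d_est, d_true), axis=-1)
    dot = np.sum(d_est * d_true, axis=-1)
    combined = np.degrees(np.arctan2(cross, dot))
    return az_e - az_t, el_e - el_t, combined


def angular_error(head, est_por, true_por, screen: ScreenParams):
    """Scalar wrapper: one head pose, one estimated and one true POR."""
    az, el, comb = angular_error_batch(
        head.position, [est_por.u, est_por.v], [true_por.u, true_por.v], screen
    )
    return float(az[0]), float(el[0]), float(comb[0])


def _bins(data: SessionDataset):
    h = np.floor(data.head_positions / HEAD_BIN_CM).astype(int)
    p = np.floor(data.pupil / PUPIL_BIN_UNITS).astype(int)
    return set(map(tuple, np.hstack([h, p])))


def overlap_metric(calib: SessionDataset, valid: SessionDataset,
                   denominator: str = "all_valid") -> float:
    """Proportion of validation-occupied 5-D bins also visited in calibration.

    The space is (h_x, h_y, h_z, p_x, p_y) with 10 cm head bins and 1500
    image-unit pupil bins, half-open intervals anchored at the origin.
    ``denominator="all_valid"`` (default) divides by every bin the
    validation data occupies, giving a value in [0, 1];
    ``denominator="valid_only"`` divides by the bins occupied exclusively
    by validation, an alternative reading that can exceed 1.
    """
    if len(calib) == 0 or len(valid) == 0:
        raise ValueError("overlap requires non-empty datasets")
    bc, bv = _bins(calib), _bins(valid)
    joint = len(bc & bv)
    if denominator == "all_valid":
        return joint / len(bv)
    if denominator == "valid_only":
        only = len(bv - bc)
        return joint / only if only else np.inf
    raise ValueError("denominator must be 'all_valid' or 'valid_only'")


def reject_by_confidence(predictions, threshold_px: float = SIGMA_REJECT_PX):
    """Drop predictions whose mean predictive SD is at or above threshold.

    ``predictions`` is a list of :class:`~gazecal.gp.PORPrediction` (or an
    (n, 2) sigma array paired with anything indexable).  Returns
    ``(kept list, rejected_fraction)``.
    """
    if threshold_px <= 0:
        raise ValueError("threshold must be positive")
    preds = list(predictions)
    kept = [p for p in preds if p.mean_sigma < threshold_px]
    frac = 1.0 - len(kept) / len(preds) if preds else 0.0
    return kept, frac


def run_evaluation(
    pairing: EvalPairing,
    method: str,
    screen: ScreenParams,
    *,
    subset_size: int = 500,
    gp_max_train: int = 1500,
    reject_threshold_px: float | None = None,
    rng_seed: int | None = None,
) -> ErrorSummary:
    """Calibrate on ``pairing.calib``, predict on ``pairing.valid``, score.

    ``method`` is "geometric" or "gpr".  For the regression method the
    per-sample table carries the predictive SDs and, if
    ``reject_threshold_px`` is set, the summary statistics are computed
    after confidence-based rejection (the rejected fraction is reported
    either way, at the 75 px default threshold).
    """
    if method not in ("geometric", "gpr"):
        raise ValueError("method must be 'geometric' or 'gpr'")
    calib = pairing.calib.with_targets()
    valid = pairing.valid.with_targets()
    if len(calib) == 0 or len(valid) == 0:
        raise ValueError("pairing has an empty calibration or validation set")

    sigma = None
    if method == "geometric":
        res = calibrate_user(calib, screen, subset_size=subset_size)
        model = GeometricModel(head_eye=res.head_eye, eye=res.eye, screen=screen)
        est, valid_mask = predict_geometric_batch(model, valid)
        est = np.where(valid_mask[:, None], est, np.nan)
        extras = {"calibration_cost_px": res.cost}
    else:
        gps = train_gaze_gp(calib, subset_size=subset_size, max_train=gp_max_train)
        est, sigma = predict_por(gps, valid.X)
        extras = {}

    az, el, comb = angular_error_batch(valid.head_positions, est, valid.targets, screen)
    table = pd.DataFrame(
        {
            "t_s": valid.t,
            "est_u": est[:, 0],
            "est_v": est[:, 1],
            "true_u": valid.targets[:, 0],
            "true_v": valid.targets[:, 1],
            "azimuth_err_deg": az,
            "elevation_err_deg": el,
            "combined_err_deg": comb,
        }
    )
    rejected = 0.0
    keep = np.isfinite(comb)
    if sigma is not None:
        table["sigma_u"] = sigma[:, 0]
        table["sigma_v"] = sigma[:, 1]
        mean_sigma = sigma.mean(axis=1)
        rejected = float(np.mean(mean_sigma >= SIGMA_REJECT_PX))
        if reject_threshold_px is not None:
            keep &= mean_sigma < reject_threshold_px
            rejected = float(1.0 - keep.mean())
    return ErrorSummary(
        azimuth_mean=float(np.mean(np.abs(az[keep]))),
        elevation_mean=float(np.mean(np.abs(el[keep]))),
        combined_mean=float(np.mean(comb[keep])),
        per_sample=table,
        rejected_fraction=rejected,
        extras=extras,
    )
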