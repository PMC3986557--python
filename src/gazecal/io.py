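"""Session CSV reading/writing, mixed-rate stream alignment and model files.

The session file is a plain UTF-8 CSV with a mandatory header and one row
per aligned sample (columns documented on :mod:`gazecal.dataset`).  Floats
are written with 12 significant digits so that a fixed seed reproduces a
byte-identical file.

Calibrated models are JSON documents carrying a semantic version and a
``type`` tag.  A geometric model is fully contained in the JSON; a GP model
stores its hyperparameters in the JSON and its training arrays in a binary
``.npz`` sidecar next to the file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SESSION_COLUMNS, SessionDataset
from .geometric import EyeModelParams, GeometricModel, HeadEyeParams
from .gp import GazeGP, GPHyperParams
from .screen import ScreenParams

__all__ = [
    "read_session",
    "write_session",
    "align_streams",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1.0"
FLOAT_FMT = "%.12g"


def write_session(data: SessionDataset, path) -> None:
    """Write a session to CSV (deterministic float formatting)."""
    df = data.df[SESSION_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_session(path, user: str | None = None) -> SessionDataset:
    """Read and validate a session CSV.

    Raises with the first offending line number on missing columns,
    non-monotone timestamps or malformed numeric fields.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"{path}: empty session file") from e
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in SESSION_COLUMNS[:11]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() if col.startswith("stim") else vals.isna()
        if bad.any():
            # +2: header line and 1-based numbering
            raise ValueError(f"{path}: malformed value in column {col!r} "
                             f"at line {int(np.argmax(bad.to_numpy())) + 2}")
        df[col] = vals
    t = df["t_s"].to_numpy(float)
    drops = np.diff(t) < 0
    if drops.any():
        raise ValueError(f"{path}: time not non-decreasing at line "
                         f"{int(np.argmax(drops)) + 3}")
    df["stim_id"] = df["stim_id"].fillna(-1).astype(int)
    return SessionDataset(df, user=user or path.stem)


def _slerp_euler(t_src, angles_deg, t_query):
    """Shortest-arc interpolation of orientation streams (degrees in/out)."""
    from scipy.spatial.transform import Rotation, Slerp

    from .geometry import euler_from_rotation, rotation_from_euler

    R = rotation_from_euler(angles_deg[:, 0], angles_deg[:, 1], angles_deg[:, 2])
    sl = Slerp(t_src, Rotation.from_matrix(R))
    Rq = sl(np.clip(t_query, t_src[0], t_src[-1])).as_matrix()
    phi, theta, psi = euler_from_rotation(Rq)
    return np.stack([phi, theta, psi], axis=-1)


def align_streams(head_df: pd.DataFrame, pupil_df: pd.DataFrame) -> pd.DataFrame:
    """Merge head and pupil streams recorded at different rates.

    Both inputs need a ``t_s`` column; the head stream the six pose
    columns, the pupil stream ``p_x, p_y``.  The slower stream is resampled
    onto the faster stream's timestamps inside the overlap window — linear
    interpolation for positions and pupil coordinates, shortest-arc
    spherical interpolation for orientations.  Returns a DataFrame with the
    nine aligned columns.
    """
    t_h = head_df["t_s"].to_numpy(float)
    t_p = pupil_df["t_s"].to_numpy(float)
    lo, hi = max(t_h[0], t_p[0]), min(t_h[-1], t_p[-1])
    if hi < lo:
        raise ValueError("head and pupil streams do not overlap in time")
    rate_h = (len(t_h) - 1) / (t_h[-1] - t_h[0]) if len(t_h) > 1 else 0.0
    rate_p = (len(t_p) - 1) / (t_p[-1] - t_p[0]) if len(t_p) > 1 else 0.0
    t_out = (t_p if rate_p >= rate_h else t_h)
    t_out = t_out[(t_out >= lo) & (t_out <= hi)]

    out = pd.DataFrame({"t_s": t_out})
    for col in ("h_x", "h_y", "h_z"):
        out[col] = np.interp(t_out, t_h, head_df[col].to_numpy(float))
    ang = head_df[["h_phi", "h_theta", "h_psi"]].to_numpy(float)
    if len(t_h) > 1:
        interp_ang = _slerp_euler(t_h, ang, t_out)
    else:
        interp_ang = np.tile(ang[0], (len(t_out), 1))
    out[["h_phi", "h_theta", "h_psi"]] = interp_ang
    for col in ("p_x", "p_y"):
        out[col] = np.interp(t_out, t_p, pupil_df[col].to_numpy(float))
    return out


def save_model(model, path, *, kernel_form: str | None = None) -> None:
    """Serialize a calibrated model to JSON (+ ``.npz`` sidecar for GPs).

    ``model`` is either a :class:`GeometricModel` or a pair of trained
    :class:`GazeGP` objects.
    """
    path = Path(path)
    if isinstance(model, GeometricModel):
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "type": "geometric",
            "units": {"offsets": "cm", "angles": "deg",
                      "eye_slope": "deg_per_image_unit"},
            "head_eye": vars(model.head_eye),
            "eye": vars(model.eye),
            "screen": model.screen.to_dict(),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        return
    gp_u, gp_v = model
    sidecar = path.with_suffix(".npz")
    np.savez(sidecar, X_u=gp_u.train_X, y_u=gp_u.train_y,
             X_v=gp_v.train_X, y_v=gp_v.train_y)
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "type": "gpr",
        "kernel_form": kernel_form or gp_u.form,
        "theta_u": gp_u.theta.to_dict(),
        "theta_v": gp_v.theta.to_dict(),
        "sidecar": sidecar.name,
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path):
    """Load a model written by :func:`save_model`."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc["type"] == "geometric":
        return GeometricModel(
            head_eye=HeadEyeParams(**doc["head_eye"]),
            eye=EyeModelParams(**doc["eye"]),
            screen=ScreenParams.from_dict(doc["screen"]),
        )
    if doc["type"] == "gpr":
        arrays = np.load(path.parent / doc["sidecar"])
        form = doc["kernel_form"]
        gp_u = GazeGP(arrays["X_u"], arrays["y_u"],
                      GPHyperParams(doc["theta_u"]["sigma_s"], doc["theta_u"]["sigma_n"],
                                    doc["theta_u"]["lengthscales"]), form=form)
        gp_v = GazeGP(arrays["X_v"], arrays["y_v"],
                      GPHyperParams(doc["theta_v"]["sigma_s"], doc["theta_v"]["sigma_n"],
                                    doc["theta_v"]["lengthscales"]), form=form)
        return gp_u, gp_v
    raise ValueError(f"unknown model type {doc['type']!r}")
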