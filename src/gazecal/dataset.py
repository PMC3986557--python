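"""Time-ordered session data: aligned (head pose, pupil, stimulus) samples.

A :class:`SessionDataset` wraps a pandas DataFrame with one row per aligned
sample and the columns

    t_s, h_x, h_y, h_z, h_phi, h_theta, h_psi, p_x, p_y,
    stim_u, stim_v, phase, stim_id

(`stim_u`/`stim_v` are NaN when no stimulus was shown; `phase` is one of
"dynamic", "static", "none"; `stim_id` is -1 outside static presentations).
Positions are cm in the world frame, orientation angles are degrees and the
pupil coordinates are dimensionless eye-camera image units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import rotation_from_euler

__all__ = ["SESSION_COLUMNS", "SessionDataset"]

SESSION_COLUMNS = [
    "t_s",
    "h_x",
    "h_y",
    "h_z",
    "h_phi",
    "h_theta",
    "h_psi",
    "p_x",
    "p_y",
    "stim_u",
    "stim_v",
    "phase",
    "stim_id",
]

_NUMERIC = SESSION_COLUMNS[:11]


@dataclass
class SessionDataset:
    """Calibration/validation data of one user: the set {x, y}_n."""

    df: pd.DataFrame
    user: str = "anonymous"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in SESSION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"session data missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        t = self.df["t_s"].to_numpy(float)
        if len(t) and np.any(np.diff(t) < 0):
            bad = int(np.argmax(np.diff(t) < 0)) + 1
            raise ValueError(f"timestamps not non-decreasing at row {bad}")

    def __len__(self) -> int:
        return len(self.df)

    # ---- column views -------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.df["t_s"].to_numpy(float)

    @property
    def head_positions(self) -> np.ndarray:
        return self.df[["h_x", "h_y", "h_z"]].to_numpy(float)

    @property
    def head_angles(self) -> np.ndarray:
        return self.df[["h_phi", "h_theta", "h_psi"]].to_numpy(float)

    @property
    def head_rotations(self) -> np.ndarray:
        """Stack of head orientation matrices, shape (n, 3, 3)."""
        a = self.head_angles
        return rotation_from_euler(a[:, 0], a[:, 1], a[:, 2])

    @property
    def pupil(self) -> np.ndarray:
        return self.df[["p_x", "p_y"]].to_numpy(float)

    @property
    def targets(self) -> np.ndarray:
        """Known stimulus POR per sample, shape (n, 2) pixels."""
        return self.df[["stim_u", "stim_v"]].to_numpy(float)

    @property
    def X(self) -> np.ndarray:
        """The 8-D regression inputs (h_x..h_psi, p_x, p_y), shape (n, 8)."""
        return self.df[["h_x", "h_y", "h_z", "h_phi", "h_theta", "h_psi", "p_x", "p_y"]].to_numpy(
            float
        )

    # ---- slicing ------------------------------------------------------
    def _wrap(self, df: pd.DataFrame) -> "SessionDataset":
        return SessionDataset(df.reset_index(drop=True), user=self.user, meta=dict(self.meta))

    def select(self, mask) -> "SessionDataset":
        return self._wrap(self.df.loc[np.asarray(mask, bool)])

    def phase(self, name: str) -> "SessionDataset":
        return self.select(self.df["phase"].to_numpy() == name)

    def time_slice(self, t0: float, t1: float) -> "SessionDataset":
        t = self.t
        return self.select((t >= t0) & (t < t1))

    def with_targets(self) -> "SessionDataset":
        tg = self.targets
        return self.select(np.isfinite(tg).all(axis=1))

    def subsample(self, n: int) -> "SessionDataset":
        """Uniform temporal subsample of at most ``n`` rows (the subset D')."""
        if n >= len(self):
            return self
        idx = np.unique(np.round(np.linspace(0, len(self) - 1, n)).astype(int))
        return self._wrap(self.df.iloc[idx])

    @staticmethod
    def concat(parts) -> "SessionDataset":
        parts = list(parts)
        df = pd.concat([p.df for p in parts], ignore_index=True)
        df = df.sort_values("t_s", kind="stable").reset_index(drop=True)
        return SessionDataset(df, user=parts[0].user if parts else "anonymous")

    @staticmethod
    def from_arrays(t, head_pos, head_ang, pupil, stim_uv, phase, stim_id, user="anonymous"):
        n = len(t)
        stim_uv = np.asarray(stim_uv, float).reshape(n, 2)
        df = pd.DataFrame(
            {
                "t_s": np.asarray(t, float),
                "h_x": head_pos[:, 0],
                "h_y": head_pos[:, 1],
                "h_z": head_pos[:, 2],
                "h_phi": head_ang[:, 0],
                "h_theta": head_ang[:, 1],
                "h_psi": head_ang[:, 2],
                "p_x": np.asarray(pupil, float)[:, 0],
                "p_y": np.asarray(pupil, float)[:, 1],
                "stim_u": stim_uv[:, 0],
                "stim_v": stim_uv[:, 1],
                "phase": phase,
                "stim_id": np.asarray(stim_id, int),
            }
        )
        return SessionDataset(df, user=user)
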