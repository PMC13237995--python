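"""Flexion pose series: loading, validation, varus–valgus correction, resampling.

A :class:`FlexionPoseSeries` is an ordered list of (flexion angle, femur
pose relative to the tibia) frames for one subject, e.g. a weight-bearing
lunge from 0° to 100°.  The canonical on-disk form is a CSV with columns
``flexion_deg, AP_mm, PD_mm, ML_mm, FE_deg, AA_deg, IE_deg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import RigidPose

__all__ = [
    "FlexionPoseSeries",
    "StandingAlignment",
    "load_series",
    "save_series",
    "correct_varus_valgus",
    "resample",
]

CSV_COLUMNS = ["flexion_deg", "AP_mm", "PD_mm", "ML_mm", "FE_deg", "AA_deg", "IE_deg"]


@dataclass(frozen=True)
class StandingAlignment:
    """Static alignment from standing radiographs.

    ``hka_deg`` is the hip–knee–ankle mechanical-axis deviation, positive
    varus; ``posterior_slope_deg`` the native tibial posterior slope.
    """

    hka_deg: float = 0.0
    posterior_slope_deg: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.hka_deg) >= 30:
            raise ValueError("|HKA| must be below 30 degrees")


@dataclass
class FlexionPoseSeries:
    frames: list[tuple[float, RigidPose]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = sorted(self.frames, key=lambda f: f[0])
        angles = self.angles()
        if len(angles) >= 2 and np.any(np.diff(angles) <= 0):
            raise ValueError("duplicate flexion angles in series")

    def angles(self) -> np.ndarray:
        return np.array([a for a, _ in self.frames])

    def poses(self) -> list[RigidPose]:
        return [p for _, p in self.frames]

    def frame_at(self, flexion_deg: float, tol: float = 1e-6) -> tuple[float, RigidPose]:
        for a, p in self.frames:
            if abs(a - flexion_deg) <= tol:
                return a, p
        raise KeyError(f"no frame at flexion {flexion_deg} deg")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [[a, p.AP_mm, p.PD_mm, p.ML_mm, p.FE_deg, p.AA_deg, p.IE_deg]
                for a, p in self.frames]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)

    def __len__(self) -> int:
        return len(self.frames)


def _series_from_dataframe(df: pd.DataFrame, subject_id: str) -> FlexionPoseSeries:
    frames = [
        (
            float(r.flexion_deg),
            RigidPose(
                AP_mm=float(r.AP_mm), PD_mm=float(r.PD_mm), ML_mm=float(r.ML_mm),
                FE_deg=float(r.FE_deg), AA_deg=float(r.AA_deg), IE_deg=float(r.IE_deg),
            ),
        )
        for r in df.itertuples()
    ]
    return FlexionPoseSeries(frames=frames, subject_id=subject_id)


def load_series(path, subject_id: str = "") -> FlexionPoseSeries:
    """Read and validate a kinematics CSV.

    Rejects missing columns, NaN entries (naming the offending row) and
    duplicate flexion angles; rows are sorted by ascending flexion.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinematics CSV missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("kinematics CSV contains no frames")
    bad = df[CSV_COLUMNS].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"malformed (NaN) kinematics row {row + 2} in {path}")
    if df["flexion_deg"].duplicated().any():
        dup = float(df.loc[df["flexion_deg"].duplicated(), "flexion_deg"].iloc[0])
        raise ValueError(f"duplicate flexion angle {dup} deg in {path}")
    return _series_from_dataframe(df.sort_values("flexion_deg"), subject_id)


def save_series(series: FlexionPoseSeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def correct_varus_valgus(
    series: FlexionPoseSeries, alignment: StandingAlignment
) -> FlexionPoseSeries:
    """Remove the standing coronal deformity from every frame.

    The correction is a constant abduction–adduction shift of ``-hka_deg``
    applied to each frame; all other degrees of freedom are untouched.
    """
    frames = [
        (a, RigidPose(p.AP_mm, p.PD_mm, p.ML_mm, p.FE_deg,
                      p.AA_deg - alignment.hka_deg, p.IE_deg))
        for a, p in series.frames
    ]
    return FlexionPoseSeries(frames=frames, subject_id=series.subject_id)


def resample(series: FlexionPoseSeries, angles) -> FlexionPoseSeries:
    """Per-DOF linear interpolation of the series onto ``angles``.

    Requested angles must lie within the observed flexion range
    (no extrapolation).
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    src = series.angles()
    if len(src) < 2:
        raise ValueError("need at least two frames to resample")
    if angles.min() < src[0] - 1e-9 or angles.max() > src[-1] + 1e-9:
        raise ValueError(
            f"requested angles [{angles.min()}, {angles.max()}] outside "
            f"observed range [{src[0]}, {src[-1]}]"
        )
    dof = np.array([p.as_array() for p in series.poses()])  # (n, 6)
    frames = []
    for a in angles:
        vals = [float(np.interp(a, src, dof[:, j])) for j in range(6)]
        frames.append((float(a), RigidPose.from_array(vals)))
    return FlexionPoseSeries(frames=frames, subject_id=series.subject_id)
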