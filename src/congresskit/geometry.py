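"""Spindle reference frame and per-frame sister-pair kinematics.

The spindle frame is rebuilt on every time point from the two tracked
centrosomes: the equatorial (metaphase) plane passes through the midpoint of
the pole-pole segment, perpendicular to it.  All pair-level kinematic
quantities (distance to that plane, distance to the nearest pole,
interkinetochore distance, positional and orientation angles) are derived in
this frame.

Positions are in micrometres, time in minutes.  The default mode is
projected-2D (tracking on maximum-intensity projections); the identical
formulas apply in 3D, where the z column is simply kept.  Tracking gaps are
first-class: short gaps (<= ``max_gap`` frames) are filled by linear
interpolation, longer gaps leave the frame undefined rather than fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSpindleError,
    EmptyKinematicsError,
    EmptyOverlapError,
    UndefinedAngleError,
    UndefinedFrameError,
)

#: default minimum pole separation (um) below which a spindle frame is undefined
EPS_POLE_DEFAULT = 1.0
#: default maximum gap length (frames) bridged by linear interpolation
MAX_GAP_DEFAULT = 2


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped positions of one tracked object (pole or kinetochore).

    Parameters
    ----------
    object_id : str
        Identifier unique within a cell.
    object_type : {'pole', 'kinetochore'}
    frame : array of int
        Strictly increasing 0-based frame indices; missing frames are gaps.
    t : array of float
        Time in minutes, strictly increasing, aligned with ``frame``.
    xyz : array, shape (n, 3)
        Positions in um.  In projected-2D data the z column is zero.
    dt : float
        Nominal frame interval in minutes.
    """

    object_id: str
    object_type: str
    frame: np.ndarray
    t: np.ndarray
    xyz: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.frame.size == 0:
            raise ValueError(f"trajectory {self.object_id!r} is empty")
        if self.xyz.shape != (self.frame.size, 3):
            raise ValueError("xyz must have shape (n_frames, 3)")
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError("frames must be strictly increasing")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return int(self.frame.size)


@dataclass
class SisterPairTrack:
    """Two sister-kinetochore trajectories sharing a time base."""

    pair_id: str
    cell_id: str
    sister1: Trajectory
    sister2: Trajectory

    def __post_init__(self) -> None:
        if self.sister1.dt != self.sister2.dt:
            raise ValueError("sisters must share the declared frame interval")


def _interpolate_gaps(
    frame: np.ndarray, t: np.ndarray, xyz: np.ndarray, max_gap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resample onto the contiguous frame range, bridging short gaps.

    Returns (full_frames, t_full, xyz_full, defined) where ``defined`` marks
    frames that are observed or interpolated across a gap of <= max_gap
    missing frames.  Values on undefined frames are NaN.
    """
    full = np.arange(frame[0], frame[-1] + 1)
    observed = np.isin(full, frame)
    t_full = np.interp(full, frame, t)
    xyz_full = np.column_stack([np.interp(full, frame, xyz[:, k]) for k in range(3)])
    defined = observed.copy()
    # mark interpolated frames inside short gaps as defined
    gap_start = None
    for i, obs in enumerate(observed):
        if not obs and gap_start is None:
            gap_start = i
        elif obs and gap_start is not None:
            if i - gap_start <= max_gap:
                defined[gap_start:i] = True
            gap_start = None
    t_full = np.where(defined, t_full, np.nan)
    xyz_full = np.where(defined[:, None], xyz_full, np.nan)
    return full, t_full, xyz_full, defined


# ---------------------------------------------------------------------------
# spindle frame series
# ---------------------------------------------------------------------------

class FrameGeometry(NamedTuple):
    """Spindle geometry on a single frame."""

    pole_a: np.ndarray
    pole_b: np.ndarray
    midpoint: np.ndarray
    axis: np.ndarray
    separation: float


@dataclass
class SpindleFrameSeries:
    """Per-frame pole positions, midpoint, unit spindle axis and separation.

    Frames where either pole is untracked (beyond gap interpolation) or where
    the pole separation L <= eps_pole carry ``defined == False`` and NaN
    values; they are never fabricated.
    """

    frame: np.ndarray
    t: np.ndarray
    pole_a: np.ndarray
    pole_b: np.ndarray
    defined: np.ndarray
    midpoint: np.ndarray = field(init=False)
    axis: np.ndarray = field(init=False)
    separation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.midpoint = 0.5 * (self.pole_a + self.pole_b)
        diff = self.pole_b - self.pole_a
        self.separation = np.linalg.norm(diff, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.axis = diff / self.separation[:, None]

    def index_of(self, frame: int) -> int:
        i = int(frame) - int(self.frame[0])
        if i < 0 or i >= self.frame.size:
            raise UndefinedFrameError(f"frame {frame} outside spindle series")
        return i

    def at(self, frame: int) -> FrameGeometry:
        """Geometry on one frame; raises if the frame is undefined."""
        i = self.index_of(frame)
        if not self.defined[i]:
            raise UndefinedFrameError(f"spindle frame {frame} is undefined")
        return FrameGeometry(
            self.pole_a[i], self.pole_b[i], self.midpoint[i],
            self.axis[i], float(self.separation[i]),
        )


def _project_mode(xyz: np.ndarray, mode: str) -> np.ndarray:
    if mode == "2d":
        out = xyz.copy()
        out[..., 2] = 0.0
        return out
    if mode == "3d":
        return xyz
    raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")


def build_spindle_frames(
    pole_a: Trajectory,
    pole_b: Trajectory,
    eps_pole: float = EPS_POLE_DEFAULT,
    max_gap: int = MAX_GAP_DEFAULT,
    mode: str = "2d",
) -> SpindleFrameSeries:
    """Reconstruct the spindle reference frame from the two pole tracks.

    The axis unit vector is u = (poleB - poleA)/||poleB - poleA|| and the
    equatorial plane passes through the midpoint m = (poleA + poleB)/2,
    perpendicular to u.  Frames with separation L <= eps_pole are marked
    undefined.

    Raises
    ------
    EmptyOverlapError
        If the two pole tracks share no frames after gap interpolation.
    DegenerateSpindleError
        If no frame has separation above ``eps_pole``.
    """
    fa, ta, xa, da = _interpolate_gaps(pole_a.frame, pole_a.t, pole_a.xyz, max_gap)
    fb, tb, xb, db = _interpolate_gaps(pole_b.frame, pole_b.t, pole_b.xyz, max_gap)
    lo, hi = max(fa[0], fb[0]), min(fa[-1], fb[-1])
    if lo > hi:
        raise EmptyOverlapError("pole tracks share no overlapping frames")
    frames = np.arange(lo, hi + 1)
    ia, ib = frames - fa[0], frames - fb[0]
    defined = da[ia] & db[ib]
    if not defined.any():
        raise EmptyOverlapError("pole tracks share no defined frames")
    pa = _project_mode(xa[ia], mode)
    pb = _project_mode(xb[ib], mode)
    t = np.where(defined, np.where(np.isnan(ta[ia]), tb[ib], ta[ia]), np.nan)
    sep = np.linalg.norm(pb - pa, axis=1)
    with np.errstate(invalid="ignore"):
        collapsed = defined & ~(sep > eps_pole)
    defined = defined & ~collapsed
    if not defined.any():
        raise DegenerateSpindleError(
            f"pole separation never exceeds eps_pole={eps_pole} um"
        )
    pa = np.where(defined[:, None], pa, np.nan)
    pb = np.where(defined[:, None], pb, np.nan)
    return SpindleFrameSeries(frame=frames, t=t, pole_a=pa, pole_b=pb, defined=defined)


# ---------------------------------------------------------------------------
# point-level operations
# ---------------------------------------------------------------------------

def pair_center(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Arithmetic midpoint of the two sister positions."""
    return 0.5 * (np.asarray(p1, float) + np.asarray(p2, float))


def interkinetochore_distance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Euclidean distance between sister kinetochore centers (um)."""
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))


def distance_to_equatorial_plane(
    p: np.ndarray, frames: SpindleFrameSeries, frame: int
) -> float:
    """Nearest distance from a point to the equatorial plane, |(p - m) . u|.

    In projected-2D mode the plane degenerates to the perpendicular line
    through the midpoint; the formula is unchanged.
    """
    g = frames.at(frame)
    return float(abs(np.dot(np.asarray(p, float) - g.midpoint, g.axis)))


def distance_to_nearest_pole(
    p: np.ndarray, frames: SpindleFrameSeries, frame: int
) -> tuple[float, str]:
    """Distance to the nearest spindle pole and its label; exact tie -> 'A'."""
    g = frames.at(frame)
    p = np.asarray(p, float)
    da = float(np.linalg.norm(p - g.pole_a))
    db = float(np.linalg.norm(p - g.pole_b))
    return (da, "A") if da <= db else (db, "B")


def _acute_angle_deg(v: np.ndarray, w: np.ndarray) -> float:
    """Acute angle between the lines spanned by v and w, in [0, 90] degrees."""
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise UndefinedAngleError("zero-length direction vector")
    c = abs(float(np.dot(v, w))) / (nv * nw)
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def positional_angle(c: np.ndarray, frames: SpindleFrameSeries, frame: int) -> float:
    """Angle between the pole-pole line and the line joining the pair center
    to its nearest pole, reported as the acute value in [0, 90] degrees."""
    g = frames.at(frame)
    c = np.asarray(c, float)
    _, label = distance_to_nearest_pole(c, frames, frame)
    pole = g.pole_a if label == "A" else g.pole_b
    v = c - pole
    if np.linalg.norm(v) == 0:
        raise UndefinedAngleError("pair center coincides with its nearest pole")
    return _acute_angle_deg(v, g.axis)


def pair_orientation_angle(
    p1: np.ndarray, p2: np.ndarray, frames: SpindleFrameSeries, frame: int
) -> float:
    """Acute angle between the sister-sister axis and the spindle axis."""
    g = frames.at(frame)
    d = np.asarray(p2, float) - np.asarray(p1, float)
    if np.linalg.norm(d) == 0:
        raise UndefinedAngleError("coincident sisters")
    return _acute_angle_deg(d, g.axis)


# ---------------------------------------------------------------------------
# per-pair kinematics assembly
# ---------------------------------------------------------------------------

#: columns of the kinematics table produced by :func:`compute_pair_kinematics`
KINEMATICS_COLUMNS = [
    "frame", "t", "cx", "cy", "cz", "d_plane", "d_pole", "nearest_pole",
    "d_kt", "theta_pos", "theta_orient",
]


def compute_pair_kinematics(
    pair: SisterPairTrack,
    frames: SpindleFrameSeries,
    max_gap: int = MAX_GAP_DEFAULT,
    mode: str = "2d",
) -> pd.DataFrame:
    """Assemble the per-frame kinematics table for one sister pair.

    One row per frame on which both sisters and the spindle frame are defined
    (after gap interpolation).  Columns: pair center (cx, cy, cz), distance to
    the equatorial plane ``d_plane``, distance to the nearest pole ``d_pole``
    with its label, interkinetochore distance ``d_kt``, positional angle
    ``theta_pos`` and sister-axis orientation angle ``theta_orient`` (both
    acute, degrees; NaN where geometrically undefined).

    Raises
    ------
    EmptyKinematicsError
        If no frame has both sisters and the spindle frame defined.
    """
    f1, t1, x1, d1 = _interpolate_gaps(
        pair.sister1.frame, pair.sister1.t, pair.sister1.xyz, max_gap
    )
    f2, _, x2, d2 = _interpolate_gaps(
        pair.sister2.frame, pair.sister2.t, pair.sister2.xyz, max_gap
    )
    lo = max(f1[0], f2[0], frames.frame[0])
    hi = min(f1[-1], f2[-1], frames.frame[-1])
    if lo > hi:
        raise EmptyKinematicsError(f"pair {pair.pair_id}: no joint frame support")
    fr = np.arange(lo, hi + 1)
    i1, i2, isf = fr - f1[0], fr - f2[0], fr - frames.frame[0]
    ok = d1[i1] & d2[i2] & frames.defined[isf]
    if not ok.any():
        raise EmptyKinematicsError(f"pair {pair.pair_id}: no jointly defined frame")
    fr = fr[ok]
    p1 = _project_mode(x1[i1][ok], mode)
    p2 = _project_mode(x2[i2][ok], mode)
    t = t1[i1][ok]
    g_m = frames.midpoint[isf][ok]
    g_u = frames.axis[isf][ok]
    g_a = frames.pole_a[isf][ok]
    g_b = frames.pole_b[isf][ok]

    c = 0.5 * (p1 + p2)
    d_plane = np.abs(np.einsum("ij,ij->i", c - g_m, g_u))
    da = np.linalg.norm(c - g_a, axis=1)
    db = np.linalg.norm(c - g_b, axis=1)
    nearest = np.where(da <= db, "A", "B")
    d_pole = np.minimum(da, db)
    d_kt = np.linalg.norm(p1 - p2, axis=1)

    def acute(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.abs(np.einsum("ij,ij->i", v, g_u)) / n
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        return np.where(n > 0, ang, np.nan)

    pole_pts = np.where((da <= db)[:, None], g_a, g_b)
    theta_pos = acute(c - pole_pts)
    theta_orient = acute(p2 - p1)

    return pd.DataFrame(
        {
            "frame": fr,
            "t": t,
            "cx": c[:, 0],
            "cy": c[:, 1],
            "cz": c[:, 2],
            "d_plane": d_plane,
            "d_pole": d_pole,
            "nearest_pole": nearest,
            "d_kt": d_kt,
            "theta_pos": theta_pos,
            "theta_orient": theta_orient,
        }
    )
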