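"""Polar/aligned classification, congression-event detection and velocimetry.

Decision rules, with positions relative to the spindle frame of
:mod:`congresskit.geometry`:

* a pair is **polar** on a frame when it is strictly closer to a spindle pole
  than to the equatorial plane (d_pole < d_plane);
* a pair is **aligned-ever** when its center came within 3 um of the
  equatorial plane on any frame (inclusive boundary);
* the **plate crossing** is the first frame on which the pair-center distance
  to the plane drops strictly below 2 um (no persistence requirement by
  default; an optional minimum dwell is available);
* the **congression velocity** is the signed decrease of distance-to-plane
  over the last ``velocity_window`` minutes before the crossing (6 min
  default, 4 min in the U2OS preset), positive toward the plate;
* **alignment success** of an initially polar pair means reaching within 2 um
  of the plane within 30 min of the reference event;
* polar pairs are **counted** at 12 min after mitosis onset and every 6 min
  thereafter;
* cells are **categorised** by misalignment: no plate formed / high (>= 5
  chromosomes outside the plate) / low (1-4 outside) / tight (none outside).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import (
    InsufficientWindowError,
    UndefinedDenominatorError,
    UndefinedFrameError,
)


@dataclass(frozen=True)
class AlignmentThresholds:
    """Thresholds and schedules governing the congression decision rules.

    All distances in um, times in minutes.  ``d_align_ever`` is the inclusive
    aligned-at-any-time boundary; ``d_success`` is the strict plate-crossing
    boundary (also the inclusive success boundary for the 30-min rule);
    ``min_dwell`` optionally requires the pair to stay below ``d_success``
    for that many consecutive defined frames after the crossing.
    """

    d_align_ever: float = 3.0
    d_success: float = 2.0
    success_window: float = 30.0
    velocity_window: float = 6.0
    count_start: float = 12.0
    count_step: float = 6.0
    min_dwell: int = 0

    def __post_init__(self) -> None:
        for name in (
            "d_align_ever", "d_success", "success_window",
            "velocity_window", "count_start", "count_step",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.d_success > self.d_align_ever:
            raise ValueError("d_success must not exceed d_align_ever")

    def u2os(self) -> "AlignmentThresholds":
        """Preset with the shorter 4-min velocity window used for U2OS cells."""
        return replace(self, velocity_window=4.0)


@dataclass(frozen=True)
class CongressionEvent:
    """Plate-crossing time and windowed signed velocity for one pair."""

    pair_id: str
    t_cross: Optional[float]
    v_congress: Optional[float]
    window_used: Optional[float]


def _row_at(kin: pd.DataFrame, frame: int) -> pd.Series:
    hit = kin.loc[kin["frame"] == frame]
    if hit.empty:
        raise UndefinedFrameError(f"no kinematics on frame {frame}")
    return hit.iloc[0]


def classify_polar(kin: pd.DataFrame, frame: int) -> bool:
    """True iff the pair is strictly closer to a pole than to the plane."""
    row = _row_at(kin, frame)
    return bool(row["d_pole"] < row["d_plane"])


def polar_mask(kin: pd.DataFrame) -> pd.Series:
    """Vectorised polar classification over all frames of one pair."""
    return kin["d_pole"] < kin["d_plane"]


def classify_aligned_ever(kin: pd.DataFrame, thresholds: AlignmentThresholds) -> bool:
    """True iff the pair came within ``d_align_ever`` of the plane on any frame."""
    if kin.empty:
        raise ValueError("empty kinematics")
    return bool(kin["d_plane"].min() <= thresholds.d_align_ever)


def detect_plate_crossing(
    kin: pd.DataFrame, thresholds: AlignmentThresholds
) -> Optional[float]:
    """Time of the first frame with d_plane strictly below ``d_success``.

    With ``min_dwell`` > 0 the pair must additionally remain below the
    boundary for that many consecutive defined frames starting at the
    crossing.  Returns None if the pair never crosses.
    """
    if kin.empty:
        raise ValueError("empty kinematics")
    below = (kin["d_plane"] < thresholds.d_success).to_numpy()
    n = thresholds.min_dwell
    for i in np.flatnonzero(below):
        if n <= 1:
            return float(kin["t"].iloc[i])
        if i + n <= below.size and bool(below[i : i + n].all()):
            return float(kin["t"].iloc[i])
    return None


def congression_velocity(
    kin: pd.DataFrame, t_cross: float, thresholds: AlignmentThresholds
) -> tuple[float, float]:
    """Signed congression velocity over the window before the plate crossing.

    v = (d_plane(t_cross - w_eff) - d_plane(t_cross)) / w_eff, positive toward
    the plate.  ``w_eff`` is the nominal ``velocity_window`` shortened to the
    span actually covered by defined frames; spans below half the window raise
    :class:`InsufficientWindowError`.  Returns ``(v, w_eff)``.
    """
    w = thresholds.velocity_window
    sel = kin.loc[(kin["t"] >= t_cross - w) & (kin["t"] <= t_cross)]
    if sel.empty or sel["t"].iloc[-1] != t_cross:
        raise UndefinedFrameError(f"no kinematics at crossing time {t_cross}")
    w_eff = float(t_cross - sel["t"].iloc[0])
    if w_eff < w / 2.0:
        raise InsufficientWindowError(
            f"window coverage {w_eff:.2f} min < {w / 2:.2f} min before crossing"
        )
    d0 = float(sel["d_plane"].iloc[0])
    d1 = float(sel["d_plane"].iloc[-1])
    return (d0 - d1) / w_eff, w_eff


def mean_speed_over_interval(
    kin: pd.DataFrame, t0: float, duration: float
) -> float:
    """Mean signed approach speed (d_plane(t0) - d_plane(t0+duration)) / duration.

    The nearest defined frames within one nominal frame interval of each
    endpoint are used; unresolvable endpoints raise.
    """
    t = kin["t"].to_numpy()
    dt_nominal = float(np.median(np.diff(t))) if t.size > 1 else np.inf

    def nearest(target: float) -> float:
        i = int(np.argmin(np.abs(t - target)))
        if abs(t[i] - target) > dt_nominal + 1e-9:
            raise UndefinedFrameError(f"no defined frame within one dt of t={target}")
        return float(kin["d_plane"].iloc[i])

    return (nearest(t0) - nearest(t0 + duration)) / duration


def alignment_success_fraction(
    pair_kinematics: Mapping[str, pd.DataFrame],
    thresholds: AlignmentThresholds,
    t_ref: float = 0.0,
) -> tuple[float, int, int]:
    """Percentage of initially polar pairs reaching the plate within the window.

    A pair counts as initially polar when it is polar on its first defined
    frame at or after ``t_ref``; it succeeds when d_plane <= ``d_success`` on
    any defined frame in (t_ref, t_ref + success_window].  Pairs lost before
    the window ends that never crossed count as failures.  Returns
    ``(percentage, n_success, n_polar)``.

    Raises
    ------
    UndefinedDenominatorError
        If no pair is polar at the reference time.
    """
    n_polar = 0
    n_success = 0
    t_end = t_ref + thresholds.success_window
    for kin in pair_kinematics.values():
        start = kin.loc[kin["t"] >= t_ref]
        if start.empty:
            continue
        row0 = start.iloc[0]
        if not row0["d_pole"] < row0["d_plane"]:
            continue
        n_polar += 1
        win = kin.loc[(kin["t"] > t_ref) & (kin["t"] <= t_end)]
        if not win.empty and (win["d_plane"] <= thresholds.d_success).any():
            n_success += 1
    if n_polar == 0:
        raise UndefinedDenominatorError("no pair is polar at the reference time")
    return 100.0 * n_success / n_polar, n_success, n_polar


def polar_counts_timeline(
    pair_kinematics: Mapping[str, pd.DataFrame],
    thresholds: AlignmentThresholds,
    t_end: float,
) -> list[tuple[float, int]]:
    """Counts of polar pairs at t = count_start, +count_step, ... <= t_end.

    A pair contributes at a time point when it has a defined frame within half
    a counting step of that time; the nearest such frame is classified.
    """
    times = np.arange(thresholds.count_start, t_end + 1e-9, thresholds.count_step)
    out: list[tuple[float, int]] = []
    for tc in times:
        count = 0
        for kin in pair_kinematics.values():
            t = kin["t"].to_numpy()
            i = int(np.argmin(np.abs(t - tc)))
            if abs(t[i] - tc) > thresholds.count_step / 2.0:
                continue
            row = kin.iloc[i]
            if row["d_pole"] < row["d_plane"]:
                count += 1
        out.append((float(tc), count))
    return out


MISALIGNMENT_CATEGORIES = ("no_plate", "high", "low", "tight")


def misalignment_category(
    d_plane_values: Iterable[float],
    thresholds: AlignmentThresholds,
    plate_fraction: float = 0.75,
) -> str:
    """Categorise a cell at one frame by how many pairs sit off the plate.

    The metaphase plate counts as formed when at least ``plate_fraction`` of
    pairs lie within ``d_align_ever`` of the plane.  With a formed plate the
    number of pairs outside that boundary decides the category: 0 -> tight,
    1-4 -> low misalignment, >= 5 -> high misalignment; otherwise no_plate.
    """
    d = np.asarray(list(d_plane_values), dtype=float)
    if d.size == 0:
        raise ValueError("need at least one defined pair")
    outside = int(np.sum(d > thresholds.d_align_ever))
    if (d.size - outside) / d.size < plate_fraction:
        return "no_plate"
    if outside == 0:
        return "tight"
    if outside < 5:
        return "low"
    return "high"


def max_chromosome_spread(centers: np.ndarray) -> float:
    """Largest pairwise distance between pair centers at one frame (um)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 2:
        raise ValueError("need at least two pair centers")
    return float(pdist(centers).max())


def register_to_event(
    kin: pd.DataFrame, event_time: float, pre: float, post: float
) -> pd.DataFrame:
    """Re-index a kinematics series so the event maps to t = 0.

    Returns the rows with registered time in [-pre, post], with ``t`` replaced
    by time relative to the event.
    """
    if event_time is None or not np.isfinite(event_time):
        raise ValueError("event time undefined")
    out = kin.copy()
    out["t"] = out["t"] - event_time
    return out.loc[(out["t"] >= -pre) & (out["t"] <= post)].reset_index(drop=True)


def detect_congression_event(
    kin: pd.DataFrame, pair_id: str, thresholds: AlignmentThresholds
) -> CongressionEvent:
    """Crossing detection plus windowed velocimetry for one pair.

    Velocity is None when the pair never crosses or the pre-crossing window
    coverage is insufficient.
    """
    t_cross = detect_plate_crossing(kin, thresholds)
    if t_cross is None:
        return CongressionEvent(pair_id, None, None, None)
    try:
        v, w_eff = congression_velocity(kin, t_cross, thresholds)
    except InsufficientWindowError:
        return CongressionEvent(pair_id, t_cross, None, None)
    return CongressionEvent(pair_id, t_cross, v, w_eff)
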