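import numpy as np
import pandas as pd
import pytest

from congresskit.events import AlignmentThresholds
from congresskit.geometry import Trajectory, build_spindle_frames


@pytest.fixture
def thresholds():
    return AlignmentThresholds()


@pytest.fixture
def straight_frames():
    """Static spindle with poles at (0,0,0) and (10,0,0) over 60 frames."""
    n = 61
    f = np.arange(n)
    t = f.astype(float)
    pa = Trajectory("A", "pole", f, t, np.tile([0.0, 0.0, 0.0], (n, 1)))
    pb = Trajectory("B", "pole", f, t, np.tile([10.0, 0.0, 0.0], (n, 1)))
    return build_spindle_frames(pa, pb)


def make_kin(t, d_plane, d_pole=None, cx=None, cy=None):
    """Minimal kinematics table for event-rule tests."""
    t = np.asarray(t, dtype=float)
    d_plane = np.asarray(d_plane, dtype=float)
    if d_pole is None:
        d_pole = np.full_like(d_plane, 100.0)
    if cx is None:
        cx = d_plane.copy()
    if cy is None:
        cy = np.zeros_like(d_plane)
    return pd.DataFrame(
        {
            "frame": np.arange(len(t)),
            "t": t,
            "cx": np.asarray(cx, float),
            "cy": np.asarray(cy, float),
            "cz": np.zeros_like(d_plane),
            "d_plane": d_plane,
            "d_pole": np.asarray(d_pole, float),
            "nearest_pole": "A",
            "d_kt": np.ones_like(d_plane),
            "theta_pos": np.zeros_like(d_plane),
            "theta_orient": np.zeros_like(d_plane),
        }
    )
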