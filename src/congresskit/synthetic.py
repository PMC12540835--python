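"""Synthetic congression data with known ground truth.

The generator emulates the statistical structure the analysis assumes, not
spindle mechanics: polar kinetochore pairs wait an exponential time T for
congression initiation (rate ``lambda_init`` per condition), drift slowly
poleward/plateward with positional jitter before T, then move toward the
equatorial plane at a near-constant per-pair fast velocity until they reach
the plate and jitter there.  The interkinetochore distance rises logistically
from its lateral to its bioriented value around T, the sister axis relaxes
toward the spindle axis after T, and a Mad2-like checkpoint intensity starts
decaying ``tau_pre`` minutes *before* the fast movement (slowly from t = 0
for pairs that never initiate).  A per-pair latent Gaussian couples the
realised fast velocity with the Mad2 decay rate (correlation ``coupling_rho``).

Image stacks render each kinetochore as a pixel-integrated 3D Gaussian over a
constant cytoplasmic background, optionally with Poisson noise.

All randomness derives from counter-based substreams of ``master_seed`` so
any single pair is reproducible in isolation.  Default parameter values are
simulator choices (the emulated study reports no numeric fast-phase
velocity); see docs/methods.md for the rationale behind each.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import SchemaError
from .geometry import SisterPairTrack, Trajectory
from .intensity import ImageStack

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionParams:
    """Kinematic parameters of one experimental condition.

    lambda_init : 1/min
        Rate of the exponential congression-initiation time.  ``np.inf``
        means immediate initiation (T = 0), 0 means never.
    v_fast, v_slow : um/min
        Fast-phase plate-approach speed and pre-initiation drift.
    sigma_noise : um
        Per-frame positional jitter (s.d. per coordinate, per sister).
    tau_pre : min, optional
        Condition-specific Mad2 pre-movement lead; None uses the global one.
    """

    lambda_init: float = 0.1
    v_fast: float = 0.8
    v_slow: float = 0.02
    sigma_noise: float = 0.05
    tau_pre: Optional[float] = None


@dataclass(frozen=True)
class InterKTParams:
    """Interkinetochore-distance rise from lateral to bioriented (um, min)."""

    delta_lat: float = 0.6
    delta_bio: float = 1.0
    rise_time: float = 4.0

    def __post_init__(self) -> None:
        if self.delta_bio < self.delta_lat:
            raise ValueError("delta_bio must be >= delta_lat")


@dataclass(frozen=True)
class Mad2Params:
    """Checkpoint-intensity model: plateau, pre-movement lead, decay rates."""

    I0: float = 1.0
    tau_pre: float = 2.0
    k_fast: float = 0.3   # 1/min, decay of initiating pairs
    k_slow: float = 0.03  # 1/min, decay of never-initiating pairs
    cv: float = 0.1       # multiplicative lognormal measurement noise


@dataclass(frozen=True)
class OpticsParams:
    """Rendering parameters for synthetic image stacks."""

    pixel_size_xy: float = 0.27  # um
    z_step: float = 0.5          # um
    shape_yx: tuple[int, int] = (64, 64)
    n_z: int = 9
    sigma_psf_xy: float = 1.5    # px
    sigma_psf_z: float = 1.0     # slices
    background: float = 20.0     # a.u. per voxel
    noise: str = "none"          # 'none' or 'poisson'


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-design description for a synthetic experiment."""

    n_cells: int = 5
    pairs_per_cell: int = 10
    polar_fraction: float = 0.7
    pole_separation: float = 12.0   # um
    elongation_rate: float = 0.0    # um/min, optional spindle elongation ramp
    conditions: dict = field(
        default_factory=lambda: {
            "reactivated": ConditionParams(lambda_init=0.1),
            "inhibited": ConditionParams(lambda_init=0.01),
        }
    )
    interkt: InterKTParams = field(default_factory=InterKTParams)
    mad2: Mad2Params = field(default_factory=Mad2Params)
    optics: OpticsParams = field(default_factory=OpticsParams)
    coupling_rho: float = 0.8       # latent corr(v_fast, Mad2 k_fast)
    v_fast_sigma: float = 0.2       # lognormal spread of per-pair v_fast
    k_fast_sigma: float = 0.4       # lognormal spread of per-pair k_fast
    tau_orient: float = 3.0         # min, sister-axis relaxation time
    plate_halfwidth: float = 1.0    # um, distance at which plate jitter begins
    gap_rate: float = 0.0           # per-frame probability of a tracking gap
    dt: float = 1.0                 # min
    duration: float = 60.0          # min
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [-1, 1]")
        if self.dt <= 0 or self.duration <= 0 or self.pole_separation <= 0:
            raise ValueError("dt, duration and pole separation must be positive")


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    """Counter-based substream: reproducible per (condition, cell, pair, purpose)."""
    return np.random.default_rng([int(config.master_seed) % (2**31), *key])


def _condition_key(condition: str) -> int:
    return zlib.crc32(condition.encode())


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------


def _pair_kinematics_truth(
    config: SimulationConfig,
    cond: ConditionParams,
    rng: np.random.Generator,
    polar: bool,
    t: np.ndarray,
) -> dict:
    """Draw one pair's latent parameters and its noise-free center path."""
    L2 = config.pole_separation / 2.0
    if polar:
        side = -1.0 if rng.random() < 0.5 else 1.0
        d0 = rng.uniform(1.0, 3.0)
        psi = rng.uniform(-np.pi / 3, np.pi / 3)
        x0 = side * (L2 - d0 * np.cos(psi))
        y0 = d0 * np.sin(psi)
        if cond.lambda_init == np.inf:
            T = 0.0
        elif cond.lambda_init <= 0:
            T = np.inf
        else:
            T = rng.exponential(1.0 / cond.lambda_init)
    else:
        side = 1.0
        x0 = rng.normal(0.0, 0.3)
        y0 = rng.uniform(-2.0, 2.0)
        T = 0.0
    # latent bivariate normal coupling speed and checkpoint decay
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, config.coupling_rho], [config.coupling_rho, 1.0]],
    )
    sv, sk = config.v_fast_sigma, config.k_fast_sigma
    v_pair = cond.v_fast * np.exp(sv * z[0] - sv**2 / 2)
    k_pair = config.mad2.k_fast * np.exp(sk * z[1] - sk**2 / 2)

    # noise-free center path along the spindle axis (x) and off-axis (y)
    x = np.empty_like(t)
    if polar:
        sgn = np.sign(x0) if x0 != 0 else 1.0
        if np.isfinite(T):
            slow = np.minimum(t, T)
            ax = np.abs(x0) - cond.v_slow * slow - v_pair * np.maximum(t - T, 0.0)
        else:
            ax = np.abs(x0) - cond.v_slow * t       # slow approach only
        ax = np.maximum(ax, config.plate_halfwidth * 0.3)
        # clamp at the plate: once within plate_halfwidth, hold position
        reached = ax <= config.plate_halfwidth
        if reached.any():
            i0 = int(np.argmax(reached))
            ax[i0:] = ax[i0]
        x[:] = sgn * ax
    else:
        x[:] = x0
    y = np.full_like(t, y0)
    return {
        "side": side,
        "T": float(T),
        "v_pair": float(v_pair),
        "k_pair": float(k_pair),
        "x": x,
        "y": y,
        "polar": polar,
    }


def _logistic_rise(t: np.ndarray, T: float, interkt: InterKTParams) -> np.ndarray:
    """Interkinetochore distance rising logistically around initiation."""
    if not np.isfinite(T):
        return np.full_like(t, interkt.delta_lat)
    tau = max(interkt.rise_time / 4.0, 1e-6)
    frac = 1.0 / (1.0 + np.exp(-(t - T) / tau))
    return interkt.delta_lat + (interkt.delta_bio - interkt.delta_lat) * frac


def simulate_cell(
    config: SimulationConfig, condition: str, cell_index: int
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate one cell: pole tracks, sister tracks, and ground truth.

    Returns (trajectories, ground_truth).  Trajectories contain the two poles
    (ids ``pole_A``/``pole_B``) and two sisters per pair (``p<k>_s1/2``).  The
    ground-truth frame has one row per pair with its true initiation time,
    fast velocity and Mad2 decay rate.
    """
    if condition not in config.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    cond = config.conditions[condition]
    n_frames = int(round(config.duration / config.dt)) + 1
    t = np.arange(n_frames) * config.dt
    frames = np.arange(n_frames)
    L2 = config.pole_separation / 2.0 + 0.5 * config.elongation_rate * t

    def _traj(oid: str, otype: str, xyz: np.ndarray, rng_gap) -> Trajectory:
        keep = np.ones(n_frames, dtype=bool)
        if config.gap_rate > 0:
            keep[1:-1] = rng_gap.random(n_frames - 2) >= config.gap_rate
        return Trajectory(oid, otype, frames[keep], t[keep], xyz[keep], dt=config.dt)

    ckey = _condition_key(condition)
    gap_rng = _rng(config, ckey, cell_index, 9999)
    pole_a = _traj("pole_A", "pole", np.column_stack([-L2, 0 * t, 0 * t]), gap_rng)
    pole_b = _traj("pole_B", "pole", np.column_stack([L2, 0 * t, 0 * t]), gap_rng)
    trajectories = [pole_a, pole_b]

    n_polar = int(round(config.polar_fraction * config.pairs_per_cell))
    truth_rows = []
    for k in range(config.pairs_per_cell):
        rng = _rng(config, ckey, cell_index, k)
        polar = k < n_polar
        kin = _pair_kinematics_truth(config, cond, rng, polar, t)
        d_kt = _logistic_rise(t, kin["T"], config.interkt)
        if polar:
            phi0 = np.deg2rad(rng.uniform(20.0, 80.0))
        else:
            phi0 = np.deg2rad(rng.uniform(0.0, 15.0))
        if np.isfinite(kin["T"]):
            phi = phi0 * np.exp(-np.maximum(t - kin["T"], 0.0) / config.tau_orient)
        else:
            phi = np.full_like(t, phi0)
        ux, uy = np.cos(phi), np.sin(phi)
        half = 0.5 * d_kt
        cx, cy = kin["x"], kin["y"]
        noise = rng.normal(0.0, cond.sigma_noise, size=(2, n_frames, 2))
        s1 = np.column_stack(
            [cx - half * ux + noise[0, :, 0], cy - half * uy + noise[0, :, 1], 0 * t]
        )
        s2 = np.column_stack(
            [cx + half * ux + noise[1, :, 0], cy + half * uy + noise[1, :, 1], 0 * t]
        )
        pid = f"p{k}"
        trajectories.append(_traj(f"{pid}_s1", "kinetochore", s1, rng))
        trajectories.append(_traj(f"{pid}_s2", "kinetochore", s2, rng))
        truth_rows.append(
            {
                "cell_id": f"{condition}_c{cell_index}",
                "pair_id": pid,
                "condition": condition,
                "polar": polar,
                "T_init": kin["T"],
                "v_fast_true": kin["v_pair"],
                "k_mad2_true": kin["k_pair"],
                "side": kin["side"],
            }
        )
    return trajectories, pd.DataFrame(truth_rows)


def simulate_mad2(
    truth_row: pd.Series | dict, config: SimulationConfig, t: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Mad2-like intensity series for one pair.

    Initiating pairs hold I0 until tau_pre minutes before their fast movement,
    then decay exponentially at their per-pair k_fast; pairs that never
    initiate within the recording decay at the slower k_slow from t = 0; the
    intensity decline therefore precedes movement by construction.
    Multiplicative lognormal measurement noise with the configured CV is
    applied when a generator is supplied.
    """
    m = config.mad2
    T = float(truth_row["T_init"])
    tau_pre = m.tau_pre
    cond = config.conditions.get(truth_row.get("condition", ""), None)
    if cond is not None and cond.tau_pre is not None:
        tau_pre = cond.tau_pre
    k = float(truth_row["k_mad2_true"])
    if not bool(truth_row.get("polar", True)):
        I = np.full_like(np.asarray(t, float), 0.1 * m.I0)
    elif np.isfinite(T) and T <= t[-1]:
        t_on = T - tau_pre
        I = np.where(t < t_on, m.I0, m.I0 * np.exp(-k * np.maximum(t - t_on, 0.0)))
    else:
        I = m.I0 * np.exp(-m.k_slow * np.asarray(t, float))
    if rng is not None and m.cv > 0:
        s = np.sqrt(np.log1p(m.cv**2))
        I = I * np.exp(rng.normal(0.0, s, size=len(t)) - s**2 / 2)
    return I


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate all cells of all conditions.

    Returns (tracks, truth, mad2) long-format frames: ``tracks`` in the
    trajectory CSV schema, ``truth`` with one row per pair, ``mad2`` with one
    row per pair per frame.
    """
    track_rows, truth_frames, mad2_rows = [], [], []
    t = np.arange(int(round(config.duration / config.dt)) + 1) * config.dt
    for condition in config.conditions:
        for ci in range(config.n_cells):
            cell_id = f"{condition}_c{ci}"
            trajs, truth = simulate_cell(config, condition, ci)
            truth_frames.append(truth)
            for tr in trajs:
                is_pole = tr.object_type == "pole"
                pair_id = "" if is_pole else tr.object_id.rsplit("_", 1)[0]
                sister = "" if is_pole else tr.object_id.rsplit("_s", 1)[1]
                for i in range(len(tr)):
                    track_rows.append(
                        (
                            cell_id, tr.object_id, tr.object_type, pair_id,
                            sister, int(tr.frame[i]), float(tr.t[i]),
                            tr.xyz[i, 0], tr.xyz[i, 1], tr.xyz[i, 2],
                        )
                    )
            for _, row in truth.iterrows():
                rng = _rng(
                    config, _condition_key(condition), ci,
                    int(row["pair_id"][1:]), 7,
                )
                I = simulate_mad2(row, config, t, rng)
                for ti, Ii in zip(t, I):
                    mad2_rows.append((cell_id, row["pair_id"], float(ti), float(Ii)))
    tracks = pd.DataFrame(
        track_rows,
        columns=[
            "cell_id", "object_id", "object_type", "pair_id", "sister",
            "frame", "t_min", "x_um", "y_um", "z_um",
        ],
    )
    mad2 = pd.DataFrame(mad2_rows, columns=["cell_id", "pair_id", "t_min", "intensity"])
    return tracks, pd.concat(truth_frames, ignore_index=True), mad2


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _pixel_gaussian_weights(n: int, mu: float, sigma: float) -> np.ndarray:
    """Pixel-integrated 1D Gaussian weights (exact via the error function)."""
    edges = np.arange(n + 1) - 0.5
    c = (edges - mu) / (sigma * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(c))
    return np.diff(cdf)


def render_stack(
    positions_px: np.ndarray,
    amplitudes: dict[str, np.ndarray],
    optics: OpticsParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render kinetochores as pixel-integrated 3D Gaussian spots.

    ``positions_px`` has one (x, y) row per spot in pixels (z centered in the
    stack); ``amplitudes`` maps channel name to the programmed *integrated*
    photon count of each spot.  A constant cytoplasmic background is added to
    every voxel; Poisson noise is applied when configured and a generator is
    given.  Spots outside the field are clipped with a warning.  Returns the
    stack and a ground-truth amplitude table.
    """
    ny, nx = optics.shape_yx
    nz = optics.n_z
    positions_px = np.atleast_2d(np.asarray(positions_px, dtype=float))
    channels = list(amplitudes)
    vol = np.full((nz, len(channels), ny, nx), float(optics.background))
    zc = (nz - 1) / 2.0
    truth = []
    for s, (x, y) in enumerate(positions_px):
        if not (0 <= x < nx and 0 <= y < ny):
            warnings.warn(f"spot {s} at ({x:.1f}, {y:.1f}) outside field; clipped")
        wx = _pixel_gaussian_weights(nx, x, optics.sigma_psf_xy)
        wy = _pixel_gaussian_weights(ny, y, optics.sigma_psf_xy)
        wz = _pixel_gaussian_weights(nz, zc, optics.sigma_psf_z)
        spot = wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
        for c, name in enumerate(channels):
            amp = float(np.asarray(amplitudes[name])[s])
            vol[:, c] += amp * spot
            truth.append({"spot": s, "channel": name, "amplitude": amp,
                          "x_px": x, "y_px": y})
    if optics.noise == "poisson":
        if rng is None:
            raise ValueError("Poisson noise requested without a generator")
        vol = rng.poisson(vol).astype(float)
    elif optics.noise != "none":
        raise ValueError(f"unknown noise model {optics.noise!r}")
    stack = ImageStack(
        voxels=vol,
        pixel_size_xy=optics.pixel_size_xy,
        z_step=optics.z_step,
        channels=channels,
    )
    return stack, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# trajectory CSV round-trip
# ---------------------------------------------------------------------------

TRACKS_COLUMNS = [
    "cell_id", "object_id", "object_type", "pair_id", "sister",
    "frame", "t_min", "x_um", "y_um", "z_um",
]
_REQUIRED_COLUMNS = TRACKS_COLUMNS[:-1]  # z_um optional (projected-2D data)


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    """Write a trajectory table to CSV at 6-decimal precision."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in tracks.columns]
    if missing:
        raise SchemaError(f"tracks table missing column(s): {missing}")
    out = tracks.copy()
    if "z_um" not in out.columns:
        out["z_um"] = 0.0
    out[TRACKS_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_tracks_csv(path) -> pd.DataFrame:
    """Read and validate a trajectory CSV.

    Missing required columns, unknown object types and non-numeric fields
    raise :class:`SchemaError` naming the offending row/column.  Rows out of
    frame order are sorted per object with a warning.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "object_id": str,
                                  "pair_id": str, "sister": str},
                     keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tracks CSV missing column(s): {missing}")
    if "z_um" not in df.columns:
        df["z_um"] = 0.0
    bad = ~df["object_type"].isin(["pole", "kinetochore"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"row {row}: invalid object_type {df['object_type'].iloc[row]!r}"
        )
    for col in ("frame", "t_min", "x_um", "y_um", "z_um"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r}: {exc}") from None
    keys = ["cell_id", "object_id"]
    disorder = df.groupby(keys, sort=False)["frame"].apply(
        lambda f: bool((np.diff(f.to_numpy()) <= 0).any())
    )
    if disorder.any():
        warnings.warn("tracks CSV rows out of frame order; sorting per object")
        df = df.sort_values(keys + ["frame"], kind="stable").reset_index(drop=True)
    return df


def tracks_to_cells(
    tracks: pd.DataFrame, dt: float = 1.0
) -> dict[str, dict]:
    """Group a trajectory table into per-cell pole tracks and sister pairs.

    Returns ``{cell_id: {"pole_a", "pole_b", "pairs": {pair_id:
    SisterPairTrack}}}``.  Cells need exactly two pole tracks and each pair
    both sisters.
    """
    cells: dict[str, dict] = {}
    for cell_id, cdf in tracks.groupby("cell_id", sort=False):
        poles = []
        for oid, odf in cdf.loc[cdf["object_type"] == "pole"].groupby(
            "object_id", sort=True
        ):
            poles.append(
                Trajectory(
                    oid, "pole",
                    odf["frame"].to_numpy(), odf["t_min"].to_numpy(),
                    odf[["x_um", "y_um", "z_um"]].to_numpy(), dt=dt,
                )
            )
        if len(poles) != 2:
            raise SchemaError(
                f"cell {cell_id!r}: expected exactly 2 pole tracks, got {len(poles)}"
            )
        pairs: dict[str, SisterPairTrack] = {}
        kdf = cdf.loc[cdf["object_type"] == "kinetochore"]
        for pair_id, pdf in kdf.groupby("pair_id", sort=True):
            sisters = {}
            for sister, sdf in pdf.groupby("sister"):
                sisters[str(sister)] = Trajectory(
                    f"{pair_id}_s{sister}", "kinetochore",
                    sdf["frame"].to_numpy(), sdf["t_min"].to_numpy(),
                    sdf[["x_um", "y_um", "z_um"]].to_numpy(), dt=dt,
                )
            if set(sisters) != {"1", "2"}:
                raise SchemaError(
                    f"cell {cell_id!r} pair {pair_id!r}: needs sisters 1 and 2"
                )
            pairs[str(pair_id)] = SisterPairTrack(
                str(pair_id), str(cell_id), sisters["1"], sisters["2"]
            )
        cells[str(cell_id)] = {"pole_a": poles[0], "pole_b": poles[1], "pairs": pairs}
    return cells
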